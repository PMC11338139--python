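"""Pearson and partial correlation with exact-t significance tests.

Both coefficients share one significance rule: the statistic
``t = r * sqrt(df / (1 - r^2))`` is referred to a Student t distribution
with ``df = n - 2 - m`` degrees of freedom (m = number of controls,
0 for the marginal Pearson case), two-sided.  The exact t distribution is
used rather than a normal approximation because value-range windows can be
small.

Partial correlation is computed by the residual-regression route: regress x
and y each on the controls (with intercept) by least squares and correlate
the residuals.  This is numerically robust at small n; the equivalent
precision-matrix form -Omega_xy/sqrt(Omega_xx * Omega_yy) serves as an
independent oracle in the test suite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrResult",
    "SignificanceLevel",
    "pearson",
    "partial_corr",
    "classify_significance",
    "collinearity_check",
]


class SignificanceLevel(enum.Enum):
    """Four-level stratification of a two-sided p-value.

    ========  ====================  =====
    level     p-value interval      color
    ========  ====================  =====
    NS        p >= 0.05             black
    L1        0.01 <= p < 0.05      blue
    L2        0.001 <= p < 0.01     green
    L3        p < 0.001             red
    ========  ====================  =====

    Interval endpoints belong to the *less* significant class (so p = 0.01
    is L1 and p = 0.001 is L2, extending the p = 0.05 -> NS rule).
    """

    NS = "NS"
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"

    @property
    def display_color(self) -> str:
        return _LEVEL_COLORS[self]


_LEVEL_COLORS = {
    SignificanceLevel.NS: "black",
    SignificanceLevel.L1: "blue",
    SignificanceLevel.L2: "green",
    SignificanceLevel.L3: "red",
}


@dataclass(frozen=True)
class CorrResult:
    """A correlation coefficient with its test: r, two-sided p, n, df, m."""

    r: float
    p: float
    n: int
    df: int
    n_controls: int

    @property
    def level(self) -> SignificanceLevel:
        return classify_significance(self.p)


def _as_vector(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _t_pvalue(r: float, df: int) -> float:
    # |r| = 1 gives an infinite t statistic; the p-value limit is 0.
    denom = 1.0 - r * r
    if denom <= 0.0:
        return 0.0
    t = r * np.sqrt(df / denom)
    return float(2.0 * stats.t.sf(abs(t), df))


def pearson(x, y) -> CorrResult:
    """Sample Pearson coefficient with a two-sided t test (df = n - 2)."""
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(xd @ xd)
    sy = np.sqrt(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.clip((xd @ yd) / (sx * sy), -1.0, 1.0))
    df = n - 2
    return CorrResult(r=r, p=_t_pvalue(r, df), n=n, df=df, n_controls=0)


def partial_corr(x, y, controls=None) -> CorrResult:
    """Partial correlation of x and y given a matrix of control covariates.

    *controls* is an (n, m) array (or None/empty for m = 0, which reduces
    exactly to :func:`pearson`).  Residuals of x and y on the controls
    (intercept included) are correlated; p comes from the t test with
    ``n - 2 - m`` degrees of freedom.

    Raises
    ------
    ValueError
        If the control design (intercept plus controls) is rank-deficient,
        or n < m + 3.
    """
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if controls is None:
        return pearson(x, y)
    Z = np.asarray(controls, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.size == 0 or Z.shape[1] == 0:
        return pearson(x, y)
    n, m = Z.shape
    if n != x.size:
        raise ValueError(f"controls have {n} rows, data have {x.size}")
    if n < m + 3:
        raise ValueError(f"need n >= m + 3 (n={n}, m={m})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < m + 1:
        raise ValueError("control matrix is rank-deficient (collinear controls)")
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    # residuals at rounding-error scale mean the variable is (numerically)
    # an exact linear function of the controls: no partial variance remains
    xc = x - x.mean()
    yc = y - y.mean()
    tol_x = 1e-10 * max(np.sqrt(xc @ xc), 1e-300)
    tol_y = 1e-10 * max(np.sqrt(yc @ yc), 1e-300)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("partial correlation undefined: a variable is fully "
                         "explained by the controls")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - m
    return CorrResult(r=r, p=_t_pvalue(r, df), n=n, df=df, n_controls=m)


def classify_significance(p: float) -> SignificanceLevel:
    """Map a p-value onto the four-level scheme (endpoints go downward)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p >= 0.05:
        return SignificanceLevel.NS
    if p >= 0.01:
        return SignificanceLevel.L1
    if p >= 0.001:
        return SignificanceLevel.L2
    return SignificanceLevel.L3


def collinearity_check(
    controls, names: list[str] | None = None, threshold: float = 0.9
) -> list[str]:
    """Warn about highly correlated control pairs (|r| > threshold).

    Near-collinear controls make partial correlations unstable; this is a
    diagnostic, never an error.  Returns one message per offending pair.
    """
    Z = np.asarray(controls, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    m = Z.shape[1]
    if names is None:
        names = [f"control_{j}" for j in range(m)]
    warnings: list[str] = []
    for i in range(m):
        for j in range(i + 1, m):
            r = pearson(Z[:, i], Z[:, j]).r
            if abs(r) > threshold:
                warnings.append(
                    f"controls {names[i]!r} and {names[j]!r} are highly "
                    f"correlated (r = {r:.3f}); partial correlations may be unstable"
                )
    return warnings
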
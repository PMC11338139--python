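"""The sliding-window sweep and the regime-transition scan.

The windowed (partial) correlation coefficient acts as an order parameter:
plotted against the window's sample mean it traces how the driver-response
coupling changes along the driver's value range.  The transition scan
implements the rule used to read that curve: a run of significantly positive
windows at low driver values that loses significance marks the regime
change, and the minimum driver value observed inside the transition window
is reported as the intensity threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import (
    CorrResult,
    SignificanceLevel,
    partial_corr,
    pearson,
    collinearity_check,
)
from .data_model import NormalizationParams, denormalize
from .windowing import WindowSpec, assign_samples, generate_windows

logger = logging.getLogger(__name__)

__all__ = [
    "WindowResult",
    "SweepResult",
    "TransitionReport",
    "run_sweep",
    "detect_transition",
]

#: Qualitative transition patterns.
PATTERN_POS_NS = "pos->ns"
PATTERN_POS_NS_NEG = "pos->ns->neg"
PATTERN_NONE = "none"
PATTERN_OTHER = "other"


@dataclass(frozen=True)
class WindowResult:
    """One window's descriptive statistics and (possibly undefined) coefficient.

    ``r``, ``p`` and ``level`` are None when the window has fewer than
    ``min_samples`` members or is degenerate (constant column, collinear
    controls within the window).  Descriptive fields are populated whenever
    the window holds at least one sample.  ``x_coord`` (the sample mean) and
    ``y_coord`` (r) are the plotting coordinates.
    """

    window_id: int
    nominal_lower: float
    nominal_upper: float
    sample_min: float | None
    sample_max: float | None
    sample_mean: float | None
    n: int
    controls: tuple[str, ...]
    r: float | None
    p: float | None
    level: SignificanceLevel | None

    @property
    def defined(self) -> bool:
        return self.r is not None

    @property
    def x_coord(self) -> float | None:
        return self.sample_mean

    @property
    def y_coord(self) -> float | None:
        return self.r


@dataclass(frozen=True)
class SweepResult:
    """Ordered window results with everything needed to reproduce the run."""

    driver: str
    response: str
    controls: tuple[str, ...]
    spec: WindowSpec
    windows: tuple[WindowResult, ...]
    norm_params: NormalizationParams | None = None

    def defined_windows(self) -> list[WindowResult]:
        return [w for w in self.windows if w.defined]


@dataclass(frozen=True)
class TransitionReport:
    """Outcome of the transition scan.

    ``transition_window_id`` is None when no transition was found; then only
    ``pattern`` is informative.  ``threshold_normalized`` is the transition
    window's minimum sample value (on the driver's analysis scale);
    ``threshold_original`` is that value mapped back through the recorded
    normalization, when available.
    """

    transition_window_id: int | None
    transition_range: tuple[float, float] | None
    threshold_normalized: float | None
    threshold_original: float | None
    pattern: str


def _window_result(
    table: pd.DataFrame,
    driver: str,
    response: str,
    controls: tuple[str, ...],
    window,
    min_samples: int,
) -> WindowResult:
    idx = window.member_indices
    n = int(idx.size)
    if n == 0:
        smin = smax = smean = None
    else:
        x = table[driver].to_numpy(dtype=float)[idx]
        smin, smax, smean = float(x.min()), float(x.max()), float(x.mean())
    res: CorrResult | None = None
    if n >= min_samples:
        x = table[driver].to_numpy(dtype=float)[idx]
        y = table[response].to_numpy(dtype=float)[idx]
        Z = table[list(controls)].to_numpy(dtype=float)[idx] if controls else None
        try:
            res = partial_corr(x, y, Z) if controls else pearson(x, y)
        except ValueError as exc:  # degenerate window: report, don't abort
            logger.warning("window %d [%g, %g]: coefficient undefined (%s)",
                           window.index, window.lower, window.upper, exc)
    return WindowResult(
        window_id=window.index,
        nominal_lower=window.lower,
        nominal_upper=window.upper,
        sample_min=smin,
        sample_max=smax,
        sample_mean=smean,
        n=n,
        controls=controls,
        r=res.r if res else None,
        p=res.p if res else None,
        level=res.level if res else None,
    )


def run_sweep(
    table: pd.DataFrame,
    driver: str,
    response: str,
    controls: list[str] | tuple[str, ...] = (),
    spec: WindowSpec = WindowSpec(w=40.0, l=5.0),
    norm_params: NormalizationParams | None = None,
) -> SweepResult:
    """Run the full sliding-window analysis.

    For every window over the driver's value range, compute the Pearson
    coefficient between driver and response (when *controls* is empty) or
    the partial coefficient controlling the named covariates.  Windows with
    too few members, or degenerate within-window data, yield a result record
    with an undefined coefficient rather than being dropped.

    Parameters
    ----------
    table
        Observation table; all named columns must exist and be numeric.
    driver, response
        Column names of the driving and responding variable.
    controls
        Covariate column names for partial correlation (may be empty).
    spec
        Window geometry.  ``spec.min_samples=None`` resolves to
        ``len(controls) + 3``.
    norm_params
        Normalization parameters, if the table was rescaled; carried through
        so thresholds can be reported in original units.
    """
    controls = tuple(controls)
    for col in (driver, response, *controls):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    if driver == response:
        raise ValueError("driver and response must differ")
    if driver in controls or response in controls:
        raise ValueError("controls must exclude driver and response")
    min_samples = spec.min_samples if spec.min_samples is not None else len(controls) + 3

    if controls:
        for msg in collinearity_check(
            table[list(controls)].to_numpy(dtype=float), names=list(controls)
        ):
            logger.warning(msg)

    x = table[driver].to_numpy(dtype=float)
    if x.min() < spec.origin:
        logger.warning(
            "%d samples lie below the window origin %g and enter no window",
            int((x < spec.origin).sum()), spec.origin,
        )
    windows = generate_windows(spec, float(x.max()))
    results = tuple(
        _window_result(table, driver, response, controls,
                       assign_samples(table, driver, win), min_samples)
        for win in windows
    )
    n_undefined = sum(not w.defined for w in results)
    if n_undefined:
        logger.info("%d of %d windows have an undefined coefficient "
                    "(fewer than %d samples or degenerate)",
                    n_undefined, len(results), min_samples)
    return SweepResult(
        driver=driver,
        response=response,
        controls=controls,
        spec=spec,
        windows=results,
        norm_params=norm_params,
    )


def detect_transition(
    sweep: SweepResult,
    alpha: float = 0.05,
    min_run: int = 1,
    neg_alpha: float = 0.001,
) -> TransitionReport:
    """Scan defined windows in ascending driver order for the regime change.

    The transition is the first window whose coefficient loses significance
    (p >= *alpha*) after a run of at least *min_run* windows with r > 0 and
    p < *alpha*.  Its minimum sample value is the reported threshold.  The
    pattern is upgraded from ``pos->ns`` to ``pos->ns->neg`` when any later
    defined window is significantly negative (r < 0, p < *neg_alpha*).

    Patterns: ``none`` — no significant positive run exists; ``other`` — a
    positive run exists but never loses significance (no transition).
    Windows with undefined coefficients are skipped during the scan but kept
    in the sweep output.
    """
    defined = sweep.defined_windows()
    if not defined:
        raise ValueError("sweep contains no window with a defined coefficient")

    run = 0
    transition: WindowResult | None = None
    for win in defined:
        if transition is None:
            if win.r > 0 and win.p < alpha:
                run += 1
            elif run >= min_run and win.p >= alpha:
                transition = win
            else:
                run = 0
    if transition is None:
        pattern = PATTERN_OTHER if run >= min_run else PATTERN_NONE
        return TransitionReport(
            transition_window_id=None,
            transition_range=None,
            threshold_normalized=None,
            threshold_original=None,
            pattern=pattern,
        )

    pattern = PATTERN_POS_NS
    for win in defined:
        if win.window_id > transition.window_id and win.r < 0 and win.p < neg_alpha:
            pattern = PATTERN_POS_NS_NEG
            break

    threshold = transition.sample_min
    threshold_original = None
    if sweep.norm_params is not None and sweep.driver in sweep.norm_params:
        threshold_original = denormalize(threshold, sweep.norm_params, sweep.driver)
    return TransitionReport(
        transition_window_id=transition.window_id,
        transition_range=(transition.sample_min, transition.sample_max),
        threshold_normalized=threshold,
        threshold_original=threshold_original,
        pattern=pattern,
    )
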
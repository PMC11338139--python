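"""Synthetic coupled driver/response systems with known regime structure.

The generator emulates the qualitative structure the windowed-coefficient
method is built to detect: a response that couples to the driver with a
different slope in different value ranges (positive coupling at low
intensity, decoupling, negative coupling at high intensity), plus
confounding covariates that load on both variables and additive Gaussian
noise.  Because the ground truth (breakpoints, slopes, loadings, seed) is
returned with the data, every stage of the pipeline is testable without any
external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfounderSpec", "PiecewiseCouplingModel", "GroundTruth", "generate", "write_fixture"]

DRIVER_COL = "driver"
RESPONSE_COL = "response"


@dataclass(frozen=True)
class ConfounderSpec:
    """A covariate loading on both driver and response.

    The confounder is built as ``driver_loading * z(driver) + N(0, 1)`` where
    ``z`` standardizes the driver, and contributes ``response_loading * c``
    to the response.  A nonzero product of the two loadings opens a spurious
    driver-response path that partial correlation (controlling c) removes.
    """

    driver_loading: float = 1.0
    response_loading: float = 1.0


@dataclass(frozen=True)
class PiecewiseCouplingModel:
    """Continuous piecewise-linear coupling of response to a uniform driver.

    The driver is uniform on [0, 100].  ``breakpoints`` (strictly inside
    (0, 100), ascending) split the range into ``len(slopes)`` segments; the
    response follows the continuous piecewise-linear function with those
    per-segment slopes, starting from 0 at driver 0.  Continuity (segments
    joined at the breakpoints) makes window means vary smoothly, as real
    intensity data do.  ``noise_sd`` is the additive Gaussian noise scale in
    response units.
    """

    n: int = 2000
    breakpoints: tuple[float, ...] = (40.0, 60.0)
    slopes: tuple[float, ...] = (1.0, 0.0, -1.0)
    noise_sd: float = 4.0
    confounders: tuple[ConfounderSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size and (np.any(bp <= 0.0) or np.any(bp >= 100.0)):
            raise ValueError("breakpoints must lie strictly inside (0, 100)")
        if bp.size > 1 and not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly ascending")
        if len(self.slopes) != bp.size + 1:
            raise ValueError(
                f"need {bp.size + 1} slopes for {bp.size} breakpoints, "
                f"got {len(self.slopes)}"
            )
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew: the targets recovery tests aim at."""

    breakpoints: tuple[float, ...]
    slopes: tuple[float, ...]
    noise_sd: float
    confounders: tuple[ConfounderSpec, ...]
    seed: int
    response_range: float


def piecewise_response(u: np.ndarray, breakpoints: Sequence[float],
                       slopes: Sequence[float]) -> np.ndarray:
    """Continuous piecewise-linear f(u) with f(0) = 0 and per-segment slopes."""
    knots = np.concatenate([[0.0], np.asarray(breakpoints, dtype=float)])
    slopes = np.asarray(slopes, dtype=float)
    # value of f at each knot, by accumulating slope * segment length
    knot_vals = np.concatenate([[0.0], np.cumsum(slopes[:-1] * np.diff(knots))])
    seg = np.clip(np.searchsorted(knots, u, side="right") - 1, 0, slopes.size - 1)
    return knot_vals[seg] + slopes[seg] * (u - knots[seg])


def generate(
    model: PiecewiseCouplingModel,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one dataset from the model; reproducible given ``model.seed``.

    Returns the observation table (columns ``driver``, ``response``,
    ``conf1..confm``) and the ground-truth record.
    """
    rng = np.random.default_rng(model.seed)
    u = rng.uniform(0.0, 100.0, size=model.n)
    signal = piecewise_response(u, model.breakpoints, model.slopes)

    z = (u - 50.0) / (100.0 / np.sqrt(12.0))  # standardized uniform driver
    columns: dict[str, np.ndarray] = {DRIVER_COL: u}
    response = signal.copy()
    conf_cols: dict[str, np.ndarray] = {}
    for j, spec in enumerate(model.confounders, start=1):
        c = spec.driver_loading * z + rng.standard_normal(model.n)
        response = response + spec.response_loading * c
        conf_cols[f"conf{j}"] = c
    response = response + rng.normal(0.0, model.noise_sd, size=model.n)
    columns[RESPONSE_COL] = response
    columns.update(conf_cols)

    sig_range = float(signal.max() - signal.min()) if model.n > 1 else 0.0
    truth = GroundTruth(
        breakpoints=tuple(model.breakpoints),
        slopes=tuple(model.slopes),
        noise_sd=model.noise_sd,
        confounders=tuple(model.confounders),
        seed=model.seed,
        response_range=sig_range,
    )
    return pd.DataFrame(columns), truth


def write_fixture(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as the CSV dialect the loader consumes (lossless repr)."""
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    return path
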
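"""Loading, validation and 0–100 min–max normalization of observation tables.

The analysis operates on a plain :class:`pandas.DataFrame` of named numeric
columns ("sample table"): one driver column (e.g. an input intensity in
sej/ha), one response column (e.g. output intensity), and zero or more
control columns.  Driver and response are conventionally normalized to the
range 0–100 before windowing so that window size and step are comparable
across variables; the normalization constants are retained so thresholds can
be mapped back to original units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationParams",
    "load_table",
    "normalize_minmax",
    "denormalize",
    "flag_outliers",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column affine min–max parameters mapping observed range to [0, 100].

    ``ranges`` maps column name to ``(observed_min, observed_max)``.  The
    target interval is fixed at [0, 100]: min–max scaling is the unique
    affine map onto that range.
    """

    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    target_lo: float = 0.0
    target_hi: float = 100.0

    def __post_init__(self) -> None:
        for col, (lo, hi) in self.ranges.items():
            if not hi > lo:
                raise ValueError(
                    f"column {col!r}: observed max ({hi}) must exceed min ({lo})"
                )

    def __contains__(self, column: str) -> bool:
        return column in self.ranges


def load_table(
    path: str | Path,
    required_columns: Iterable[str],
) -> pd.DataFrame:
    """Read a comma-delimited table and validate the analysis columns.

    Parameters
    ----------
    path
        CSV file with a header row, UTF-8, decimal-point notation.
    required_columns
        Columns that must be present and numeric.  Rows with a missing value
        in any of them are dropped (listwise deletion) with a logged count.

    Returns
    -------
    pandas.DataFrame
        The table with required columns coerced to float and incomplete rows
        removed; the index is reset to 0..n-1.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    KeyError
        If a required column is absent.
    ValueError
        If a required column contains a non-numeric, non-missing cell, or no
        complete rows remain.
    """
    path = Path(path)
    required = list(required_columns)
    if not path.is_file():
        raise FileNotFoundError(f"no such input file: {path}")
    table = pd.read_csv(path)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise KeyError(
            f"required column(s) {missing} not found; file has {list(table.columns)}"
        )
    for col in required:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            offender = table.loc[bad.idxmax(), col]
            raise ValueError(
                f"non-numeric value {offender!r} in required column {col!r} "
                f"(row {int(bad.idxmax())})"
            )
        table[col] = coerced.astype(float)
    complete = table[required].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning(
            "dropped %d of %d rows with missing values in %s",
            n_dropped, len(table), required,
        )
    table = table.loc[complete].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("no complete rows remain after listwise deletion")
    return table


def normalize_minmax(
    table: pd.DataFrame,
    columns: Iterable[str],
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Rescale *columns* to [0, 100] by x -> 100*(x - min)/(max - min).

    Returns a copy of the table with the named columns replaced and the
    per-column parameters needed to invert the map.  A constant column
    (max == min) is an error: it carries no range to rescale.
    """
    table = table.copy()
    ranges: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if not hi > lo:
            raise ValueError(f"cannot normalize constant column {col!r} (all {lo})")
        # scale before multiplying so the observed extremes land exactly on 0/100
        table[col] = 100.0 * ((x - lo) / (hi - lo))
        ranges[col] = (lo, hi)
    return table, NormalizationParams(ranges=ranges)


def denormalize(value: float, params: NormalizationParams, column: str) -> float:
    """Map a 0–100-scale value back to *column*'s original units.

    Exact inverse of :func:`normalize_minmax`:
    ``min + value/100 * (max - min)``.
    """
    if column not in params:
        raise KeyError(f"no normalization parameters recorded for column {column!r}")
    lo, hi = params.ranges[column]
    span = params.target_hi - params.target_lo
    return lo + (value - params.target_lo) / span * (hi - lo)


def flag_outliers(
    table: pd.DataFrame,
    columns: Iterable[str],
    k: float = 3.0,
) -> pd.Series:
    """Flag rows with a value beyond k*IQR outside the quartiles (Tukey fence).

    An optional pre-screen — extreme values distort window correlations —
    returned as a boolean mask so the caller decides whether to drop.  The
    default fence (k=3) marks only far outliers; nothing is removed
    automatically.
    """
    mask = pd.Series(False, index=table.index)
    for col in columns:
        x = table[col].astype(float)
        q1, q3 = x.quantile(0.25), x.quantile(0.75)
        iqr = q3 - q1
        mask |= (x < q1 - k * iqr) | (x > q3 + k * iqr)
    n_flagged = int(mask.sum())
    if n_flagged:
        logger.warning("flagged %d rows as outliers (k=%.3g IQR fence)", n_flagged, k)
    return mask
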
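"""Value-range windows over the driver variable.

Windows here slide over the *values* of the driver column, not over time or
position: window k spans ``[origin + k*l, origin + k*l + w]`` in driver
units, and the samples entering a window's correlation are the observations
whose driver value falls inside the range.  Consecutive windows overlap by
``w - l`` when ``l < w``.

Boundary convention: every window is half-open ``[lower, upper)`` except the
terminal one, which is closed so the maximum sample is always captured.
Half-open interiors prevent a sample sitting exactly on a shared bound from
being counted in two windows at once only through the closure rule, while the
overlap of consecutive *ranges* (by construction) is the intended overlap of
member sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["WindowSpec", "ValueWindow", "sort_key", "generate_windows", "assign_samples"]


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry: size ``w`` and step ``l`` in driver units.

    ``min_samples`` is the smallest member count for which a window yields a
    defined coefficient; ``None`` defers to the sweep's default of
    ``n_controls + 3`` (the minimum leaving one residual degree of freedom,
    plus a margin of one).  ``origin`` is the lower bound of the first
    window, 0 by convention for data normalized to [0, 100].
    """

    w: float
    l: float
    min_samples: int | None = None
    origin: float = 0.0

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(f"window size w must be positive, got {self.w}")
        if not self.l > 0:
            raise ValueError(f"step width l must be positive, got {self.l}")
        if self.min_samples is not None and self.min_samples < 3:
            raise ValueError(f"min_samples must be >= 3, got {self.min_samples}")


@dataclass(frozen=True)
class ValueWindow:
    """One window: ordinal index, nominal bounds, and (once assigned) members."""

    index: int
    lower: float
    upper: float
    is_terminal: bool = False
    member_indices: np.ndarray | None = field(default=None, compare=False)


def sort_key(table: pd.DataFrame, driver: str) -> np.ndarray:
    """Row indices ordering the driver column ascending; ties keep row order."""
    if driver not in table.columns:
        raise KeyError(f"driver column {driver!r} not in table")
    return np.argsort(table[driver].to_numpy(dtype=float), kind="stable")


def generate_windows(spec: WindowSpec, driver_max: float) -> list[ValueWindow]:
    """Enumerate windows [origin + k*l, origin + k*l + w] for k = 0, 1, ...

    Iteration stops with the first window whose upper bound reaches or
    exceeds *driver_max*; that window is included (and marked terminal) so
    the highest-intensity samples always participate.
    """
    if not driver_max > spec.origin:
        raise ValueError(
            f"driver maximum ({driver_max}) must exceed window origin ({spec.origin})"
        )
    windows: list[ValueWindow] = []
    k = 0
    while True:
        lower = spec.origin + k * spec.l
        upper = lower + spec.w
        done = upper >= driver_max
        windows.append(ValueWindow(index=k, lower=lower, upper=upper, is_terminal=done))
        if done:
            return windows
        k += 1


def window_count(spec: WindowSpec, driver_max: float) -> int:
    """Closed form for the number of generated windows.

    ``1 + ceil((driver_max - w - origin)/l)`` when the first window does not
    already cover the maximum, else 1.
    """
    if driver_max <= spec.origin + spec.w:
        return 1
    return 1 + math.ceil((driver_max - spec.w - spec.origin) / spec.l)


def assign_samples(
    table: pd.DataFrame, driver: str, window: ValueWindow
) -> ValueWindow:
    """Attach to *window* the row indices whose driver value falls inside it.

    Membership is ``lower <= x < upper``, or ``lower <= x <= upper`` for the
    terminal window.  Empty membership is legal; downstream stages emit an
    undefined coefficient for such windows.
    """
    x = table[driver].to_numpy(dtype=float)
    if window.is_terminal:
        inside = (x >= window.lower) & (x <= window.upper)
    else:
        inside = (x >= window.lower) & (x < window.upper)
    return replace(window, member_indices=np.flatnonzero(inside))
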
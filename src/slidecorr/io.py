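"""Result export (ten-column CSV) and the significance-colored scatter plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import pandas as pd

matplotlib.use("Agg")  # headless backend; plots go straight to file
import matplotlib.pyplot as plt  # noqa: E402

from .sweep import SweepResult, TransitionReport

__all__ = ["CSV_COLUMNS", "export_csv", "plot_sweep", "format_report"]

#: Output schema, one row per window: range id, plotting coordinates
#: (x = window sample mean, y = coefficient), controls, descriptive
#: statistics, member count, coefficient and p-value.
CSV_COLUMNS = [
    "range_id",
    "x_coord",
    "y_coord",
    "controls",
    "sample_min",
    "sample_max",
    "sample_mean",
    "n_samples",
    "r",
    "p_value",
]

_CONTROL_SEP = ";"


def sweep_to_frame(sweep: SweepResult) -> pd.DataFrame:
    """One row per window in the export schema; undefined r/p become NaN."""
    controls = _CONTROL_SEP.join(sweep.controls)
    rows = [
        {
            "range_id": w.window_id,
            "x_coord": w.x_coord,
            "y_coord": w.y_coord,
            "controls": controls,
            "sample_min": w.sample_min,
            "sample_max": w.sample_max,
            "sample_mean": w.sample_mean,
            "n_samples": w.n,
            "r": w.r,
            "p_value": w.p,
        }
        for w in sweep.windows
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def export_csv(sweep: SweepResult, path: str | Path) -> Path:
    """Write the sweep as CSV: exactly the ten schema columns, in order.

    Undefined coefficients and p-values appear as empty cells; stored
    numbers keep full precision (display rounding is left to consumers).
    """
    if not sweep.windows:
        raise ValueError("cannot export an empty sweep")
    path = Path(path)
    sweep_to_frame(sweep).to_csv(path, index=False, float_format="%.17g")
    return path


def plot_sweep(sweep: SweepResult, path: str | Path) -> Path:
    """Scatter the order-parameter curve: (window mean, r), colored by p.

    Black / blue / green / red mark p >= 0.05, [0.01, 0.05), [0.001, 0.01)
    and < 0.001.  Format follows the file extension (png, svg, pdf).
    """
    defined = sweep.defined_windows()
    if not defined:
        raise ValueError("no window with a defined coefficient to plot")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    seen_levels = []
    for w in defined:
        color = w.level.display_color
        label = None
        if w.level not in seen_levels:
            seen_levels.append(w.level)
            bounds = {
                "black": "p ≥ 0.05",
                "blue": "0.01 ≤ p < 0.05",
                "green": "0.001 ≤ p < 0.01",
                "red": "p < 0.001",
            }
            label = bounds[color]
        ax.scatter(w.x_coord, w.y_coord, c=color, s=28, label=label, zorder=3)
    ax.axhline(0.0, lw=0.6, color="gray", zorder=1)
    kind = "partial correlation" if sweep.controls else "correlation"
    ax.set_xlabel(f"mean {sweep.driver} within window")
    ax.set_ylabel(f"{kind} ({sweep.driver}, {sweep.response})")
    ax.set_ylim(-1.05, 1.05)
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def format_report(report: TransitionReport, driver: str = "driver") -> str:
    """Human-readable rendering of a transition report."""
    lines = [f"coupling pattern: {report.pattern}"]
    if report.transition_window_id is None:
        lines.append("no regime transition detected")
    else:
        lo, hi = report.transition_range
        lines.append(
            f"transition window #{report.transition_window_id}: "
            f"samples span [{lo:.6g}, {hi:.6g}]"
        )
        lines.append(
            f"{driver} threshold (analysis scale): {report.threshold_normalized:.6g}"
        )
        if report.threshold_original is not None:
            lines.append(
                f"{driver} threshold (original units): {report.threshold_original:.6g}"
            )
    return "\n".join(lines)
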
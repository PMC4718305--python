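"""Concentration-curve plots in the style of the study figure:
dashed plasma, solid effect-site, a horizontal MEC line, and shaded
undertreated (sub-MEC) intervals."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metrics import WindowMetrics
from .pk_core import TherapeuticWindow
from .simulate import ConcentrationSeries


def plot_series(
    series: ConcentrationSeries,
    window: TherapeuticWindow | None = None,
    metrics: WindowMetrics | None = None,
    ax=None,
    title: str | None = None,
):
    """Plot plasma (dashed) and effect-site (solid) concentrations.

    If ``metrics`` is given, its undertreated intervals are shaded grey.
    Returns the matplotlib axes.
    """
    if window is None:
        window = TherapeuticWindow()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.plot(series.times, series.cp, "k--", lw=1.2, label="plasma")
    ax.plot(series.times, series.ce, "r-", lw=1.4, label="effect site")
    ax.axhline(window.mec, color="k", lw=1.0, label=f"MEC {window.mec:g} ng/mL")
    if metrics is not None:
        for start, end in metrics.undertreated_intervals:
            ax.axvspan(start, end, color="0.8", zorder=0)
    ax.set_xlabel("time after end of surgery (min)")
    ax.set_ylabel("fentanyl concentration (ng/mL)")
    ax.set_title(title or series.name)
    ax.legend(frameon=False)
    return ax


def save_plot(ax, path) -> None:
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
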
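"""Plots: the rmcorr scatter with parallel per-participant fits, and the
side-by-side comparison against pooled and averaged simple regressions.

Tests target the plot's data layer (line endpoints, point counts), never
rendered pixels; the line geometry comes straight from
:func:`rmcorr.core.predicted_lines`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import RmcorrResult, predicted_lines
from .data import PairedRepeatedData
from .errors import RmcorrError

__all__ = ["PlotConfig", "rmcorr_plot", "comparison_panel", "OKABE_ITO"]

# Colorblind-safe qualitative palette (Okabe-Ito); cycled when N exceeds
# its length.
OKABE_ITO = (
    "#0072B2",
    "#E69F00",
    "#009E73",
    "#D55E00",
    "#CC79A7",
    "#56B4E9",
    "#F0E442",
    "#999999",
)


@dataclass
class PlotConfig:
    """Appearance options for the rmcorr plot."""

    show_overall: bool = True
    overall_color: str = "gray"
    overall_width: float = 3.0
    overall_dash: str = "--"
    palette: object = None  # sequence of colors or a named colormap
    x_label: str | None = None
    y_label: str | None = None
    output_path: str | None = None
    format: str | None = None  # png | pdf | svg; inferred from path if None

    def colors(self, n: int) -> list:
        pal = self.palette
        if pal is None:
            pal = OKABE_ITO
        elif isinstance(pal, str):
            import matplotlib

            cmap = matplotlib.colormaps[pal]
            pal = getattr(cmap, "colors", None) or [
                cmap(i / max(n - 1, 1)) for i in range(n)
            ]
        return list(itertools.islice(itertools.cycle(pal), n))


def _save(fig, config: PlotConfig) -> None:
    if config.output_path:
        path = Path(config.output_path)
        try:
            fig.savefig(path, format=config.format, dpi=150, bbox_inches="tight")
        except OSError as exc:
            raise RmcorrError(f"cannot write figure to {path}: {exc}") from exc


def _pooled_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, intercept) of the OLS line treating all rows as independent."""
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def rmcorr_plot(
    data: PairedRepeatedData,
    result: RmcorrResult,
    config: PlotConfig | None = None,
    ax=None,
):
    """Scatter colored by participant with one parallel fit line each.

    Each participant's line spans only their observed covariate range
    (no extrapolation).  When ``config.show_overall`` is set, a dashed
    gray line shows the pooled OLS fit that would result from treating
    the rows as independent observations.  Returns the matplotlib Axes;
    saves to ``config.output_path`` when given.
    """
    import matplotlib.pyplot as plt

    config = config or PlotConfig()
    lines = predicted_lines(result, data)  # also validates data/result match
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = config.colors(data.N)

    if config.show_overall:
        slope, intercept = _pooled_line(data.measure2, data.measure1)
        xs = np.array([data.measure2.min(), data.measure2.max()])
        ax.plot(
            xs,
            intercept + slope * xs,
            color=config.overall_color,
            linewidth=config.overall_width,
            linestyle=config.overall_dash,
            zorder=1,
            label="overall (pooled OLS)",
        )
    for line, color in zip(lines, colors):
        rows = data.participant_rows(line.participant)
        ax.scatter(data.measure2[rows], data.measure1[rows], color=color, s=18, zorder=2)
        ax.plot(
            [line.x[0], line.x[-1]],
            [line.y_hat[0], line.y_hat[-1]],
            color=color,
            linewidth=1.5,
            zorder=3,
        )
    ax.set_xlabel(config.x_label or data.measure2_name)
    ax.set_ylabel(config.y_label or data.measure1_name)
    _save(ax.figure, config)
    return ax


def comparison_panel(
    data: PairedRepeatedData,
    result: RmcorrResult,
    config: PlotConfig | None = None,
    trial=None,
):
    """Three-panel comparison of levels of analysis.

    (A) simple regression treating rows as independent (per occasion if
    ``trial`` labels are given, pooled otherwise); (B) the rmcorr plot;
    (C) simple regression on participant-averaged data, one point per
    participant.  Returns the matplotlib Figure.
    """
    import matplotlib.pyplot as plt
    import pandas as pd

    config = config or PlotConfig()
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    x, y = data.measure2, data.measure1

    ax = axes[0]
    ax.scatter(x, y, color="black", s=16)
    if trial is not None:
        trial = np.asarray(trial, dtype=object)
        for lev in pd.unique(trial):
            rows = np.flatnonzero(trial == lev)
            if rows.size >= 2:
                s, b = _pooled_line(x[rows], y[rows])
                xs = np.array([x[rows].min(), x[rows].max()])
                ax.plot(xs, b + s * xs, color="red", linewidth=1.5)
        ax.set_title("(A) simple regression by occasion")
    else:
        s, b = _pooled_line(x, y)
        xs = np.array([x.min(), x.max()])
        ax.plot(xs, b + s * xs, color="red", linewidth=2)
        ax.set_title("(A) simple regression (all rows)")
    ax.set_xlabel(config.x_label or data.measure2_name)
    ax.set_ylabel(config.y_label or data.measure1_name)

    sub_config = PlotConfig(
        show_overall=False,
        palette=config.palette,
        x_label=config.x_label,
        y_label=config.y_label,
    )
    rmcorr_plot(data, result, sub_config, ax=axes[1])
    axes[1].set_title("(B) rmcorr")

    ax = axes[2]
    counts = data.counts.astype(float)
    xm = np.bincount(data.codes, weights=x, minlength=data.N) / counts
    ym = np.bincount(data.codes, weights=y, minlength=data.N) / counts
    ax.scatter(xm, ym, color="black", s=24)
    s, b = _pooled_line(xm, ym)
    xs = np.array([xm.min(), xm.max()])
    ax.plot(xs, b + s * xs, color="red", linewidth=2)
    ax.set_title("(C) simple regression (averaged)")
    ax.set_xlabel(config.x_label or data.measure2_name)
    ax.set_ylabel(config.y_label or data.measure1_name)

    fig.tight_layout()
    _save(fig, config)
    return fig
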
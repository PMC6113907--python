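"""Figure helpers: mean traces, rasters, dose-response curves.

Matplotlib is imported lazily so the simulation stack has no hard plotting
dependency; install the ``plots`` extra (or any matplotlib) to use these.
"""

from __future__ import annotations

import numpy as np

from .analysis import DoseResponse, RasterData, logistic_decreasing
from .engine import SimulationResult

__all__ = ["plot_mean_trace", "plot_raster", "plot_dose_response"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(7, 3))
    return ax


def plot_mean_trace(result: SimulationResult, ax=None, path=None):
    """Islet-mean Ca²⁺ vs time with shaded protocol epochs."""
    ax = _axes(ax)
    ax.plot(result.time_s, result.mean_ca(), lw=1.0, color="k")
    shade = {"inhibition": "0.85", "recovery": "0.95"}
    for name, (t0, t1) in result.epochs.items():
        if name in shade:
            ax.axvspan(t0, t1, color=shade[name], zorder=0)
            ax.text(0.5 * (t0 + t1), ax.get_ylim()[1], name,
                    ha="center", va="top", fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean [Ca²⁺]$_i$ (µM)")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax


def plot_raster(raster: RasterData, ax=None, path=None):
    """Binary activity raster: one row per cell, black where active."""
    ax = _axes(ax)
    ax.imshow(raster.active.T, aspect="auto", cmap="Greys",
              interpolation="nearest",
              extent=(raster.time_s[0], raster.time_s[-1],
                      raster.n_cells, 0))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax


def plot_dose_response(responses: "dict[str, DoseResponse]", ax=None,
                       path=None):
    """Activity vs inhibited fraction with the fitted logistics."""
    ax = _axes(ax)
    for label, dr in responses.items():
        x = dr.fractions_pct
        if dr.sem is not None and np.any(dr.sem > 0):
            ax.errorbar(x, dr.activity_pct, yerr=dr.sem, fmt="o",
                        label=f"{label} (x0={dr.x0:.2f}%)")
        else:
            ax.plot(x, dr.activity_pct, "o",
                    label=f"{label} (x0={dr.x0:.2f}%)")
        grid = np.linspace(0, max(x), 200)
        ax.plot(grid, logistic_decreasing(grid, dr.x0, dr.k), "-", lw=1)
    ax.set_xlabel("cells inhibited (% of islet)")
    ax.set_ylabel("Ca²⁺ activity (% of no inhibition)")
    ax.legend(fontsize=8)
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
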
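"""Diagnostic figures: ratemap pairs, classification rasters, phase histograms."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .preprocess import TemplateSet

__all__ = ["plot_ratemap_pair", "plot_classification_raster", "plot_phase_histograms"]

_CLASS_COLORS = {"ICPV": "tab:blue", "OCPV": "tab:red", "MPV": "tab:purple"}


def plot_ratemap_pair(templates: TemplateSet, cell_id, axes=None):
    """Side-by-side smoothed template maps of one cell in both environments."""
    i = templates.cell_ids.index(cell_id)
    if axes is None:
        _, axes = plt.subplots(1, len(templates.envs), figsize=(3 * len(templates.envs), 3))
    vmax = max(np.nanmax(templates.rates[e][i]) for e in templates.envs) or 1.0
    for ax, env in zip(np.atleast_1d(axes), templates.envs):
        m = templates.rates[env][i]
        im = ax.imshow(m, origin="lower", vmin=0, vmax=vmax, cmap="viridis")
        ax.set_title(f"cell {cell_id} — {env}")
        ax.set_xticks([]), ax.set_yticks([])
    plt.colorbar(im, ax=np.atleast_1d(axes)[-1], label="Hz", fraction=0.046)
    return np.atleast_1d(axes)[0].figure


def plot_classification_raster(labels: pd.DataFrame, ax=None):
    """Event times of the classified theta cycles, one row per pattern class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.2))
    for row, lab in enumerate(("ICPV", "MPV", "OCPV")):
        t = labels.loc[labels["label"] == lab, "t_start"]
        ax.vlines(t, row + 0.1, row + 0.9, color=_CLASS_COLORS[lab], lw=0.8)
    ax.set_yticks([0.5, 1.5, 2.5], ["ICPV", "MPV", "OCPV"])
    ax.set_xlabel("time (s)")
    ax.set_ylim(0, 3)
    return ax.figure


def plot_phase_histograms(spike_phases: pd.DataFrame, n_bins: int = 24):
    """Polar spike-phase histograms per pattern class (0 deg = cycle border)."""
    groups = [g for g in ("ICPV", "OCPV", "MPV-in", "MPV-out") if (spike_phases["group"] == g).any()]
    fig, axes = plt.subplots(
        1, max(len(groups), 1), subplot_kw={"projection": "polar"}, figsize=(3 * len(groups), 3)
    )
    for ax, g in zip(np.atleast_1d(axes), groups):
        ph = np.radians(spike_phases.loc[spike_phases["group"] == g, "phase_deg"])
        counts, edges = np.histogram(ph, bins=n_bins, range=(0, 2 * np.pi))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", alpha=0.7)
        mean = np.angle(np.mean(np.exp(1j * ph)))
        ax.plot([mean, mean], [0, counts.max() or 1], color="red", lw=2)
        ax.set_title(g, pad=12)
        ax.set_yticklabels([])
    fig.tight_layout()
    return fig
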
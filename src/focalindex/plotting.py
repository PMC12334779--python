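"""Minimal plotting helpers for reports and profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .profiles import HUProfile
from .regions import CC_BANDS, GRAV_BANDS, roi_id


def plot_profile_overlay(va: HUProfile, dd: HUProfile, fi_value: float | None = None, ax=None):
    """Superimpose the ventral-apical and dorsal-diaphragmatic curves; the
    area where they do not overlap is the focal index (divided by 100)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    centers = (va.bin_edges[:-1] + va.bin_edges[1:]) / 2
    ax.plot(centers, va.freq_percent, color="tab:cyan", label="ventral-apical")
    ax.plot(centers, dd.freq_percent, color="tab:pink", label="dorsal-diaphragmatic")
    ax.fill_between(
        centers, va.freq_percent, dd.freq_percent, color="0.8", label="non-overlap"
    )
    ax.set_xlabel("HU")
    ax.set_ylabel("% of ROI voxels per 5-HU bin")
    if fi_value is not None:
        ax.set_title(f"focal index = {fi_value:.1f}")
    ax.legend(frameon=False)
    return ax


def plot_region_grid(profiles: dict[str, HUProfile]):
    """3x3 grid of regional HU profiles (rows: gravitational bands,
    columns: craniocaudal bands)."""
    fig, axes = plt.subplots(3, 3, figsize=(10, 8), sharex=True, sharey=True)
    for i, g in enumerate(GRAV_BANDS):
        for j, c in enumerate(CC_BANDS):
            p = profiles[roi_id(g, c)]
            centers = (p.bin_edges[:-1] + p.bin_edges[1:]) / 2
            axes[i, j].plot(centers, p.freq_percent, color="k", lw=1)
            axes[i, j].set_title(f"{g} {c}", fontsize=9)
    fig.supxlabel("HU")
    fig.supylabel("% of ROI voxels")
    fig.tight_layout()
    return fig
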
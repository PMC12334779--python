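"""Regional HU distribution profiles and aeration compartments.

A profile is a histogram of the clipped HU values of one ROI: 220 bins of
width 5 HU spanning [-1000, +100], expressed as the percentage of the ROI's
voxels per bin. Bins are half-open ``[edge, edge + 5)`` except the last,
``[95, 100]``, so the clipped domain is covered exactly once.

Two aeration compartments summarise a profile: the hyperaerated fraction
(HU in [-1000, -800)) and the non-aerated fraction (HU in [-100, +100]).
The poorly- and normally-aerated compartments (boundaries -500 and -800 HU)
are available as optional extras.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .io import HU_MAX, HU_MIN

BIN_WIDTH = 5.0
#: 221 edges from -1000 to +100; 220 bins.
BIN_EDGES = np.arange(HU_MIN, HU_MAX + BIN_WIDTH, BIN_WIDTH)
N_BINS = len(BIN_EDGES) - 1

#: Default compartment boundaries (HU). The interior boundaries are half-open
#: on the dense side: hyperaerated is [-1000, -800), non-aerated [-100, +100].
HYPER_RANGE = (-1000.0, -800.0)
NONAER_RANGE = (-100.0, 100.0)
POORLY_RANGE = (-500.0, -100.0)
NORMALLY_RANGE = (-800.0, -500.0)


@dataclass(frozen=True)
class HUProfile:
    """Normalised HU histogram of one region of interest."""

    freq_percent: np.ndarray  # length N_BINS, sums to 100 when non-empty
    n_voxels: int
    roi_id: str
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES)

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    @property
    def probabilities(self) -> np.ndarray:
        """Per-bin probability masses (freq_percent / 100)."""
        return self.freq_percent / 100.0

    def same_grid(self, other: "HUProfile") -> bool:
        return self.bin_edges.shape == other.bin_edges.shape and bool(
            np.allclose(self.bin_edges, other.bin_edges)
        )


@dataclass(frozen=True)
class AerationSummary:
    """Percentage of ROI voxels in the two named aeration compartments.

    Both fields are NaN for an empty ROI — explicitly undefined, never a
    silent zero.
    """

    roi_id: str
    hyper_percent: float
    nonaer_percent: float

    @property
    def is_defined(self) -> bool:
        return not (np.isnan(self.hyper_percent) or np.isnan(self.nonaer_percent))


def compute_profile(hu_values: np.ndarray, roi_id: str = "") -> HUProfile:
    """Histogram a collection of clipped HU values into an :class:`HUProfile`.

    Values must already lie in [-1000, +100] (run :func:`focalindex.io.clip_hu`
    first); anything outside raises :class:`DomainError`. An empty collection
    yields an all-zero profile flagged empty.
    """
    values = np.asarray(hu_values, dtype=float).ravel()
    if values.size == 0:
        return HUProfile(freq_percent=np.zeros(N_BINS), n_voxels=0, roi_id=roi_id)
    if values.min() < HU_MIN or values.max() > HU_MAX:
        raise DomainError(
            f"HU values outside [{HU_MIN:g}, {HU_MAX:g}]; apply clip_hu before profiling"
        )
    counts, _ = np.histogram(values, bins=BIN_EDGES)
    return HUProfile(
        freq_percent=counts * (100.0 / values.size),
        n_voxels=int(values.size),
        roi_id=roi_id,
    )


def _range_percent(profile: HUProfile, lo: float, hi: float) -> float:
    """Sum of bins whose left edge lies in [lo, hi)."""
    left = profile.bin_edges[:-1]
    return float(profile.freq_percent[(left >= lo - 1e-9) & (left < hi - 1e-9)].sum())


def aeration_summary(profile: HUProfile) -> AerationSummary:
    """Hyperaerated and non-aerated percentages of a profile."""
    if profile.is_empty:
        return AerationSummary(roi_id=profile.roi_id, hyper_percent=np.nan, nonaer_percent=np.nan)
    return AerationSummary(
        roi_id=profile.roi_id,
        hyper_percent=_range_percent(profile, *HYPER_RANGE),
        nonaer_percent=_range_percent(profile, *NONAER_RANGE),
    )


def compartment_percent(profile: HUProfile, lo: float, hi: float) -> float:
    """Percentage of voxels in an arbitrary compartment [lo, hi).

    Provided for the optional poorly-/normally-aerated extras; ``lo`` and
    ``hi`` should sit on bin edges (multiples of 5 HU).
    """
    if profile.is_empty:
        return float("nan")
    return _range_percent(profile, lo, hi)
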
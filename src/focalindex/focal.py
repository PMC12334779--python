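"""The focal index: non-overlapping area between two regional HU profiles.

The ventral-apical (VA) and dorsal-diaphragmatic (DD) regions are the two
ends of the transpulmonary-pressure gradient; in focal lung injury their HU
distributions separate, in diffuse injury they coincide. With each region's
histogram normalised to a probability vector ``p`` over the 5-HU bins, the
index is

    FI = 100 * sum_b |p_VA(b) - p_DD(b)| = 200 * TV(p_VA, p_DD),

twice the total-variation distance on a 0-200 scale: 0 means the curves
overlap completely (homogeneous aeration), 200 means they do not overlap at
all (maximal focality). The discrete bin sum is exactly the integral of the
piecewise-constant densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EmptyProfileError, GridMismatchError
from .profiles import HUProfile


@dataclass(frozen=True)
class FocalIndexResult:
    """Focal index of one VA/DD profile pair."""

    value: float  # 0..200
    va_profile: HUProfile
    dd_profile: HUProfile

    @property
    def overlap_percent(self) -> float:
        """Overlapping probability mass of the two curves, in percent."""
        return 100.0 - self.value / 2.0


def focal_index(va: HUProfile, dd: HUProfile) -> FocalIndexResult:
    """Compute the focal index between two non-empty profiles on one grid.

    Symmetric in its arguments; the result lies in [0, 200].
    """
    for p in (va, dd):
        if p.is_empty:
            raise EmptyProfileError(
                f"focal index undefined: ROI {p.roi_id or '<unnamed>'} has no voxels"
            )
    if not va.same_grid(dd):
        raise GridMismatchError("profiles are not on the same HU bin grid")
    value = float(np.abs(va.probabilities - dd.probabilities).sum() * 100.0)
    return FocalIndexResult(value=min(value, 200.0), va_profile=va, dd_profile=dd)


def pairwise_focal_matrix(
    profiles: Sequence[HUProfile] | Mapping[str, HUProfile],
) -> np.ndarray:
    """Symmetric matrix of focal indices between every pair of profiles.

    A diagnostic generalisation of the VA-DD score. Entries involving an
    empty profile are NaN (undefined), the diagonal is 0 for non-empty
    profiles.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    n = len(profiles)
    matrix = np.zeros((n, n))
    for i in range(n):
        if profiles[i].is_empty:
            matrix[i, :] = matrix[:, i] = np.nan
    for i in range(n):
        for j in range(i + 1, n):
            if profiles[i].is_empty or profiles[j].is_empty:
                continue
            matrix[i, j] = matrix[j, i] = focal_index(profiles[i], profiles[j]).value
    return matrix
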
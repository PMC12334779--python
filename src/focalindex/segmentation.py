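"""Fallback semiautomatic lung segmentation.

An externally supplied mask always takes precedence; this module exists so a
scan can be processed end-to-end without one. The recipe is the standard
quantitative-CT one: threshold below an air/parenchyma cutoff, drop the
exterior air (any low-density component touching the in-plane image border),
drop small components, and morphologically close the result so dense
consolidations enclosed by aerated lung are re-included. Optional seed points
provide the "semiautomatic" interaction: when given, only components
containing a seed are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, SegmentationFailedError
from .io import CTVolume, LungMask


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the threshold-and-components segmentation.

    air_threshold:
        HU below which a voxel is a lung/air candidate. Must lie in
        (-1000, 0); -300 HU separates parenchyma from soft tissue.
    min_component_volume:
        Smallest connected component kept, in ml; removes airways fragments
        and noise specks.
    closing_radius:
        Radius (mm) of the morphological closing that re-includes enclosed
        consolidated tissue; 0 disables closing.
    seed_points:
        Optional voxel coordinates; when present, only components containing
        at least one seed survive.
    """

    air_threshold: float = -300.0
    min_component_volume: float = 30.0
    closing_radius: float = 3.0
    seed_points: list[tuple[int, int, int]] | None = None

    def __post_init__(self) -> None:
        if not (-1000.0 < self.air_threshold < 0.0):
            raise ConfigurationError(
                f"air_threshold must lie in (-1000, 0) HU, got {self.air_threshold}"
            )
        if self.closing_radius < 0:
            raise ConfigurationError("closing_radius must be >= 0")
        if self.min_component_volume <= 0:
            raise ConfigurationError("min_component_volume must be > 0")


def _ellipsoid_footprint(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    radii = np.maximum(1, np.round(radius_mm / np.asarray(spacing)).astype(int))
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    return sum((g / r) ** 2 for g, r in zip(grids, radii)) <= 1.0


def segment_lungs(volume: CTVolume, params: SegmentationParams | None = None) -> LungMask:
    """Segment the lung parenchyma of a canonical CT volume.

    Raises :class:`SegmentationFailedError` with a diagnostic when the result
    is empty (threshold too low, lungs outside the field of view, or seeds
    missing every candidate component).
    """
    params = params or SegmentationParams()
    candidate = volume.voxels < params.air_threshold
    if not candidate.any():
        raise SegmentationFailedError(
            f"no voxels below {params.air_threshold} HU; threshold too low or "
            "lungs outside the field of view"
        )

    labels, n_comp = ndimage.label(candidate)

    # Exterior air reaches the in-plane (axial) image border.
    border = np.zeros_like(candidate)
    border[:, (0, -1), :] = True
    border[:, :, (0, -1)] = True
    border_labels = np.unique(labels[border & candidate])
    keep = np.ones(n_comp + 1, dtype=bool)
    keep[0] = False
    keep[border_labels] = False

    min_voxels = params.min_component_volume * 1000.0 / np.prod(volume.spacing)
    counts = np.bincount(labels.ravel(), minlength=n_comp + 1)
    keep &= counts >= min_voxels

    if params.seed_points is not None:
        seeded = np.zeros(n_comp + 1, dtype=bool)
        for seed in params.seed_points:
            seeded[labels[tuple(seed)]] = True
        seeded[0] = False
        keep &= seeded

    mask = keep[labels]
    if not mask.any():
        raise SegmentationFailedError(
            "all candidate components rejected (border-connected, below "
            f"{params.min_component_volume} ml, or not containing a seed)"
        )

    if params.closing_radius > 0:
        footprint = _ellipsoid_footprint(params.closing_radius, volume.spacing)
        mask = ndimage.binary_closing(mask, structure=footprint)

    return LungMask(labels=mask)
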
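"""Slice selection and the nine-region (craniocaudal x gravitational) partition.

Eighteen axial slices are picked evenly over the lung's craniocaudal extent
and split into three equal groups (apical, mediastinal, diaphragmatic).
Within each selected slice the lung's ventral-to-dorsal extent is divided
into three equal-length bands (ventral, medial, dorsal), measured in
physical mm. The product gives nine three-dimensional regions of interest;
every in-mask voxel on a selected slice belongs to exactly one of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InsufficientExtentError, PartitionError
from .io import CTVolume, LungMask

CC_BANDS = ("apical", "mediastinal", "diaphragmatic")
GRAV_BANDS = ("ventral", "medial", "dorsal")

#: The nine ROI identifiers, in integer-code order 1..9 (craniocaudal-major).
ROI_IDS = tuple(f"{g}-{c}" for c in CC_BANDS for g in GRAV_BANDS)

VENTRAL_APICAL = "ventral-apical"
DORSAL_DIAPHRAGMATIC = "dorsal-diaphragmatic"


def roi_id(grav_band: str, cc_band: str) -> str:
    return f"{grav_band}-{cc_band}"


def roi_code(roi: str) -> int:
    """Integer label (1..9) of an ROI id, craniocaudal-major (VA=1, DD=9)."""
    return ROI_IDS.index(roi) + 1


@dataclass(frozen=True)
class SliceSelection:
    """The analysed axial slices, ordered cranial to caudal."""

    indices: tuple[int, ...]
    slice_thickness: float  # mm, native axis-0 spacing

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise PartitionError("slice indices must be strictly increasing")


@dataclass(frozen=True)
class RegionMap:
    """Voxel-to-ROI assignment on the selected slices.

    ``roi_labels`` is an integer volume congruent with the CT grid: 0 outside
    the analysed voxels, otherwise the ROI code 1..9 (see :func:`roi_code`).
    """

    selection: SliceSelection
    cc_band: tuple[str, ...]  # per selected slice
    roi_labels: np.ndarray
    roi_voxel_counts: dict[str, int]
    warnings: tuple[str, ...] = ()

    def voxels_of(self, roi: str, volume: CTVolume) -> np.ndarray:
        """HU values of the voxels assigned to ``roi``."""
        return volume.voxels[self.roi_labels == roi_code(roi)]


def lung_slice_range(mask: LungMask) -> tuple[int, int]:
    """First and last axial slice containing lung, inclusive."""
    has_lung = mask.labels.any(axis=(1, 2))
    if not has_lung.any():
        raise InsufficientExtentError("mask contains no lung voxels")
    idx = np.flatnonzero(has_lung)
    return int(idx[0]), int(idx[-1])


def select_slices(volume: CTVolume, mask: LungMask, n_slices: int = 18) -> SliceSelection:
    """Pick ``n_slices`` evenly spaced slices covering the lung extent.

    Ideal positions are a linspace from the first to the last lung-containing
    slice, rounded half-away-from-cranial; a collision shifts caudally to the
    next free slice (with lung extent >= n_slices rounding alone cannot
    collide, so this is a safety net).
    """
    mask.check_congruent(volume)
    first, last = lung_slice_range(mask)
    extent = last - first + 1
    if extent < n_slices:
        raise InsufficientExtentError(
            f"lung spans {extent} slices, fewer than the {n_slices} requested"
        )
    ideal = np.linspace(first, last, n_slices)
    rounded = np.floor(ideal + 0.5).astype(int)
    indices: list[int] = []
    for r in rounded:
        r = max(r, indices[-1] + 1) if indices else r
        indices.append(int(r))
    if indices[-1] > last:
        raise PartitionError("slice collision resolution exceeded the lung extent")
    return SliceSelection(indices=tuple(indices), slice_thickness=volume.spacing[0])


def assign_cc_bands(selection: SliceSelection) -> tuple[str, ...]:
    """Label the selected slices apical / mediastinal / diaphragmatic in thirds."""
    n = len(selection.indices)
    if n == 0 or n % 3:
        raise PartitionError(f"cannot split {n} slices into three equal craniocaudal groups")
    per = n // 3
    return tuple(band for band in CC_BANDS for _ in range(per))


def grav_band_of_rows(rows: np.ndarray, row_min: int, row_max: int) -> np.ndarray:
    """Gravitational band index (0 ventral, 1 medial, 2 dorsal) of AP rows.

    The extent [row_min, row_max] (voxel cells, inclusive) is divided into
    three equal-length intervals, half-open with the ventral edge closed, so
    a voxel exactly on a boundary falls in the more dorsal band.
    """
    n_rows = row_max - row_min + 1
    band = ((rows - row_min) * 3) // n_rows
    return np.minimum(band, 2).astype(int)


def assign_grav_bands(
    volume: CTVolume,
    mask: LungMask,
    selection: SliceSelection,
    extent_mode: str = "per-slice",
) -> np.ndarray:
    """Gravitational band of every in-mask voxel on the selected slices.

    Returns an int volume congruent with the grid: -1 where unassigned, else
    0/1/2 for ventral/medial/dorsal. With ``extent_mode="per-slice"`` the
    thirds follow the lung's anterior-posterior extent on each slice (the
    default); ``"global"`` uses one extent over all selected slices. Band
    boundaries are equal thirds of the physical (mm) extent; with uniform
    in-plane spacing this reduces to thirds of the row range.
    """
    if extent_mode not in ("per-slice", "global"):
        raise ConfigurationError(f"unknown gravitational extent mode {extent_mode!r}")
    mask.check_congruent(volume)
    bands = np.full(volume.shape, -1, dtype=np.int8)

    if extent_mode == "global":
        rows_any = mask.labels[list(selection.indices)].any(axis=(0, 2))
        if not rows_any.any():
            return bands
        gmin, gmax = int(np.flatnonzero(rows_any)[0]), int(np.flatnonzero(rows_any)[-1])

    for z in selection.indices:
        slice_mask = mask.labels[z]
        if not slice_mask.any():
            warnings.warn(f"selected slice {z} contains no lung voxels; skipped", stacklevel=2)
            continue
        rows, cols = np.nonzero(slice_mask)
        if extent_mode == "per-slice":
            rmin, rmax = int(rows.min()), int(rows.max())
        else:
            rmin, rmax = gmin, gmax
        bands[z, rows, cols] = grav_band_of_rows(rows, rmin, rmax)
    return bands


def build_region_map(
    volume: CTVolume,
    mask: LungMask,
    selection: SliceSelection | None = None,
    n_slices: int = 18,
    extent_mode: str = "per-slice",
) -> RegionMap:
    """Compose craniocaudal and gravitational bands into the nine-ROI map."""
    if selection is None:
        selection = select_slices(volume, mask, n_slices=n_slices)
    cc = assign_cc_bands(selection)
    grav = assign_grav_bands(volume, mask, selection, extent_mode=extent_mode)

    roi_labels = np.zeros(volume.shape, dtype=np.int8)
    for z, cc_band in zip(selection.indices, cc):
        cc_idx = CC_BANDS.index(cc_band)
        assigned = grav[z] >= 0
        # code 1..9, craniocaudal-major: code = 3*cc + grav + 1
        roi_labels[z][assigned] = 3 * cc_idx + grav[z][assigned] + 1

    counts = np.bincount(roi_labels.ravel(), minlength=10)
    roi_voxel_counts = {roi: int(counts[i + 1]) for i, roi in enumerate(ROI_IDS)}
    notes = tuple(f"ROI {roi} is empty" for roi, n in roi_voxel_counts.items() if n == 0)

    n_analysed = int(mask.labels[list(selection.indices)].sum())
    assert sum(roi_voxel_counts.values()) == n_analysed, "ROI partition lost voxels"
    return RegionMap(
        selection=selection,
        cc_band=cc,
        roi_labels=roi_labels,
        roi_voxel_counts=roi_voxel_counts,
        warnings=notes,
    )
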
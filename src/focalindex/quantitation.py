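"""Lung gas volume and tissue weight from voxel HU values.

Standard quantitative-CT relations: a voxel's HU is the volume-weighted mix
of gas (-1000 HU) and tissue (~water, 0 HU), so

    gas fraction    = max(0, -HU / 1000)          (HU in [-1000, 0]),
    tissue density  = (HU + 1000) / 1000  g/ml,

giving per-voxel gas volume ``v * gas_fraction`` and weight
``v * (1 + HU/1000)`` for voxel volume ``v`` ml. Slightly-positive HU
(0, +100] maps to gas 0 and density just above water. Per-slice quantities
at the analysed slices are extended to the whole lung by linear
interpolation between consecutive analysed slices (zero-order hold beyond
the outermost ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientSupportError
from .io import HU_MAX, HU_MIN, CTVolume, LungMask
from .regions import SliceSelection, lung_slice_range


@dataclass(frozen=True)
class SliceQuantities:
    slice_index: int
    gas_ml: float
    weight_g: float
    analysed: bool


@dataclass(frozen=True)
class QuantitationResult:
    gas_volume_ml: float
    lung_weight_g: float
    per_slice: tuple[SliceQuantities, ...]
    method: str  # "analysed-slices-only" | "whole-lung-interpolated"


def voxel_fractions(hu: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gas and tissue volume fractions of clipped HU values; they sum to 1."""
    hu = np.asarray(hu, dtype=float)
    if np.any(hu < HU_MIN) or np.any(hu > HU_MAX):
        raise DomainError(f"HU outside [{HU_MIN:g}, {HU_MAX:g}]; apply clip_hu first")
    gas = np.maximum(0.0, -hu / 1000.0)
    return gas, 1.0 - gas


def slice_quantities(volume: CTVolume, mask: LungMask, slice_index: int) -> tuple[float, float]:
    """Gas (ml) and weight (g) of the in-mask voxels of one axial slice."""
    mask.check_congruent(volume)
    hu = volume.voxels[slice_index][mask.labels[slice_index]]
    if hu.size == 0:
        return 0.0, 0.0
    gas, _ = voxel_fractions(hu)
    v = volume.voxel_volume_ml
    gas_ml = float(v * gas.sum())
    weight_g = float(v * (1.0 + hu / 1000.0).sum())  # density (HU+1000)/1000 g/ml
    return gas_ml, weight_g


def analysed_slice_quantities(
    volume: CTVolume, mask: LungMask, selection: SliceSelection
) -> QuantitationResult:
    """Gas and weight summed over the analysed slices only."""
    per = tuple(
        SliceQuantities(z, *slice_quantities(volume, mask, z), analysed=True)
        for z in selection.indices
    )
    return QuantitationResult(
        gas_volume_ml=sum(s.gas_ml for s in per),
        lung_weight_g=sum(s.weight_g for s in per),
        per_slice=per,
        method="analysed-slices-only",
    )


def whole_lung_interpolate(
    per_slice: tuple[SliceQuantities, ...] | list[SliceQuantities],
    all_lung_slices: range | tuple[int, int],
) -> QuantitationResult:
    """Extend analysed per-slice quantities to every lung slice by linear
    interpolation; at analysed slices the interpolant equals the measurement.

    ``all_lung_slices`` is the inclusive (first, last) lung slice pair or an
    equivalent range. Beyond the outermost analysed slices the nearest
    measured value is held constant.
    """
    measured = sorted((s for s in per_slice if s.analysed), key=lambda s: s.slice_index)
    if len(measured) < 2:
        raise InsufficientSupportError(
            f"whole-lung interpolation needs >= 2 analysed slices, got {len(measured)}"
        )
    if isinstance(all_lung_slices, range):
        zs = np.asarray(all_lung_slices)
    else:
        first, last = all_lung_slices
        zs = np.arange(first, last + 1)
    xp = np.array([s.slice_index for s in measured], dtype=float)
    gas = np.interp(zs, xp, [s.gas_ml for s in measured])
    weight = np.interp(zs, xp, [s.weight_g for s in measured])
    analysed_set = {s.slice_index for s in measured}
    per = tuple(
        SliceQuantities(int(z), float(g), float(w), analysed=int(z) in analysed_set)
        for z, g, w in zip(zs, gas, weight)
    )
    return QuantitationResult(
        gas_volume_ml=float(gas.sum()),
        lung_weight_g=float(weight.sum()),
        per_slice=per,
        method="whole-lung-interpolated",
    )


def quantify(volume: CTVolume, mask: LungMask, selection: SliceSelection) -> QuantitationResult:
    """Analysed-slice quantities interpolated over the whole lung extent."""
    direct = analysed_slice_quantities(volume, mask, selection)
    return whole_lung_interpolate(direct.per_slice, lung_slice_range(mask))
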
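"""Reading, writing and canonicalising CT volumes and lung masks.

Volumes are held as HU arrays in a fixed anatomical order so that every
downstream operation can address the craniocaudal and gravitational axes by
array axis alone:

* axis 0 — cranial → caudal (index grows toward the diaphragm),
* axis 1 — ventral → dorsal (index grows toward the back; the gravitational
  axis for a supine acquisition),
* axis 2 — left → right.

NIfTI files are reoriented from their header affine with nibabel; DICOM
series are assembled from slice geometry and rescaled to HU. Orientation is
never guessed: a volume without usable orientation metadata is rejected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import nibabel as nib
from nibabel import orientations as nio

from .errors import CongruenceError, GeometryError, OrientationError, ReadError

#: HU value of pure gas and the densest parenchyma considered "lung".
HU_MIN = -1000.0
HU_MAX = 100.0

#: Anatomical direction each canonical array axis points toward.
CANONICAL_AXES = ("cranial-caudal", "ventral-dorsal", "left-right")

# nibabel axis codes for the canonical order: index grows toward
# Inferior (caudal), Posterior (dorsal), Right.
_CANONICAL_AXCODES = ("I", "P", "R")


@dataclass(frozen=True)
class CTVolume:
    """A canonically oriented HU voxel grid.

    Attributes
    ----------
    voxels:
        3-D float array of HU values, axes ordered per :data:`CANONICAL_AXES`.
    spacing:
        Physical voxel size in mm along each array axis ``(d0, d1, d2)``.
    axes:
        The anatomical labels of the array axes (always canonical).
    source_id:
        Opaque identifier of the originating scan.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = CANONICAL_AXES
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise GeometryError(f"expected a 3-D volume, got {self.voxels.ndim}-D")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if tuple(self.axes) != CANONICAL_AXES:
            raise OrientationError(f"volume not in canonical axis order: {self.axes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class LungMask:
    """Binary lung-parenchyma labels congruent with a :class:`CTVolume`."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=bool))
        if self.labels.ndim != 3:
            raise GeometryError(f"expected a 3-D mask, got {self.labels.ndim}-D")

    @property
    def voxel_count(self) -> int:
        return int(self.labels.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def check_congruent(self, volume: CTVolume) -> None:
        if self.shape != volume.shape:
            raise CongruenceError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


def _canonicalize(data: np.ndarray, affine: np.ndarray, source_id: str) -> CTVolume:
    """Reorder/flip ``data`` so its axes follow the canonical convention."""
    rzs = affine[:3, :3]
    if not np.all(np.isfinite(rzs)) or abs(np.linalg.det(rzs)) < 1e-12:
        raise OrientationError(
            f"{source_id}: degenerate or missing orientation matrix; refusing to guess"
        )
    current = nio.io_orientation(affine)
    target = nio.axcodes2ornt(_CANONICAL_AXCODES)
    transform = nio.ornt_transform(current, target)
    canonical = nio.apply_orientation(data, transform)
    new_affine = affine @ nio.inv_ornt_aff(transform, data.shape)
    spacing = tuple(float(s) for s in np.sqrt((new_affine[:3, :3] ** 2).sum(axis=0)))
    return CTVolume(
        voxels=np.ascontiguousarray(canonical),
        spacing=spacing,  # type: ignore[arg-type]
        source_id=source_id,
    )


def _canonical_affine(volume: CTVolume) -> np.ndarray:
    d0, d1, d2 = volume.spacing
    # index 0 grows toward Inferior (-S), 1 toward Posterior (-A), 2 toward Right.
    aff = np.zeros((4, 4))
    aff[2, 0] = -d0
    aff[1, 1] = -d1
    aff[0, 2] = d2
    aff[3, 3] = 1.0
    return aff


def load_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom_series"``; when omitted it is
    inferred (directories are treated as DICOM series).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ReadError(f"no such file or directory: {path}")
    if format is None:
        format = "dicom_series" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ReadError(f"unknown format {format!r}; expected 'nifti' or 'dicom_series'")


def _load_nifti(path: str) -> CTVolume:
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise ReadError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return _canonicalize(data, img.affine, source_id=os.path.basename(path))


def _load_dicom_series(path: str) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue  # skip non-DICOM files (DICOMDIR, reports)
        if hasattr(ds, "PixelData") and hasattr(ds, "ImagePositionPatient"):
            slices.append(ds)
    if not slices:
        raise ReadError(f"no readable DICOM image slices in {path}")

    ref = slices[0]
    iop = np.asarray([float(v) for v in ref.ImageOrientationPatient])
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    for ds in slices:
        if (ds.Rows, ds.Columns) != (ref.Rows, ref.Columns):
            raise GeometryError("DICOM series has inconsistent slice dimensions")
        if not np.allclose([float(v) for v in ds.ImageOrientationPatient], iop, atol=1e-4):
            raise GeometryError("DICOM series has inconsistent slice orientations")
        if not np.allclose(
            [float(v) for v in ds.PixelSpacing], [float(v) for v in ref.PixelSpacing], atol=1e-6
        ):
            raise GeometryError("DICOM series has inconsistent pixel spacing")

    slices.sort(key=lambda ds: float(np.dot(normal, [float(v) for v in ds.ImagePositionPatient])))
    positions = np.array([[float(v) for v in ds.ImagePositionPatient] for ds in slices])
    if len(slices) > 1:
        steps = np.diff(positions @ normal)
        if np.any(steps <= 0) or (np.ptp(steps) > 1e-3 * abs(steps.mean())):
            raise GeometryError("DICOM series slice positions are not uniformly spaced")

    hu = np.stack(
        [
            np.asarray(ds.pixel_array, dtype=np.float64) * float(getattr(ds, "RescaleSlope", 1.0))
            + float(getattr(ds, "RescaleIntercept", 0.0))
            for ds in slices
        ]
    )

    # Voxel (s, r, c) -> patient LPS; convert to RAS for nibabel orientation codes.
    row_spacing, col_spacing = (float(v) for v in ref.PixelSpacing)
    slice_step = (
        (positions[-1] - positions[0]) / (len(slices) - 1)
        if len(slices) > 1
        else normal * float(getattr(ref, "SliceThickness", 1.0))
    )
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = slice_step
    affine_lps[:3, 1] = col_dir * row_spacing
    affine_lps[:3, 2] = row_dir * col_spacing
    affine_lps[:3, 3] = positions[0]
    lps_to_ras = np.diag([-1.0, -1.0, 1.0, 1.0])
    return _canonicalize(hu, lps_to_ras @ affine_lps, source_id=os.path.basename(path))


def save_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a canonical volume as NIfTI; loading it back is a bit-exact round trip."""
    img = nib.Nifti1Image(volume.voxels, _canonical_affine(volume))
    nib.save(img, os.fspath(path))


def load_mask(path: str | os.PathLike, reference: CTVolume | None = None) -> LungMask:
    """Load a binary lung mask (NIfTI, values {0, 1}) on the reference grid."""
    vol = load_volume(path, format="nifti")
    values = np.unique(vol.voxels)
    if not np.all(np.isin(values, (0, 1))):
        raise ReadError(f"{path}: mask values must be 0/1, found {values[:5]}")
    mask = LungMask(labels=vol.voxels > 0.5)
    if reference is not None:
        mask.check_congruent(reference)
        if not np.allclose(vol.spacing, reference.spacing, rtol=1e-4):
            raise CongruenceError(
                f"mask spacing {vol.spacing} does not match volume spacing {reference.spacing}"
            )
    return mask


def save_mask(mask: LungMask, spacing: tuple[float, float, float], path: str | os.PathLike) -> None:
    vol = CTVolume(voxels=mask.labels.astype(np.uint8), spacing=spacing, source_id="mask")
    img = nib.Nifti1Image(vol.voxels, _canonical_affine(vol))
    nib.save(img, os.fspath(path))


def clip_hu(volume: CTVolume, mask: LungMask) -> CTVolume:
    """Clip in-mask voxels to the lung HU domain [-1000, +100].

    Out-of-range values are clipped rather than dropped so the percentage
    histograms keep the full mask voxel count as denominator. Voxels outside
    the mask are untouched; the input volume is not modified.
    """
    mask.check_congruent(volume)
    voxels = volume.voxels.copy()
    voxels[mask.labels] = np.clip(voxels[mask.labels], HU_MIN, HU_MAX)
    return replace(volume, voxels=voxels)
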
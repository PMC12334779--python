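"""Synthetic thoracic CT phantoms with analytically known focal index.

A phantom is two lung-shaped ellipsoids of HU noise embedded in a soft-tissue
body (+40 HU) on an air background. Each of the nine nominal regions draws
its voxels independently from a region-specific mixture of truncated normals
over [-1000, +100]. A single focality parameter ``phi`` blends a homogeneous
law (``phi = 0``: every region identical, focal index 0) into a fully
separated one (``phi = 1``: ventral-apical purely aerated, dorsal-
diaphragmatic purely consolidated with disjoint HU support, focal index 200).
Region severity grows linearly toward the dorsal-diaphragmatic corner, so the
analytic focal index is ``200 * phi * TV(aerated, consolidated)`` — exactly
``200 * phi`` for the default disjoint-support laws, nondecreasing in phi.

Region labels are assigned with the same partition operators the measurement
pipeline uses (slice selection, craniocaudal sixths, per-slice gravitational
thirds), so the empirical profile of each measured ROI is an i.i.d. sample
from its generating law and recovery error is pure binomial sampling noise.

The default mixture components are deliberately narrow peaks (SD 12 HU): the
sharper the generating histograms, the smaller the sampling noise of the
empirical focal index at a given voxel count, which keeps recovery error
well below the index resolution being validated. Real ARDS profiles are
broader; see the methods note for what this does and does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, GeometryError
from .io import HU_MAX, HU_MIN, CTVolume, LungMask
from .profiles import BIN_EDGES, BIN_WIDTH
from .regions import (
    CC_BANDS,
    GRAV_BANDS,
    ROI_IDS,
    assign_cc_bands,
    grav_band_of_rows,
    roi_id,
    select_slices,
)

BODY_HU = 40.0
BACKGROUND_HU = -1000.0


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [lo, hi] within the lung HU domain."""

    mean: float
    sd: float
    lo: float = HU_MIN
    hi: float = HU_MAX

    def __post_init__(self) -> None:
        if not (HU_MIN <= self.lo < self.hi <= HU_MAX):
            raise ConfigurationError(
                f"truncation [{self.lo}, {self.hi}] must lie within [{HU_MIN:g}, {HU_MAX:g}]"
            )
        if self.sd <= 0:
            raise ConfigurationError("component sd must be positive")
        if self._mass() < 1e-12:
            raise ConfigurationError(
                f"component N({self.mean}, {self.sd}) has no mass in [{self.lo}, {self.hi}]"
            )

    def _ab(self) -> tuple[float, float]:
        return (self.lo - self.mean) / self.sd, (self.hi - self.mean) / self.sd

    def _mass(self) -> float:
        return float(
            sps.norm.cdf(self.hi, self.mean, self.sd) - sps.norm.cdf(self.lo, self.mean, self.sd)
        )

    def cdf(self, x: np.ndarray) -> np.ndarray:
        a, b = self._ab()
        return sps.truncnorm.cdf(x, a, b, loc=self.mean, scale=self.sd)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        a, b = self._ab()
        return sps.truncnorm.pdf(x, a, b, loc=self.mean, scale=self.sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a, b = self._ab()
        return sps.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


@dataclass(frozen=True)
class MixtureLaw:
    """Weighted mixture of truncated normals; a region's HU distribution."""

    components: tuple[TruncatedNormal, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights) or not self.components:
            raise ConfigurationError("mixture needs matching, non-empty components and weights")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"mixture weights must be nonnegative and sum to 1, got {w}")

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return sum(w * c.cdf(x) for w, c in zip(self.weights, self.components))

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return sum(w * c.pdf(x) for w, c in zip(self.weights, self.components))

    def bin_masses(self, edges: np.ndarray) -> np.ndarray:
        """Exact probability mass per histogram bin (CDF differences)."""
        return np.diff(self.cdf(np.asarray(edges, dtype=float)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        counts = rng.multinomial(n, self.weights)
        parts = [c.sample(k, rng) for c, k in zip(self.components, counts) if k > 0]
        values = np.concatenate(parts) if parts else np.empty(0)
        return rng.permutation(values)

    def mixed_with(self, other: "MixtureLaw", weight_other: float) -> "MixtureLaw":
        if not 0.0 <= weight_other <= 1.0:
            raise ConfigurationError("mixing weight must lie in [0, 1]")
        if weight_other == 0.0:
            return self
        if weight_other == 1.0:
            return other
        return MixtureLaw(
            components=self.components + other.components,
            weights=tuple((1 - weight_other) * w for w in self.weights)
            + tuple(weight_other * w for w in other.weights),
        )


#: Well-aerated parenchyma: a narrow peak at -850 HU, support capped at -400.
AERATED_LAW = MixtureLaw((TruncatedNormal(-850.0, 12.0, -1000.0, -400.0),), (1.0,))
#: Consolidated tissue: a narrow peak at +30 HU, support starting at -150.
CONSOLIDATED_LAW = MixtureLaw((TruncatedNormal(30.0, 12.0, -150.0, 100.0),), (1.0,))


def region_severity(grav_band: str, cc_band: str) -> float:
    """Consolidation severity in [0, 1]: 0 at ventral-apical, 1 at
    dorsal-diaphragmatic, linear in the band indices."""
    return (GRAV_BANDS.index(grav_band) + CC_BANDS.index(cc_band)) / 4.0


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid; centre and semi-axes in mm (canonical axes)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise GeometryError("ellipsoid semi-axes must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic scan; one seed determines it exactly."""

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.5, 1.0, 1.0)
    ellipsoids: tuple[Ellipsoid, ...] = ()
    aerated_law: MixtureLaw = AERATED_LAW
    consolidated_law: MixtureLaw = CONSOLIDATED_LAW
    phi: float = 0.5
    noise_sd: float = 0.0
    n_slices: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ConfigurationError(f"phi must lie in [0, 1], got {self.phi}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def region_law(self, roi: str) -> MixtureLaw:
        grav_band, cc_band = roi.split("-", 1)
        return self.aerated_law.mixed_with(
            self.consolidated_law, self.phi * region_severity(grav_band, cc_band)
        )


def default_config(
    phi: float = 0.5,
    seed: int = 0,
    target_roi_voxels: int = 10_000,
    noise_sd: float = 0.0,
) -> PhantomConfig:
    """A two-lung phantom sized so the smallest ROI (ventral-apical /
    dorsal-diaphragmatic) holds at least ``target_roi_voxels`` voxels.

    The lungs span exactly 18 axial slices so slice selection covers every
    lung slice. In-plane semi-axes are scaled from the analytic minimum-ROI
    voxel count of an ellipsoid partitioned into craniocaudal sixths and
    per-slice gravitational thirds.
    """
    dz, dy, dx = 1.5, 1.0, 1.0
    nz = 20
    cz_vox = 8.7  # lung occupies slices 1..18 around centre 9.5
    # Minimum ROI count ~= 2 lungs * pi*a*b * (apical-sixth area factor) *
    # (outer gravitational third of an ellipse) with ~5% slack.
    u = (np.arange(1, 7) - 9.5) / cz_vox
    apical_factor = float((1.0 - u**2).sum())  # ~2.92 of 6 slices
    outer_third = (math.acos(1.0 / 3.0) - math.sqrt(8.0) / 9.0) / math.pi  # ~0.2918
    ab = 1.05 * target_roi_voxels / (2.0 * math.pi * apical_factor * outer_third)
    aspect = 2.0  # left-right semi-axis twice the anterior-posterior one
    a = math.sqrt(ab / aspect)  # AP semi-axis, voxels
    b = aspect * a  # LR semi-axis, voxels
    ny = int(2 * a) + 10
    nx = int(4 * b) + 16
    cy = ny / 2.0
    lungs = (
        Ellipsoid(center=(9.5 * dz, cy * dy, (nx * 0.25 + 1) * dx), semi_axes=(cz_vox * dz, a * dy, b * dx)),
        Ellipsoid(center=(9.5 * dz, cy * dy, (nx * 0.75 - 1) * dx), semi_axes=(cz_vox * dz, a * dy, b * dx)),
    )
    return PhantomConfig(
        grid_shape=(nz, ny, nx),
        spacing=(dz, dy, dx),
        ellipsoids=lungs,
        phi=phi,
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth shipped with a generated phantom."""

    mask: LungMask
    region_laws: dict[str, MixtureLaw]
    analytic_fi: float
    roi_labels: np.ndarray  # generating ROI code per voxel (0 outside)


def _fine_bin_masses(law: MixtureLaw, noise_sd: float) -> np.ndarray:
    """Probability mass per 5-HU bin, via a 1-HU grid; with measurement noise
    the fine masses are convolved with the noise kernel and the spill beyond
    the domain is clipped back onto the edge bins, mirroring clip_hu."""
    if noise_sd == 0.0:
        fine_edges = np.arange(HU_MIN, HU_MAX + 1.0)
    else:
        pad = float(np.ceil(8.0 * noise_sd))
        fine_edges = np.arange(HU_MIN - pad, HU_MAX + pad + 1.0)
    masses = law.bin_masses(fine_edges)
    if noise_sd > 0.0:
        half = int(np.ceil(6.0 * noise_sd))
        kernel_edges = np.arange(-half, half + 2) - 0.5  # cells centred on -half..half
        kernel = np.diff(sps.norm.cdf(kernel_edges, 0, noise_sd))
        kernel[0] += sps.norm.cdf(kernel_edges[0], 0, noise_sd)
        kernel[-1] += sps.norm.sf(kernel_edges[-1], 0, noise_sd)
        masses = np.convolve(masses, kernel, mode="same")  # odd kernel, centred
        centers = (fine_edges[:-1] + fine_edges[1:]) / 2.0
        inside = (centers > HU_MIN) & (centers < HU_MAX)
        clipped = np.zeros(int(HU_MAX - HU_MIN))
        lo_spill = masses[centers <= HU_MIN].sum()
        hi_spill = masses[centers >= HU_MAX].sum()
        clipped[:] = masses[inside]
        clipped[0] += lo_spill
        clipped[-1] += hi_spill
        masses = clipped
    per_bin = masses.reshape(len(BIN_EDGES) - 1, int(BIN_WIDTH)).sum(axis=1)
    total = per_bin.sum()
    if total < 1e-12:
        raise ConfigurationError("law has no mass in the HU domain")
    return per_bin / total


def analytic_focal_index(law_va: MixtureLaw, law_dd: MixtureLaw, noise_sd: float = 0.0) -> float:
    """Ground-truth focal index between two generating laws on the 5-HU grid."""
    p_va = _fine_bin_masses(law_va, noise_sd)
    p_dd = _fine_bin_masses(law_dd, noise_sd)
    return float(np.abs(p_va - p_dd).sum() * 100.0)


def _ellipsoid_mask(config: PhantomConfig, ell: Ellipsoid) -> np.ndarray:
    nz, ny, nx = config.grid_shape
    dz, dy, dx = config.spacing
    z = (np.arange(nz) * dz - ell.center[0]) / ell.semi_axes[0]
    y = (np.arange(ny) * dy - ell.center[1]) / ell.semi_axes[1]
    x = (np.arange(nx) * dx - ell.center[2]) / ell.semi_axes[2]
    return (
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    ) <= 1.0


def _check_inside(config: PhantomConfig, ell: Ellipsoid) -> None:
    for axis in range(3):
        lo = ell.center[axis] - ell.semi_axes[axis]
        hi = ell.center[axis] + ell.semi_axes[axis]
        extent = (config.grid_shape[axis] - 1) * config.spacing[axis]
        margin = 2 * config.spacing[axis] if axis else 0.0  # in-plane body margin
        if lo < margin or hi > extent - margin:
            raise GeometryError(
                f"ellipsoid overlaps the grid boundary on axis {axis} "
                f"([{lo:.1f}, {hi:.1f}] mm vs extent {extent:.1f} mm)"
            )


def generate_phantom(config: PhantomConfig) -> tuple[CTVolume, LungMask, PhantomTruth]:
    """Generate a phantom volume, its true mask, and the analytic ground truth.

    Identical configs (including seed) give bit-identical output.
    """
    if len(config.ellipsoids) < 1:
        raise ConfigurationError("phantom needs at least one lung ellipsoid")
    for ell in config.ellipsoids:
        _check_inside(config, ell)

    rng = np.random.default_rng(config.seed)
    lung = np.zeros(config.grid_shape, dtype=bool)
    for ell in config.ellipsoids:
        lung |= _ellipsoid_mask(config, ell)
    mask = LungMask(labels=lung)

    voxels = np.full(config.grid_shape, BACKGROUND_HU, dtype=np.float64)
    zs, ys, xs = np.nonzero(lung)
    body = (
        slice(max(0, zs.min() - 1), min(config.grid_shape[0], zs.max() + 2)),
        slice(max(1, ys.min() - 3), min(config.grid_shape[1] - 1, ys.max() + 4)),
        slice(max(1, xs.min() - 3), min(config.grid_shape[2] - 1, xs.max() + 4)),
    )
    voxels[body] = BODY_HU

    volume = CTVolume(
        voxels=voxels, spacing=config.spacing, source_id=f"phantom-seed{config.seed}"
    )

    # Assign nominal regions with the pipeline's own partition so measured ROI
    # membership equals generating-law membership.
    selection = select_slices(volume, mask, n_slices=config.n_slices)
    cc_of_selected = assign_cc_bands(selection)
    sel = np.asarray(selection.indices)
    cc_idx_by_z = np.empty(config.grid_shape[0], dtype=int)
    for z in range(config.grid_shape[0]):
        nearest = int(np.argmin(np.abs(sel - z)))
        cc_idx_by_z[z] = CC_BANDS.index(cc_of_selected[nearest])

    roi_labels = np.zeros(config.grid_shape, dtype=np.int8)
    for z in np.unique(zs):
        rows, cols = np.nonzero(lung[z])
        grav = grav_band_of_rows(rows, int(rows.min()), int(rows.max()))
        roi_labels[z, rows, cols] = 3 * cc_idx_by_z[z] + grav + 1

    for code, roi in enumerate(ROI_IDS, start=1):
        where = roi_labels == code
        n = int(where.sum())
        if n == 0:
            continue
        voxels[where] = config.region_law(roi).sample(n, rng)

    if config.noise_sd > 0:
        voxels[lung] += rng.normal(0.0, config.noise_sd, size=int(lung.sum()))
    voxels[lung] = np.clip(voxels[lung], HU_MIN, HU_MAX)

    truth = PhantomTruth(
        mask=mask,
        region_laws={roi: config.region_law(roi) for roi in ROI_IDS},
        analytic_fi=analytic_focal_index(
            config.region_law(roi_id("ventral", "apical")),
            config.region_law(roi_id("dorsal", "diaphragmatic")),
            noise_sd=config.noise_sd,
        ),
        roi_labels=roi_labels,
    )
    return volume, mask, truth
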
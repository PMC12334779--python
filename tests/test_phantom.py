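import numpy as np
import pytest

import focalindex as fx
from focalindex.errors import ConfigurationError, GeometryError
from focalindex.phantom import (
    AERATED_LAW,
    CONSOLIDATED_LAW,
    Ellipsoid,
    region_severity,
)
from focalindex.profiles import BIN_EDGES


def _fine_grid_fi(law_a, law_b, step=0.1):
    """Independent oracle: trapezoid-integrate the pdfs on a 0.1-HU grid,
    aggregate to the 5-HU bins, then take the absolute-difference sum."""

    def bin_masses(law):
        masses = []
        for lo, hi in zip(BIN_EDGES[:-1], BIN_EDGES[1:]):
            x = np.arange(lo, hi + step / 2, step)
            masses.append(np.trapezoid(law.pdf(x), x))
        m = np.asarray(masses)
        return m / m.sum()

    return 100.0 * np.abs(bin_masses(law_a) - bin_masses(law_b)).sum()


class TestAnalyticFocalIndex:
    def test_identical_laws_zero(self):
        assert fx.analytic_focal_index(AERATED_LAW, AERATED_LAW) == 0.0

    def test_disjoint_support_laws_200(self):
        assert np.isclose(fx.analytic_focal_index(AERATED_LAW, CONSOLIDATED_LAW), 200.0)

    def test_overlapping_normals_match_fine_grid_oracle(self):
        a = fx.MixtureLaw((fx.TruncatedNormal(-800.0, 50.0),), (1.0,))
        b = fx.MixtureLaw((fx.TruncatedNormal(-300.0, 50.0),), (1.0,))
        ours = fx.analytic_focal_index(a, b)
        oracle = _fine_grid_fi(a, b)
        assert abs(ours - oracle) < 0.5
        assert 0.0 < ours < 200.0

    def test_nondecreasing_in_phi(self):
        values = [
            fx.analytic_focal_index(
                fx.default_config(phi=phi).region_law(fx.VENTRAL_APICAL),
                fx.default_config(phi=phi).region_law(fx.DORSAL_DIAPHRAGMATIC),
            )
            for phi in np.linspace(0, 1, 9)
        ]
        assert np.all(np.diff(values) >= -1e-9)

    def test_noise_widens_distributions_but_keeps_normalisation(self):
        quiet = fx.analytic_focal_index(AERATED_LAW, CONSOLIDATED_LAW, noise_sd=0.0)
        noisy = fx.analytic_focal_index(AERATED_LAW, CONSOLIDATED_LAW, noise_sd=30.0)
        assert noisy <= quiet
        assert noisy > 150.0  # still near-separated for far-apart modes


class TestMixtureLaw:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            fx.MixtureLaw((fx.TruncatedNormal(-500, 50),), (0.7,))

    def test_component_truncation_must_fit_domain(self):
        with pytest.raises(ConfigurationError):
            fx.TruncatedNormal(-500, 50, lo=-1200.0)

    def test_empty_truncation_mass_rejected(self):
        with pytest.raises(ConfigurationError):
            fx.TruncatedNormal(-900.0, 1.0, lo=0.0, hi=100.0)

    def test_bin_masses_sum_to_one(self):
        law = AERATED_LAW.mixed_with(CONSOLIDATED_LAW, 0.4)
        assert np.isclose(law.bin_masses(BIN_EDGES).sum(), 1.0, atol=1e-9)

    def test_severity_map_corners(self):
        assert region_severity("ventral", "apical") == 0.0
        assert region_severity("dorsal", "diaphragmatic") == 1.0
        assert region_severity("ventral", "diaphragmatic") == 0.5


class TestGeneratePhantom:
    def test_determinism_bit_identical(self):
        cfg = fx.default_config(phi=0.6, seed=9, target_roi_voxels=2_000)
        v1, m1, t1 = fx.generate_phantom(cfg)
        v2, m2, t2 = fx.generate_phantom(cfg)
        assert np.array_equal(v1.voxels, v2.voxels)
        assert np.array_equal(m1.labels, m2.labels)
        assert t1.analytic_fi == t2.analytic_fi

    def test_homogeneous_phantom_measures_near_zero(self, homogeneous_phantom):
        _, vol, mask, truth = homogeneous_phantom
        rep = fx.run_scan_arrays(vol, mask)
        assert truth.analytic_fi == 0.0
        assert rep.focal_index.value < 5.0  # binomial sampling noise bound

    def test_separated_phantom_measures_near_200(self, focal_phantom):
        _, vol, mask, truth = focal_phantom
        rep = fx.run_scan_arrays(vol, mask)
        assert np.isclose(truth.analytic_fi, 200.0)
        assert rep.focal_index.value > 195.0

    def test_smallest_roi_meets_target(self, focal_phantom):
        _, vol, mask, _ = focal_phantom
        rmap = fx.build_region_map(vol, mask)
        assert min(rmap.roi_voxel_counts.values()) >= 10_000

    def test_out_of_grid_ellipsoid_rejected(self):
        cfg = fx.default_config(phi=0.5, seed=0, target_roi_voxels=2_000)
        bad = fx.PhantomConfig(
            grid_shape=cfg.grid_shape,
            spacing=cfg.spacing,
            ellipsoids=(Ellipsoid(center=(0.0, 10.0, 10.0), semi_axes=(30.0, 5.0, 5.0)),),
        )
        with pytest.raises(GeometryError):
            fx.generate_phantom(bad)

    def test_in_lung_values_within_domain(self, focal_phantom):
        _, vol, mask, _ = focal_phantom
        hu = vol.voxels[mask.labels]
        assert hu.min() >= -1000.0 and hu.max() <= 100.0

    def test_noise_sd_recovery_against_convolved_truth(self):
        import dataclasses

        # modes close enough that 40-HU scanner noise blurs them together
        base = fx.default_config(phi=1.0, seed=13, target_roi_voxels=10_000, noise_sd=40.0)
        cfg = dataclasses.replace(
            base,
            aerated_law=fx.MixtureLaw((fx.TruncatedNormal(-500.0, 20.0, -1000.0, -360.0),), (1.0,)),
            consolidated_law=fx.MixtureLaw((fx.TruncatedNormal(-250.0, 20.0, -340.0, 100.0),), (1.0,)),
        )
        vol, mask, truth = fx.generate_phantom(cfg)
        rep = fx.run_scan_arrays(vol, mask)
        assert 150.0 < truth.analytic_fi < 199.5  # noise blurs the separation
        assert abs(rep.focal_index.value - truth.analytic_fi) < 5.0

    def test_phi_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            fx.default_config(phi=1.5)
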
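import numpy as np
import pytest

import focalindex as fx
from focalindex.errors import InsufficientExtentError, PartitionError
from focalindex.regions import CC_BANDS, GRAV_BANDS, ROI_IDS, grav_band_of_rows, roi_code


def _mask_spanning(shape, z0, z1):
    labels = np.zeros(shape, dtype=bool)
    labels[z0 : z1 + 1, 5:-5, 5:-5] = True
    return fx.LungMask(labels=labels)


def _volume(shape, spacing=(1.5, 1.0, 1.0)):
    return fx.CTVolume(voxels=np.full(shape, -500.0), spacing=spacing)


class TestSelectSlices:
    def test_endpoints_always_included(self):
        shape = (200, 20, 20)
        vol, mask = _volume(shape), _mask_spanning(shape, 10, 180)
        sel = fx.select_slices(vol, mask)
        assert len(sel.indices) == 18
        assert sel.indices[0] == 10 and sel.indices[-1] == 180
        assert np.all(np.diff(sel.indices) > 0)

    def test_extent_equal_to_n_returns_identity(self):
        shape = (30, 20, 20)
        vol, mask = _volume(shape), _mask_spanning(shape, 5, 22)
        sel = fx.select_slices(vol, mask)
        assert sel.indices == tuple(range(5, 23))

    def test_nineteen_slices_skip_one_interior(self):
        shape = (30, 20, 20)
        vol, mask = _volume(shape), _mask_spanning(shape, 5, 23)
        sel = fx.select_slices(vol, mask)
        # brute-force even-spacing rule: round(linspace) is collision-free here
        expected = tuple(int(np.floor(x + 0.5)) for x in np.linspace(5, 23, 18))
        assert sel.indices == expected
        skipped = set(range(5, 24)) - set(sel.indices)
        assert len(skipped) == 1 and 5 < next(iter(skipped)) < 23

    def test_insufficient_extent_raises(self):
        shape = (30, 20, 20)
        vol, mask = _volume(shape), _mask_spanning(shape, 5, 15)
        with pytest.raises(InsufficientExtentError):
            fx.select_slices(vol, mask)

    @pytest.mark.parametrize("z0,z1", [(0, 39), (3, 25), (10, 29)])
    def test_even_spacing_against_bruteforce(self, z0, z1):
        shape = (40, 20, 20)
        sel = fx.select_slices(_volume(shape), _mask_spanning(shape, z0, z1))
        ideal = np.linspace(z0, z1, 18)
        assert np.all(np.abs(np.asarray(sel.indices) - ideal) <= 0.5 + 1e-9)


class TestCCBands:
    def test_18_slices_split_6_6_6(self):
        sel = fx.SliceSelection(indices=tuple(range(18)), slice_thickness=1.5)
        bands = fx.assign_cc_bands(sel)
        assert bands == ("apical",) * 6 + ("mediastinal",) * 6 + ("diaphragmatic",) * 6

    def test_reversed_selection_rejected(self):
        with pytest.raises(PartitionError):
            fx.SliceSelection(indices=tuple(range(18))[::-1], slice_thickness=1.5)

    def test_generalised_split_n12(self):
        sel = fx.SliceSelection(indices=tuple(range(12)), slice_thickness=1.5)
        bands = fx.assign_cc_bands(sel)
        assert bands == ("apical",) * 4 + ("mediastinal",) * 4 + ("diaphragmatic",) * 4

    def test_indivisible_count_raises(self):
        sel = fx.SliceSelection(indices=tuple(range(14)), slice_thickness=1.5)
        with pytest.raises(PartitionError):
            fx.assign_cc_bands(sel)


class TestGravBands:
    def test_equal_thirds_of_sixty_rows(self):
        rows = np.arange(20, 80)
        bands = grav_band_of_rows(rows, 20, 79)
        assert np.all(bands[rows < 40] == 0)
        assert np.all(bands[(rows >= 40) & (rows < 60)] == 1)
        assert np.all(bands[rows >= 60] == 2)

    def test_single_row_degenerate_extent_is_ventral(self):
        assert grav_band_of_rows(np.array([33]), 33, 33).tolist() == [0]

    def test_boundary_voxel_goes_dorsal(self):
        # 6 rows -> thirds of 2; row exactly on a boundary joins the deeper band
        bands = grav_band_of_rows(np.arange(6), 0, 5)
        assert bands.tolist() == [0, 0, 1, 1, 2, 2]


class TestRegionMap:
    def test_nine_rois_partition_selected_voxels(self, cuboid_lung):
        vol, mask = cuboid_lung
        rmap = fx.build_region_map(vol, mask)
        assert set(rmap.roi_voxel_counts) == set(ROI_IDS)
        n_selected = int(mask.labels[list(rmap.selection.indices)].sum())
        assert sum(rmap.roi_voxel_counts.values()) == n_selected
        labelled = rmap.roi_labels[rmap.roi_labels > 0]
        assert labelled.size == n_selected  # mutually exclusive and exhaustive

    def test_uniform_cuboid_has_equal_roi_counts(self, cuboid_lung):
        vol, mask = cuboid_lung
        counts = list(fx.build_region_map(vol, mask).roi_voxel_counts.values())
        assert len(set(counts)) == 1

    def test_empty_middle_third_yields_empty_rois_with_warning(self, cuboid_lung):
        # a craniocaudal gap empties the mediastinal band: 3 empty ROIs,
        # warnings recorded, 6 populated ROIs remain
        vol, mask = cuboid_lung
        labels = mask.labels.copy()
        labels[7:13] = False  # selection stays 1..18 (extent-driven)
        with pytest.warns(UserWarning):
            rmap = fx.build_region_map(vol, fx.LungMask(labels=labels))
        empty = [r for r, v in rmap.roi_voxel_counts.items() if v == 0]
        assert sorted(empty) == sorted(f"{g}-mediastinal" for g in GRAV_BANDS)
        assert len(rmap.warnings) == 3
        assert sum(v > 0 for v in rmap.roi_voxel_counts.values()) == 6

    def test_left_right_mirror_leaves_counts_unchanged(self, focal_phantom):
        _, vol, mask, _ = focal_phantom
        rmap = fx.build_region_map(vol, mask)
        vol_m = fx.CTVolume(voxels=vol.voxels[:, :, ::-1].copy(), spacing=vol.spacing)
        mask_m = fx.LungMask(labels=mask.labels[:, :, ::-1].copy())
        rmap_m = fx.build_region_map(vol_m, mask_m)
        assert rmap.roi_voxel_counts == rmap_m.roi_voxel_counts

    def test_ventral_dorsal_flip_swaps_band_counts(self, cuboid_lung):
        vol, mask = cuboid_lung
        rmap = fx.build_region_map(vol, mask)
        vol_f = fx.CTVolume(voxels=vol.voxels[:, ::-1, :].copy(), spacing=vol.spacing)
        mask_f = fx.LungMask(labels=mask.labels[:, ::-1, :].copy())
        rmap_f = fx.build_region_map(vol_f, mask_f)
        for cc in CC_BANDS:
            assert (
                rmap.roi_voxel_counts[f"ventral-{cc}"] == rmap_f.roi_voxel_counts[f"dorsal-{cc}"]
            )
            assert (
                rmap.roi_voxel_counts[f"dorsal-{cc}"] == rmap_f.roi_voxel_counts[f"ventral-{cc}"]
            )

    def test_symmetric_phantom_ventral_dorsal_counts_equal(self, cuboid_lung):
        vol, mask = cuboid_lung
        rmap = fx.build_region_map(vol, mask)
        for cc in CC_BANDS:
            assert (
                rmap.roi_voxel_counts[f"ventral-{cc}"] == rmap.roi_voxel_counts[f"dorsal-{cc}"]
            )

    def test_roi_codes_enumerate_full_product(self):
        assert sorted(roi_code(r) for r in ROI_IDS) == list(range(1, 10))
        assert roi_code(fx.VENTRAL_APICAL) == 1
        assert roi_code(fx.DORSAL_DIAPHRAGMATIC) == 9

    def test_global_extent_mode_runs(self, cuboid_lung):
        vol, mask = cuboid_lung
        rmap = fx.build_region_map(vol, mask, extent_mode="global")
        assert sum(rmap.roi_voxel_counts.values()) == int(
            mask.labels[list(rmap.selection.indices)].sum()
        )
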
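from collections import deque

import numpy as np
import pytest

import deshvol as dv
from deshvol.phantom import Box, Ellipsoid


class TestCoronalBand:
    def test_default_band_is_20_slices_at_1mm(self, inph_noiseless):
        _, image, _ = inph_noiseless
        band = dv.coronal_band(image, 20.0)
        ys = np.flatnonzero(band.data.any(axis=(0, 2)))
        assert len(ys) == 20
        assert ys[0] == image.pc_index[1]  # PC slice included

    def test_half_open_convention_small_band(self, inph_noiseless):
        _, image, _ = inph_noiseless
        band = dv.coronal_band(image, 0.5)
        ys = np.flatnonzero(band.data.any(axis=(0, 2)))
        assert list(ys) == [image.pc_index[1]]

    @pytest.mark.parametrize("pc_y,spacing_y,length", [
        (3, 0.8, 7.3), (10, 1.0, 20.0), (0, 1.3, 11.0), (17, 0.53, 5.0),
    ])
    def test_matches_voxelwise_position_oracle(self, pc_y, spacing_y, length):
        shape = (8, 40, 8)
        image = dv.ImageVolume(np.zeros(shape), (1.0, spacing_y, 1.0),
                               pc_index=(4, pc_y, 4))
        band = dv.coronal_band(image, length)
        y_pc = pc_y * spacing_y
        for y in range(shape[1]):
            pos = y * spacing_y
            expected = y_pc <= pos < y_pc + length
            assert band.data[0, y, 0] == expected

    def test_band_past_grid_rejected(self, inph_noiseless):
        _, image, _ = inph_noiseless
        with pytest.raises(ValueError, match="extends past"):
            dv.coronal_band(image, 100.0)

    def test_requires_pc_landmark(self):
        image = dv.ImageVolume(np.zeros((5, 5, 5)), (1, 1, 1))
        with pytest.raises(ValueError, match="posterior-commissure"):
            dv.coronal_band(image, 2.0)


def _hc_oracle(region, voxvol_cm3, target):
    """Independent layer-granular accumulation: sort voxels by z, top down."""
    counts = region.sum(axis=(0, 1))
    out = np.zeros_like(region)
    cum = 0.0
    for z in range(region.shape[2] - 1, -1, -1):
        layer = counts[z] * voxvol_cm3
        if cum + layer < target:
            out[:, :, z] = region[:, :, z]
            cum += layer
        else:
            if abs(cum + layer - target) < abs(cum - target):
                out[:, :, z] = region[:, :, z]
            break
    return out


class TestHighConvexityConstruction:
    def test_slab_30cc_exact_20_layers(self, preset_runs):
        spec, image, truth = preset_runs["slab_30cc"]
        band = dv.coronal_band(image, 20.0)
        mask, achieved, n_layers = dv.build_hc_search_volume(
            truth.masks["head"], band, 30.0)
        assert achieved == pytest.approx(30.0, abs=1e-12)
        assert n_layers == 20
        assert mask.volume_cm3 == pytest.approx(30.0, abs=1e-12)

    def test_saturation_returns_whole_region(self, preset_runs):
        spec, image, truth = preset_runs["slab_30cc"]
        band = dv.coronal_band(image, 20.0)
        region = truth.masks["head"].intersect(band)
        mask, achieved, _ = dv.build_hc_search_volume(
            truth.masks["head"], band, region.volume_cm3)
        np.testing.assert_array_equal(mask.data, region.data)
        assert achieved == pytest.approx(region.volume_cm3)

    def test_head_too_small_rejected(self, preset_runs):
        spec, image, truth = preset_runs["slab_30cc"]
        band = dv.coronal_band(image, 20.0)
        with pytest.raises(ValueError, match="too small"):
            dv.build_hc_search_volume(truth.masks["head"], band, 1e6)

    @pytest.mark.parametrize("target", [5.0, 10.0, 17.3, 25.0])
    def test_ellipsoid_head_matches_accumulation_oracle(self, target):
        # non-constant cross-sections exercise the nearest-to-target rule
        spec = dv.PhantomSpec(
            head=Ellipsoid(center=(47.5, 30.0, 32.0), radii=(35.0, 25.0, 28.0)),
            sf_compartments=(), hc_compartments=(), lv_compartment=None,
        )
        image, truth = dv.generate_phantom(spec)
        band = dv.coronal_band(image, 20.0)
        mask, achieved, _ = dv.build_hc_search_volume(
            truth.masks["head"], band, target)
        region = truth.masks["head"].data & band.data
        oracle = _hc_oracle(region, image.voxel_volume_mm3 / 1000.0, target)
        np.testing.assert_array_equal(mask.data, oracle)
        assert abs(achieved - target) <= 1.5  # at most one axial layer off

    def test_monotone_in_target(self, preset_runs):
        spec, image, truth = preset_runs["control"]
        band = dv.coronal_band(image, 20.0)
        prev = None
        for target in (10.0, 20.0, 30.0):
            mask, _, _ = dv.build_hc_search_volume(truth.masks["head"], band,
                                                   target)
            if prev is not None:
                assert np.all(prev <= mask.data)
            prev = mask.data


class TestSylvianFissureConstruction:
    def test_21_axial_layers_per_hemisphere(self, inph_noiseless):
        spec, image, truth = inph_noiseless
        band = dv.coronal_band(image, 20.0)
        mask = dv.build_sf_search_volume(band, truth.masks["head"],
                                         spec.search_spec())
        zs = np.flatnonzero(mask.data.any(axis=(0, 1)))
        assert len(zs) == 21  # center +/- 10 mm at 1 mm spacing
        assert zs[0] == 20 and zs[-1] == 40

    def test_contains_slab_and_respects_limits(self, inph_noiseless):
        spec, image, truth = inph_noiseless
        band = dv.coronal_band(image, 20.0)
        mask = dv.build_sf_search_volume(band, truth.masks["head"],
                                         spec.search_spec())
        slab_in_band = truth.masks["sf"].data & band.data
        assert np.all(slab_in_band <= mask.data)
        # inside band and head (dura as outer limit)
        assert np.all(mask.data <= (band.data & truth.masks["head"].data))
        xs = np.flatnonzero(mask.data.any(axis=(1, 2))) * image.spacing[0]
        limits = spec.search_spec().medial_limit_x_mm
        assert np.all((xs <= limits["left"]) | (xs >= limits["right"]))

    def test_degenerate_medial_limit_rejected(self, inph_noiseless):
        spec, image, truth = inph_noiseless
        sspec = spec.search_spec()
        sspec.medial_limit_x_mm = {"left": 2.0, "right": 95.0}  # off the head
        band = dv.coronal_band(image, 20.0)
        with pytest.raises(ValueError, match="empty"):
            dv.build_sf_search_volume(band, truth.masks["head"], sspec)

    def test_center_outside_head_rejected(self, inph_noiseless):
        spec, image, truth = inph_noiseless
        sspec = spec.search_spec()
        sspec.sf_center_z_mm = {"left": 200.0, "right": 200.0}
        band = dv.coronal_band(image, 20.0)
        with pytest.raises(ValueError):
            dv.build_sf_search_volume(band, truth.masks["head"], sspec)


def _bfs_flood_fill(data, seed, threshold):
    """Breadth-first search over the same 6-connected predicate."""
    visited = np.zeros(data.shape, dtype=bool)
    if not data[seed] < threshold:
        return visited
    queue = deque([seed])
    visited[seed] = True
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nb = (x + dx, y + dy, z + dz)
            if all(0 <= c < n for c, n in zip(nb, data.shape)):
                if not visited[nb] and data[nb] < threshold:
                    visited[nb] = True
                    queue.append(nb)
    return visited


class TestFloodFill:
    def test_single_dark_cube(self):
        data = np.full((20, 20, 20), 300.0)
        data[5:10, 5:10, 5:10] = 100.0
        image = dv.ImageVolume(data, (1, 1, 1))
        mask = dv.flood_fill_lv(image, (7, 7, 7), 200.0)
        expected = np.zeros_like(data, dtype=bool)
        expected[5:10, 5:10, 5:10] = True
        np.testing.assert_array_equal(mask.data, expected)

    def test_separated_cubes_stay_separate(self):
        data = np.full((20, 20, 20), 300.0)
        data[2:6, 2:6, 2:6] = 100.0
        data[10:14, 10:14, 10:14] = 100.0
        image = dv.ImageVolume(data, (1, 1, 1))
        mask = dv.flood_fill_lv(image, (3, 3, 3), 200.0)
        assert mask.data[3, 3, 3]
        assert not mask.data[12, 12, 12]

    def test_bright_seed_rejected(self):
        image = dv.ImageVolume(np.full((5, 5, 5), 300.0), (1, 1, 1))
        with pytest.raises(ValueError, match="not CSF-like"):
            dv.flood_fill_lv(image, (2, 2, 2), 200.0)

    def test_noisy_ventricle_matches_bfs_oracle(self):
        spec = dv.preset("inph", noise_sd=20.0, seed=12)
        image, _ = dv.generate_phantom(spec)
        mask = dv.flood_fill_lv(image, spec.lv_seed, 200.0)
        oracle = _bfs_flood_fill(np.asarray(image.data), spec.lv_seed, 200.0)
        np.testing.assert_array_equal(mask.data, oracle)

    def test_output_within_predicate(self, inph_noiseless):
        spec, image, _ = inph_noiseless
        mask = dv.flood_fill_lv(image, spec.lv_seed, 200.0)
        assert np.all(image.data[mask.data] < 200.0)


class TestManualRois:
    def test_rule_based_save_load_round_trip(self, tmp_path, inph_noiseless):
        spec, image, truth = inph_noiseless
        svs = dv.build_search_volumes(image, truth.masks["head"],
                                      spec.search_spec())
        dv.save_rois(svs, tmp_path)
        loaded = dv.load_manual_rois(image, tmp_path / "hc.nii.gz",
                                     tmp_path / "sf.nii.gz",
                                     tmp_path / "lv.nii.gz")
        for key in ("hc", "sf", "lv"):
            np.testing.assert_array_equal(
                getattr(loaded, f"{key}_mask").data,
                getattr(svs, f"{key}_mask").data,
            )
            assert loaded.provenance[key] == "manual"

    def test_band_verify_rejects_and_clip_clips(self, tmp_path, inph_noiseless):
        spec, image, truth = inph_noiseless
        svs = dv.build_search_volumes(image, truth.masks["head"],
                                      spec.search_spec())
        # enlarge sf mask one slice beyond the band
        bad = svs.sf_mask.data.copy()
        bad[:, 41, :] = bad[:, 39, :]
        dv.write_mask(dv.BinaryMask(bad, image.spacing), tmp_path / "sf.nii.gz")
        dv.save_rois(dv.SearchVolumeSet(svs.hc_mask, svs.sf_mask, svs.lv_mask),
                     tmp_path / "ok")
        band = dv.coronal_band(image, 20.0)
        with pytest.raises(ValueError, match="outside the coronal band"):
            dv.load_manual_rois(image, tmp_path / "ok" / "hc.nii.gz",
                                tmp_path / "sf.nii.gz",
                                tmp_path / "ok" / "lv.nii.gz", band=band)
        clipped = dv.load_manual_rois(image, tmp_path / "ok" / "hc.nii.gz",
                                      tmp_path / "sf.nii.gz",
                                      tmp_path / "ok" / "lv.nii.gz",
                                      band=band, band_mode="clip")
        assert np.all(clipped.sf_mask.data <= band.data)
        np.testing.assert_array_equal(clipped.sf_mask.data, svs.sf_mask.data)

    def test_manual_roi_covering_truth_recovers_truth_volume(
            self, tmp_path, inph_noiseless):
        spec, image, truth = inph_noiseless
        svs = dv.build_search_volumes(image, truth.masks["head"],
                                      spec.search_spec())
        # a hand-drawn SF ROI: the true slab plus a 1-voxel GM margin in z
        drawn = truth.masks["sf"].data.copy()
        drawn[:, :, 1:] |= truth.masks["sf"].data[:, :, :-1]
        drawn &= truth.masks["head"].data
        dv.write_mask(dv.BinaryMask(drawn, image.spacing), tmp_path / "sf.nii.gz")
        dv.save_rois(svs, tmp_path / "rest")
        loaded = dv.load_manual_rois(image, tmp_path / "rest" / "hc.nii.gz",
                                     tmp_path / "sf.nii.gz",
                                     tmp_path / "rest" / "lv.nii.gz")
        res = dv.run_pipeline(image, loaded)
        assert res.v_csf_sf == pytest.approx(truth.volumes_cm3["sf"])
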
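"""Image characterization: resampling, histograms, ROI placement, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vncstudy as v
from vncstudy.imgchar import (ROISpec, resample_mask_isotropic, rois_from_json,
                              rois_to_json)

from conftest import flat_volume, quiet_spec


def cylinder_mask(radius_mm=20.0, nx=60, ny=60, nz=30, spacing=(1.0, 1.0, 1.0)):
    ii = (np.arange(nx) * spacing[0])[:, None] - nx * spacing[0] / 2
    jj = (np.arange(ny) * spacing[1])[None, :] - ny * spacing[1] / 2
    disk = ii ** 2 + jj ** 2 <= radius_mm ** 2
    return np.repeat(disk[:, :, None], nz, axis=2)


class TestResampleIsotropic:
    def test_identity_on_isotropic_grid(self):
        vol = flat_volume(shape=(6, 6, 6), spacing=(1, 1, 1))
        vol.data += np.random.default_rng(0).normal(size=vol.shape).astype(np.float32)
        out = v.resample_isotropic(vol, 1.0)
        assert np.array_equal(out.data, vol.data)

    def test_extent_bookkeeping_upsampling_z(self):
        """10 slices at 2 mm span 18 mm -> 19 slices at 1 mm, same extent."""
        vol = flat_volume(shape=(4, 4, 10), spacing=(1.0, 1.0, 2.0))
        out = v.resample_isotropic(vol, 1.0)
        assert out.shape[2] == 19
        assert out.extent_mm[2] == pytest.approx(vol.extent_mm[2])

    def test_constant_volume_stays_constant(self):
        vol = flat_volume(value=73.0, shape=(5, 7, 9), spacing=(0.8, 1.1, 2.3))
        out = v.resample_isotropic(vol, 0.7)
        assert np.allclose(out.data, 73.0, atol=1e-4)

    def test_rejects_bad_target(self):
        with pytest.raises(ValueError):
            v.resample_isotropic(flat_volume(), 0.0)

    def test_mask_resampling_is_nearest_neighbor(self):
        mask = np.zeros((6, 6, 6), dtype=np.uint8)
        mask[2:4, 2:4, 2:4] = 1
        out = resample_mask_isotropic(mask, (1, 1, 1), 0.5)
        assert set(np.unique(out)) <= {0, 1}
        assert out.sum() > mask.sum()  # finer grid, same region

    def test_masked_mean_approximately_conserved_on_smooth_field(self):
        """Trilinear resampling moves the masked mean by < 1 HU when the
        intensity field varies smoothly over the mask."""
        nx, ny, nz = 40, 40, 30
        ii = np.arange(nx)[:, None, None] * 0.75
        jj = np.arange(ny)[None, :, None] * 0.75
        kk = np.arange(nz)[None, None, :] * 1.5
        data = (100 + 40 * np.sin(ii / 8) + 30 * np.cos(jj / 10)
                + 20 * np.sin(kk / 12)).astype(np.float32)
        vol = v.CTVolume(data, (0.75, 0.75, 1.5), 1.5, "CTA")
        mask = np.zeros((nx, ny, nz), bool)
        mask[5:35, 5:35, 5:25] = True
        iso = v.resample_isotropic(vol, 1.0)
        mask_iso = resample_mask_isotropic(mask, vol.spacing, 1.0)
        crop = tuple(slice(0, min(a, b)) for a, b in zip(iso.shape, mask_iso.shape))
        before = float(vol.data[mask].mean())
        after = float(iso.data[crop][mask_iso[crop].astype(bool)].mean())
        assert abs(before - after) < 1.0


class TestHeartHistogram:
    def test_worked_proportion_example(self):
        vol = flat_volume(shape=(2, 2, 1), spacing=(1, 1, 1))
        vol.data[:, :, 0] = [[100.0, 140.0], [200.0, 50.0]]
        mask = np.ones((2, 2, 1), bool)
        hist = v.heart_histogram(vol, mask, threshold=130.0)
        assert hist.proportion_above == pytest.approx(0.5)

    def test_all_below_threshold_gives_zero(self):
        vol = flat_volume(value=50.0)
        hist = v.heart_histogram(vol, np.ones(vol.shape, bool))
        assert hist.proportion_above == 0.0

    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.5, 40.0))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_proportion_invariant_under_bin_width(self, seed, bin_width):
        """The supra-threshold fraction is computed from raw voxels, so any
        histogram binning gives the same value."""
        rng = np.random.default_rng(seed)
        vol = flat_volume(shape=(10, 10, 5))
        vol.data += rng.normal(100, 80, vol.shape).astype(np.float32)
        vol.data.clip(-1000, 1500, out=vol.data)
        mask = np.ones(vol.shape, bool)
        ref = v.heart_histogram(vol, mask, bin_width=1.0).proportion_above
        got = v.heart_histogram(vol, mask, bin_width=bin_width).proportion_above
        assert got == ref

    def test_counts_cover_all_masked_voxels(self):
        vol = flat_volume(value=2000.0)  # beyond the default range: clipped in
        hist = v.heart_histogram(vol, np.ones(vol.shape, bool))
        assert hist.counts.sum() == hist.n_total == vol.data.size

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            v.heart_histogram(flat_volume(), np.zeros((8, 8, 4), bool))

    def test_phantom_iodine_removal_pattern(self, small_quiet_bundle):
        """Contrast series: most heart voxels above 130 HU; VNC: almost none."""
        bundle = small_quiet_bundle
        from vncstudy.imgchar import resample_mask_to_grid

        cta = v.heart_histogram(bundle.volumes["CTA"], bundle.heart_mask)
        assert cta.proportion_above > 0.7
        for sid in ("VNC_Conv_1", "VNC_PC_1", "TNC"):
            vol = bundle.volumes[sid]
            mask = (bundle.heart_mask if vol.shape == bundle.heart_mask.shape
                    else resample_mask_to_grid(bundle.heart_mask,
                                               bundle.base_spacing,
                                               vol.spacing, vol.shape))
            h = v.heart_histogram(vol, mask)
            assert h.proportion_above < 0.02


class TestROIPlacement:
    def test_feasible_mask_gives_requested_rois(self):
        mask = cylinder_mask(radius_mm=20.0)
        rois = v.place_lv_rois(mask, (1, 1, 1), diameter_mm=15.0, n_rois=3, seed=0)
        assert len(rois) == 3
        assert len({r.slice_index for r in rois}) == 3
        for r in rois:
            assert r.diameter == 15.0

    def test_infeasible_mask_reports_largest_diameter(self):
        mask = cylinder_mask(radius_mm=5.0)
        with pytest.raises(ValueError, match="largest feasible"):
            v.place_lv_rois(mask, (1, 1, 1), diameter_mm=15.0, n_rois=3, seed=0)

    def test_same_seed_identical(self):
        mask = cylinder_mask(radius_mm=20.0)
        a = v.place_lv_rois(mask, (1, 1, 1), 15.0, 3, seed=9)
        b = v.place_lv_rois(mask, (1, 1, 1), 15.0, 3, seed=9)
        assert a == b

    def test_circles_fully_inside_mask(self):
        mask = cylinder_mask(radius_mm=12.0)
        for roi in v.place_lv_rois(mask, (1, 1, 1), 10.0, 3, seed=1):
            cx, cy = roi.center
            r = roi.diameter / 2
            for ang in np.linspace(0, 2 * np.pi, 16, endpoint=False):
                i = int(round(cx + r * np.cos(ang)))
                j = int(round(cy + r * np.sin(ang)))
                assert mask[i, j, roi.slice_index]

    def test_roi_json_round_trip(self, tmp_path):
        rois = [ROISpec((3.0, 4.0), 15.0, 2), ROISpec((5.5, 1.0), 10.0, 7)]
        path = tmp_path / "rois.json"
        rois_to_json(rois, path)
        assert rois_from_json(path) == rois


class TestMeasureNoise:
    def _vol_with_noise(self, sd, seed=42, value=45.0):
        rng = np.random.default_rng(seed)
        data = np.full((60, 60, 30), value, np.float32)
        data += rng.normal(0, sd, data.shape).astype(np.float32)
        return v.CTVolume(data, (1, 1, 1), 1.0, "TNC")

    def test_constant_volume_zero_sd(self):
        vol = flat_volume(value=45.0, shape=(60, 60, 10), spacing=(1, 1, 1))
        rois = [ROISpec((30.0, 30.0), 15.0, k) for k in range(3)]
        res = v.measure_noise(vol, rois)
        assert res.per_roi_sd == [0.0, 0.0, 0.0]
        assert res.pooled_sd == 0.0

    def test_recovers_injected_sd_within_five_percent(self):
        vol = self._vol_with_noise(26.4)
        mask = cylinder_mask(radius_mm=20.0)
        rois = v.place_lv_rois(mask, (1, 1, 1), 15.0, 3, seed=0)
        res = v.measure_noise(vol, rois)
        assert abs(res.pooled_sd - 26.4) / 26.4 < 0.05

    def test_copied_rois_sample_identical_voxel_sets(self):
        """Registered series reuse one ROI list: doubling the volume doubles
        every per-ROI mean and SD exactly."""
        vol1 = self._vol_with_noise(10.0)
        vol2 = vol1.copy_with(data=vol1.data * 2.0)
        rois = [ROISpec((30.0, 30.0), 15.0, 5)]
        r1, r2 = v.measure_noise(vol1, rois), v.measure_noise(vol2, rois)
        assert r2.per_roi_mean[0] == pytest.approx(2 * r1.per_roi_mean[0], rel=1e-6)
        assert r2.per_roi_sd[0] == pytest.approx(2 * r1.per_roi_sd[0], rel=1e-6)

    def test_translation_equivariance(self):
        vol = self._vol_with_noise(15.0)
        shifted = vol.copy_with(data=np.roll(vol.data, 7, axis=0))
        roi = ROISpec((25.0, 30.0), 15.0, 4)
        roi_shifted = ROISpec((32.0, 30.0), 15.0, 4)
        a = v.measure_noise(vol, [roi])
        b = v.measure_noise(shifted, [roi_shifted])
        assert a.per_roi_sd[0] == pytest.approx(b.per_roi_sd[0], rel=1e-6)

    def test_out_of_bounds_roi_rejected(self):
        vol = flat_volume(shape=(20, 20, 5), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            v.measure_noise(vol, [ROISpec((2.0, 2.0), 15.0, 0)])
        with pytest.raises(ValueError):
            v.measure_noise(vol, [ROISpec((10.0, 10.0), 5.0, 99)])
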
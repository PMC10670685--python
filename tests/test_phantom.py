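"""Phantom generator: basis-map arithmetic, determinism, cohort sampling."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.signal import find_peaks

import vncstudy as v
from vncstudy.phantom import _insert_specks, resample_slab

from conftest import lesion_in, quiet_spec, small_spec


class TestGeneratePhantom:
    def test_zero_calcium_zero_noise_tnc_below_threshold(self):
        bundle = v.generate_phantom(quiet_spec())
        assert float(bundle.volumes["TNC"].data.max()) < 130.0

    def test_true_volume_is_sphere_formula(self):
        spec = quiet_spec()
        spec.calcifications = [lesion_in(spec, "LAD", 2.0, 400.0)]
        bundle = v.generate_phantom(spec)
        expected = 4.0 / 3.0 * math.pi * 2.0 ** 3
        assert bundle.ground_truth.true_volume_mm3.iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(33.51, abs=0.01)

    def test_cta_heart_histogram_is_trimodal_at_configured_levels(self):
        """The three strongest heart-histogram modes sit at the configured
        myocardium / RV pool / LV pool enhancement levels."""
        for spec in (quiet_spec(), small_spec()):  # noise-free and default noise
            bundle = v.generate_phantom(spec)
            hist = v.heart_histogram(bundle.volumes["CTA"], bundle.heart_mask)
            dens = ndi.gaussian_filter1d(hist.counts.astype(float), 4.0)
            peaks, props = find_peaks(dens, prominence=1.0)
            top3 = peaks[np.argsort(props["prominences"])[-3:]]
            centers = sorted(hist.bin_edges[top3] + 0.5)
            hu = spec.hu_levels
            for found, configured in zip(centers, (hu.myocardium_cta, hu.rv_pool_cta,
                                                   hu.lv_pool_cta)):
                assert abs(found - configured) < 10.0

    def test_tnc_histogram_unimodal_without_calcium(self):
        from vncstudy.imgchar import resample_mask_to_grid

        bundle = v.generate_phantom(quiet_spec())
        tnc = bundle.volumes["TNC"]
        mask = resample_mask_to_grid(bundle.heart_mask, bundle.base_spacing,
                                     tnc.spacing, tnc.shape)
        hist = v.heart_histogram(tnc, mask)
        dens = ndi.gaussian_filter1d(hist.counts.astype(float), 4.0)
        peaks, props = find_peaks(dens, prominence=dens.max() * 0.05)
        assert len(peaks) == 1

    def test_identical_seed_gives_bit_identical_bundles(self):
        spec = small_spec(seed=7)
        spec.calcifications = [lesion_in(spec, "RCA", 1.2, 300.0)]
        b1 = v.generate_phantom(spec)
        b2 = v.generate_phantom(spec)
        for sid in b1.volumes:
            assert np.array_equal(b1.volumes[sid].data, b2.volumes[sid].data)
        assert b1.ground_truth.equals(b2.ground_truth)

    @pytest.mark.parametrize("bad", ["outside", "overlap", "wrong_vessel"])
    def test_invalid_calcifications_rejected(self, bad):
        spec = quiet_spec()
        base = lesion_in(spec, "CX", 1.5, 300.0)
        if bad == "outside":
            spec.calcifications = [v.CalcificationSpec(
                center=(0.5, 0.5, 0.5), radius=2.0, peak_hu=300.0, vessel="CX")]
        elif bad == "overlap":
            near = lesion_in(spec, "CX", 1.5, 250.0, offset=(1.0, 0.0, 0.0))
            spec.calcifications = [base, near]
        else:
            spec.calcifications = [v.CalcificationSpec(
                center=base.center, radius=1.5, peak_hu=300.0, vessel="LM")]
        with pytest.raises(ValueError):
            v.generate_phantom(spec)


class TestSimulateVNC:
    def test_iodine_fully_removed(self, small_quiet_bundle):
        """With zero noise, VNC minus the resampled water map is supported
        only on calcium voxels: the iodine contribution is exactly zero."""
        bundle = small_quiet_bundle
        spec = bundle.spec
        for algorithm in ("conv", "pc"):
            vnc = v.simulate_vnc(bundle, algorithm, 1, spec)
            recon = v.RECON_SETTINGS[1]
            water = resample_slab(bundle.basis.water_equivalent, spec.base_spacing,
                                  recon.slice_thickness, recon.slice_increment)
            calcium = resample_slab(bundle.basis.calcium, spec.base_spacing,
                                    recon.slice_thickness, recon.slice_increment)
            diff = vnc.data - water
            assert np.abs(diff[calcium == 0]).max() < 1e-3
            assert diff[calcium > 0].max() > 100  # calcium survives

    def test_conv_retention_scales_calcium_excess(self, small_quiet_bundle):
        """A 400 HU lesion over a 40 HU bed keeps 0.7 x 360 HU of excess."""
        bundle = small_quiet_bundle
        cal = bundle.spec.calcifications[0]
        conv = v.simulate_vnc(bundle, "conv", 1, bundle.spec)
        idx = tuple(int(round(c / s)) for c, s in zip(cal.center, conv.spacing))
        core = float(conv.data[idx])
        assert core == pytest.approx(40.0 + 0.7 * (400.0 - 40.0), abs=1.0)
        pc = v.simulate_vnc(bundle, "pc", 1, bundle.spec)
        assert float(pc.data[idx]) == pytest.approx(400.0, abs=1.0)

    def test_conv_monotone_in_retention(self):
        import dataclasses

        spec = quiet_spec()
        spec.calcifications = [lesion_in(spec, "LM", 1.5, 500.0)]
        lo = dataclasses.replace(spec, calcium_retention_conv=0.5)
        hi = dataclasses.replace(spec, calcium_retention_conv=0.9)
        vol_lo = v.generate_phantom(lo).volumes["VNC_Conv_1"]
        vol_hi = v.generate_phantom(hi).volumes["VNC_Conv_1"]
        assert np.all(vol_hi.data >= vol_lo.data - 1e-4)

    def test_unknown_algorithm_or_setting_rejected(self, small_quiet_bundle):
        with pytest.raises(ValueError):
            v.simulate_vnc(small_quiet_bundle, "magic", 1)
        with pytest.raises(ValueError):
            v.simulate_vnc(small_quiet_bundle, "pc", 9)

    def test_speck_count_is_poisson_with_configured_rate(self):
        spec = small_spec()
        geom = v.PhantomGeometry.from_spec(spec)
        rate = 2.0
        counts = []
        for s in range(100):
            rng = np.random.default_rng(s)
            data = np.zeros((64, 64, 50), dtype=np.float32)
            counts.append(_insert_specks(data, (0.75, 0.75, 0.4), geom, rng,
                                         rate, 40.0))
        mean = np.mean(counts)
        # Poisson sampling error of the mean over 100 draws: sd ~ 0.14
        assert abs(mean - rate) < 3 * math.sqrt(rate / len(counts))

    def test_pc_specks_land_in_vessel_territories(self):
        spec = quiet_spec()
        spec.pc_false_positive_rate = 5.0
        bundle = v.generate_phantom(spec)
        pc = bundle.volumes["VNC_PC_1"]
        supra = np.argwhere(pc.data >= 130.0)
        assert len(supra)  # rate 5 makes at least one speck overwhelmingly likely
        geom = bundle.geometry
        for ijk in supra:
            p = ijk * np.array(pc.spacing)
            inside = any(np.all(p >= lo - 2.0) and np.all(p <= hi + 2.0)
                         for lo, hi in geom.territories.values())
            assert inside


class TestResampleSlab:
    def test_fast_path_matches_direct_midpoint_average(self):
        """Grid-aligned kernel path equals the brute subsample average."""
        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 5, 40)).astype(np.float32)
        dz = 0.2
        for thickness, increment in ((0.4, 0.2), (1.0, 0.4), (0.2, 0.2)):
            got = resample_slab(data, (1.0, 1.0, dz), thickness, increment)
            n_sub = max(1, round(thickness / dz))
            offsets = (np.arange(n_sub) + 0.5) / n_sub * thickness - thickness / 2
            nz = data.shape[2]
            z_out = np.arange(got.shape[2]) * increment
            expected = np.zeros_like(got)
            for off in offsets:
                zq = np.clip((z_out + off) / dz, 0, nz - 1)
                i0 = np.floor(zq).astype(int)
                i1 = np.minimum(i0 + 1, nz - 1)
                w = (zq - i0).astype(np.float32)
                expected += data[:, :, i0] * (1 - w) + data[:, :, i1] * w
            expected /= n_sub
            # interior must agree to float tolerance (edges differ only in
            # boundary handling)
            t = int(np.ceil(thickness / dz))
            assert np.allclose(got[:, :, t:-t], expected[:, :, t:-t], atol=1e-5)

    def test_tnc_grid_geometry(self):
        data = np.zeros((4, 4, 240), dtype=np.float32)
        out = resample_slab(data, (0.5, 0.5, 0.2), 3.0, 1.5)
        assert out.shape == (4, 4, 32)  # 47.8 mm span at 1.5 mm increments


class TestCohort:
    def test_length_one(self):
        assert len(v.generate_cohort(1, quiet_spec(), seed=0)) == 1

    def test_same_seed_identical_ground_truth(self):
        specs1 = v.sample_cohort_specs(6, small_spec(), seed=4)
        specs2 = v.sample_cohort_specs(6, small_spec(), seed=4)
        for s1, s2 in zip(specs1, specs2):
            assert s1.seed == s2.seed
            assert s1.calcifications == s2.calcifications
            assert s1.calcium_retention_conv == s2.calcium_retention_conv

    def test_zero_calcium_fraction_binomial_expectation(self):
        """With zero_fraction 0.15 and n=20, ~3 patients carry no calcium."""
        template = small_spec()
        zeros = [sum(len(s.calcifications) == 0
                     for s in v.sample_cohort_specs(20, template, seed=seed,
                                                    zero_fraction=0.15))
                 for seed in range(100)]
        mean = np.mean(zeros)
        sd_of_mean = math.sqrt(20 * 0.15 * 0.85 / 100)
        assert abs(mean - 3.0) < 4 * sd_of_mean

    def test_burden_spans_zero_to_heavy(self):
        specs = v.sample_cohort_specs(30, small_spec(), seed=1)
        totals = [sum(c.true_volume_mm3 for c in s.calcifications) for s in specs]
        assert min(totals) == 0.0
        assert max(totals) > 100.0
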
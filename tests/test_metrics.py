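"""Image-quality metric estimators: visibility, speckle size, resolution,
angular and phase sensitivity, CNR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from phasemct import (
    RoiSpec,
    angular_sensitivity,
    autocorr_fwhm,
    cnr,
    fourier_resolution,
    phase_sensitivity,
    visibility_map,
)


class TestVisibility:
    def test_constant_image_zero(self):
        vm = visibility_map(np.full((64, 64), 3.0))
        assert np.all(vm.values == 0.0)
        assert vm.mean_visibility == 0.0

    def test_checkerboard_formula(self):
        a, b = 2.0, 1.0
        img = np.where(
            (np.indices((64, 64)).sum(axis=0)) % 2 == 0, a, b
        ).astype(float)
        vm = visibility_map(img, window_px=4)  # equal fill per window
        inner = vm.values[10:-10, 10:-10]
        expected = abs(a - b) / (a + b)
        assert np.allclose(inner, expected, rtol=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance(self, scale):
        img = np.random.default_rng(9).uniform(1, 2, (32, 32))
        v1 = visibility_map(img).values
        v2 = visibility_map(scale * img).values
        assert np.allclose(v1, v2, atol=1e-9)

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            visibility_map(np.ones((8, 8)), window_px=2)


class TestAutocorrFwhm:
    def test_white_noise_is_sampling_limited(self, rng):
        assert autocorr_fwhm(rng.normal(0, 1, (256, 256))) <= 2.0

    def test_gaussian_field_matches_analytic_kernel(self, rng):
        """White noise smoothed with a Gaussian of std s has autocorrelation
        std s*sqrt(2), i.e. FWHM = 2.355*s*sqrt(2)."""
        for s in (1.5, 2.5):
            field = ndimage.gaussian_filter(
                rng.normal(0, 1, (512, 512)), s, mode="wrap"
            )
            expected = 2 * np.sqrt(2 * np.log(2)) * s * np.sqrt(2)
            assert autocorr_fwhm(field) == pytest.approx(expected, rel=0.05)

    def test_invariant_to_mean_and_contrast(self, rng):
        field = ndimage.gaussian_filter(rng.normal(0, 1, (256, 256)), 2.0)
        f1 = autocorr_fwhm(field)
        f2 = autocorr_fwhm(5.0 + 3.0 * field)
        assert f1 == pytest.approx(f2, rel=1e-6)

    def test_speckle_size_unit_conversion(self):
        from phasemct import px_to_um

        assert px_to_um(5.82, 1.28) == pytest.approx(7.45, abs=0.005)

    def test_monotone_autocorrelation_rejected(self):
        with pytest.raises(ValueError, match="not resolved"):
            autocorr_fwhm(np.ones((32, 32)))


class TestFourierResolution:
    def test_white_noise_is_noise_limited(self, rng):
        sl = rng.normal(0, 1, (128, 128))
        res, flagged = fourier_resolution(sl, RoiSpec((10, 10), (40, 40)), 1.28)
        assert flagged
        assert res == pytest.approx(2 * 1.28)

    def test_band_limited_slice(self, rng):
        n, f0 = 256, 0.15
        fy = np.fft.fftfreq(n)[:, None]
        fx = np.fft.fftfreq(n)[None, :]
        fr = np.sqrt(fy**2 + fx**2)
        spec = (fr < f0) * np.exp(1j * rng.uniform(0, 2 * np.pi, (n, n)))
        sl = np.real(np.fft.ifft2(spec))
        sl = sl / sl.std() + rng.normal(0, 0.02, (n, n))
        res, flagged = fourier_resolution(sl, RoiSpec((10, 10), (40, 40)), 1.28)
        assert not flagged
        assert res == pytest.approx(1.28 / f0, rel=0.1)

    def test_noise_never_improves_resolution(self, rng):
        n = 256
        base = ndimage.gaussian_filter(rng.normal(0, 1, (n, n)), 2.0)
        base = base / base.std()
        prev = 0.0
        for amp in (0.01, 0.1, 1.0):
            res, _ = fourier_resolution(
                base + rng.normal(0, amp, (n, n)),
                RoiSpec((10, 10), (40, 40)), 1.28,
            )
            # half-percent slack covers the discrete radial-bin jitter of
            # the crossing estimate
            assert res >= prev - 0.05
            prev = res


class TestAngularSensitivity:
    def test_constant_maps_zero(self):
        z = np.full((64, 64), 5e-7)
        sx, sy = angular_sensitivity(z, z, RoiSpec((10, 10), (40, 40)))
        assert sx == pytest.approx(0.0, abs=1e-6)
        assert sy == pytest.approx(0.0, abs=1e-6)

    def test_recovers_planted_noise_level(self):
        r = np.random.default_rng(42)
        sigma = 300e-9  # 300 nrad
        ax = r.normal(0, sigma, (64, 64))
        ay = r.normal(0, sigma, (64, 64))
        sx, sy = angular_sensitivity(ax, ay, RoiSpec((10, 10), (40, 40)))
        assert sx == pytest.approx(300.0, rel=0.05)
        assert sy == pytest.approx(300.0, rel=0.05)

    def test_sample_overlap_rejected(self):
        z = np.zeros((64, 64))
        mask = np.zeros((64, 64), bool)
        mask[20, 20] = True
        with pytest.raises(ValueError, match="overlaps"):
            angular_sensitivity(z, z, RoiSpec((10, 10), (40, 40)), mask)


class TestPhaseSensitivity:
    def test_constant_volume_zero(self):
        vol = np.full((8, 64, 64), 0.33)
        assert phase_sensitivity(vol, RoiSpec((10, 10), (40, 40))) == 0.0

    def test_recovers_planted_noise(self):
        r = np.random.default_rng(11)
        vol = 0.33 + r.normal(0, 0.002, (8, 64, 64))
        est = phase_sensitivity(vol, RoiSpec((5, 5), (40, 40)))
        assert est == pytest.approx(0.002, rel=0.05)

    def test_offset_invariance(self):
        r = np.random.default_rng(2)
        vol = r.normal(0, 0.01, (6, 48, 48))
        roi = RoiSpec((4, 4), (40, 40))
        assert phase_sensitivity(vol + 5.0, roi) == pytest.approx(
            phase_sensitivity(vol, roi)
        )

    def test_small_roi_warns(self):
        vol = np.random.default_rng(0).normal(0, 1, (1, 32, 32))
        with pytest.warns(UserWarning, match="1000"):
            phase_sensitivity(vol, RoiSpec((2, 2), (10, 10)))


class TestCnr:
    def test_equal_means_give_zero(self, rng):
        img = rng.normal(5.0, 1.0, (64, 64))
        val = cnr(img, RoiSpec((4, 4), (20, 20)), RoiSpec((40, 40), (20, 20)))
        assert val < 0.5

    def test_direct_arithmetic(self):
        img = np.zeros((64, 64))
        img[:20, :20] = 10.0
        img[40:, 40:] = 4.0 + np.tile([1.0, -1.0, 3.0, -3.0], 6 * 24).reshape(
            24, 24
        )[: 24, : 24]
        sig = RoiSpec((0, 0), (20, 20), "signal")
        bg = RoiSpec((40, 40), (20, 20), "background")
        bg_vals = img[40:, 40:]
        expected = abs(10.0 - bg_vals.mean()) / bg_vals.std()
        assert cnr(img, sig, bg) == pytest.approx(expected)

    def test_monte_carlo_recovers_planted_cnr(self):
        """Planted means and noise: estimates across 100 seeds agree with the
        planted CNR within 10% (mean over seeds)."""
        planted = 3.0
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            img = r.normal(4.0, 2.0, (96, 96))
            img[8:48, 8:48] += planted * 2.0  # signal = bg + cnr*sigma
            vals.append(cnr(img, RoiSpec((8, 8), (40, 40)),
                            RoiSpec((50, 50), (40, 40))))
        assert np.mean(vals) == pytest.approx(planted, rel=0.1)
        assert np.std(vals) < 0.5

    def test_overlapping_rois_rejected(self):
        img = np.random.default_rng(0).normal(0, 1, (64, 64))
        with pytest.raises(ValueError, match="disjoint"):
            cnr(img, RoiSpec((0, 0), (40, 40)), RoiSpec((20, 20), (40, 40)))

    def test_zero_background_sd_rejected(self):
        img = np.zeros((64, 64))
        img[:20, :20] = 1.0
        with pytest.raises(ValueError, match="zero"):
            cnr(img, RoiSpec((0, 0), (16, 16)), RoiSpec((40, 40), (16, 16)))
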
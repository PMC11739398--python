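"""Windowed pattern matching and displacement-to-phase conversions."""

import numpy as np
import pytest
from scipy import ndimage

from phasemct import (
    BeamConfig,
    DetectorModel,
    MatchConfig,
    ScanGeometry,
    angles_to_dpc,
    displacements_to_angles,
    umpa_match,
)
from phasemct.mbi import RefractionAngleMap
from tests.conftest import fourier_shift


def brute_force_minimiser(sample, reference, half, radius, darkfield=True):
    """Per-pixel exhaustive search replicating the matcher's cost model.

    Windows and shifts are evaluated on the periodic grid with explicit
    modulo indexing; kept free of the vectorised implementation.
    """
    n_steps, h, w = sample.shape
    ref_mean = reference.mean(axis=0)
    uy = np.zeros((h, w))
    ux = np.zeros((h, w))
    offs = [(a, b) for a in range(-half, half + 1)
            for b in range(-half, half + 1)]
    cands = [(a, b) for a in range(-radius, radius + 1)
             for b in range(-radius, radius + 1)]
    for r in range(h):
        for c in range(w):
            best = None
            arg = (0, 0)
            for cy, cx in cands:
                aa = e = cross = rr = g = 0.0
                for wy, wx in offs:
                    rr_i = (r + wy) % h
                    cc_i = (c + wx) % w
                    rs_i = (r + wy - cy) % h
                    cs_i = (c + wx - cx) % w
                    a_val = ref_mean[rs_i, cs_i]
                    for mstep in range(n_steps):
                        s = sample[mstep, rr_i, cc_i]
                        rv = reference[mstep, rs_i, cs_i]
                        aa += a_val * a_val
                        e += a_val * s
                        cross += rv * s
                        rr += rv * rv
                        g += s * s
                f = cross - e
                cc_var = rr - aa
                if darkfield:
                    p = e / max(aa, 1e-300)
                    if cc_var > 1e-12 * max(rr, 1e-300):
                        q = f / cc_var
                    else:
                        q = p
                    cost = g - p * e - q * f
                else:
                    t = cross / max(rr, 1e-300)
                    cost = g - t * cross
                if best is None or cost < best:
                    best = cost
                    arg = (cy, cx)
            uy[r, c], ux[r, c] = arg
    return uy, ux


class TestUmpaMatch:
    def test_identity_recovers_trivial_solution(self, speckle_stack):
        mm = umpa_match(speckle_stack, speckle_stack, MatchConfig())
        assert np.allclose(mm.T, 1.0)
        assert np.all(mm.u_x == 0.0) and np.all(mm.u_y == 0.0)
        assert np.allclose(mm.D, 1.0)
        assert np.allclose(mm.residual, 0.0, atol=1e-8)

    def test_integer_shift_and_transmission(self, speckle_stack):
        sample = 0.8 * np.roll(speckle_stack, (2, 0), axis=(1, 2))
        mm = umpa_match(sample, speckle_stack,
                        MatchConfig(search_radius_px=3))
        assert np.abs(mm.T - 0.8).max() < 1e-3
        assert np.abs(mm.u_y - 2.0).max() < 0.05
        assert np.abs(mm.u_x).max() < 0.05
        assert np.abs(mm.D - 1.0).max() < 0.01

    def test_blur_reduces_darkfield_by_modulation_ratio(self, speckle_stack):
        blurred = np.stack([
            ndimage.gaussian_filter(f, 1.0, mode="wrap") for f in speckle_stack
        ])
        fluct_ref = speckle_stack - speckle_stack.mean(axis=0)
        fluct_blur = blurred - blurred.mean(axis=0)
        ratio = fluct_blur.std() / fluct_ref.std()
        mm = umpa_match(blurred, speckle_stack, MatchConfig())
        inner = np.s_[8:-8, 8:-8]
        assert mm.D[inner].mean() == pytest.approx(ratio, abs=0.05)
        assert np.abs(mm.u_x[inner]).mean() < 0.1

    def test_discrete_minimiser_equals_brute_force(self, rng):
        master = ndimage.gaussian_filter(
            rng.uniform(0.5, 1.5, (32, 32)), 1.0, mode="wrap"
        )
        ref = np.stack([np.roll(master, (2 * i, 5 * i), axis=(0, 1))
                        for i in range(4)])
        sample = 0.9 * np.stack([
            ndimage.shift(f, (0.8, -1.3), order=3, mode="grid-wrap")
            for f in ref
        ]) + rng.normal(0, 0.002, (4, 32, 32))
        mm = umpa_match(sample, ref, MatchConfig(search_radius_px=3))
        uy, ux = brute_force_minimiser(sample, ref, half=1, radius=3)
        assert np.array_equal(mm.u_int_y, uy)
        assert np.array_equal(mm.u_int_x, ux)

    def test_subpixel_shift_recovery_noise_free(self, tai_reference_stack):
        ref = tai_reference_stack.astype(float)
        inner = np.s_[8:-8, 8:-8]
        sq = []
        for sy, sx in [(-1.7, 0.4), (-0.6, -0.25), (0.35, 0.4),
                       (1.25, -1.1), (0.05, 1.9)]:
            sample = fourier_shift(ref, sy, sx)
            mm = umpa_match(sample, ref, MatchConfig())
            sq.append(((mm.u_y[inner] - sy) ** 2
                       + (mm.u_x[inner] - sx) ** 2).mean())
        assert np.sqrt(np.mean(sq)) <= 0.1

    def test_subpixel_shift_recovery_with_noise(self, tai_reference_stack):
        ref = tai_reference_stack.astype(float)
        noise_rng = np.random.default_rng(17)
        inner = np.s_[8:-8, 8:-8]
        sq = []
        for sy, sx in [(-1.3, 0.6), (0.45, -0.2), (1.8, 1.1)]:
            sample = noise_rng.poisson(
                np.clip(fourier_shift(ref, sy, sx), 1, None)
            ).astype(float)
            noisy_ref = noise_rng.poisson(np.clip(ref, 1, None)).astype(float)
            mm = umpa_match(sample, noisy_ref, MatchConfig())
            sq.append(((mm.u_y[inner] - sy) ** 2
                       + (mm.u_x[inner] - sx) ** 2).mean())
        assert np.sqrt(np.mean(sq)) <= 0.2

    def test_more_steps_does_not_hurt(self, rng):
        r = np.random.default_rng(5)
        master = ndimage.gaussian_filter(r.uniform(0.5, 1.5, (64, 64)), 1.3,
                                         mode="wrap")
        full = np.stack([np.roll(master, (3 * i, 5 * i), axis=(0, 1))
                         for i in range(16)])
        inner = np.s_[8:-8, 8:-8]
        errs = {}
        for n_steps in (4, 16):
            ref = full[:n_steps]
            sample = fourier_shift(ref, 0.6, -0.8)
            mm = umpa_match(sample, ref, MatchConfig())
            errs[n_steps] = np.sqrt(((mm.u_y[inner] - 0.6) ** 2
                                     + (mm.u_x[inner] + 0.8) ** 2).mean())
        assert errs[16] <= errs[4] + 1e-6

    def test_transmission_of_pure_absorber(self, tai_reference_stack):
        ref = tai_reference_stack.astype(float)
        mm = umpa_match(0.63 * ref, ref, MatchConfig())
        inner = np.s_[8:-8, 8:-8]
        assert np.abs(mm.T[inner] - 0.63).max() <= 0.01

    def test_darkfield_off(self, speckle_stack):
        mm = umpa_match(speckle_stack, speckle_stack,
                        MatchConfig(estimate_darkfield=False))
        assert np.all(mm.D == 1.0)

    def test_shape_mismatch_rejected(self, speckle_stack):
        with pytest.raises(ValueError):
            umpa_match(speckle_stack[:, :40], speckle_stack, MatchConfig())


class TestConversions:
    det = DetectorModel()
    geom = ScanGeometry(z_prop_m=0.175)
    beam = BeamConfig(20.0)

    def test_zero_displacement_zero_angle(self):
        z = np.zeros((4, 4))
        ang = displacements_to_angles((z, z), self.det, self.geom)
        assert np.all(ang.alpha_x == 0)

    def test_one_pixel_displacement(self):
        u = np.ones((2, 2))
        ang = displacements_to_angles((u, u), self.det, self.geom)
        # 1.28 um / 175 mm = 7.314 urad
        assert ang.alpha_x[0, 0] == pytest.approx(7.3143e-6, rel=1e-3)

    def test_angle_halves_when_distance_doubles(self):
        u = np.ones((2, 2))
        a1 = displacements_to_angles((u, u), self.det, self.geom, z_eff_m=0.175)
        a2 = displacements_to_angles((u, u), self.det, self.geom, z_eff_m=0.35)
        assert np.allclose(a1.alpha_x, 2 * a2.alpha_x)

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            displacements_to_angles((np.ones((2, 2)),) * 2, self.det,
                                    self.geom, z_eff_m=-1.0)

    def test_dpc_value_and_linearity(self):
        alpha = RefractionAngleMap(
            alpha_x=np.full((2, 2), 7.314e-6), alpha_y=np.zeros((2, 2))
        )
        gx, gy = angles_to_dpc(alpha, self.beam)
        assert gx[0, 0] == pytest.approx(
            self.beam.wavenumber * 7.314e-6, rel=1e-9
        )
        alpha2 = RefractionAngleMap(2 * alpha.alpha_x, 2 * alpha.alpha_y)
        gx2, _ = angles_to_dpc(alpha2, self.beam)
        assert np.allclose(gx2, 2 * gx)
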
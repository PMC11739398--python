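"""Virtual beamline: screens, phantom, propagation, frame and scan simulation."""

import dataclasses

import numpy as np
import pytest

from phasemct import (
    BeamConfig,
    DetectorModel,
    ScanConfig,
    ScanGeometry,
    fresnel_propagate,
    make_placenta_phantom,
    make_sandpaper_screen,
    make_tai_screen,
    project_phantom,
    simulate_frame,
    simulate_scan,
    spiral_pattern,
    tilted_grid_pattern,
)
from phasemct.metrics import autocorr_fwhm, visibility_map
from phasemct.physics import OpticalConstants
from phasemct.synthetic import Phantom, load_scan, save_scan


class TestTaiScreen:
    def test_etched_fraction_matches_duty_cycle(self):
        scr = make_tai_screen(duty_cycle=1 / 3, shape_px=(512, 512))
        assert scr.params["etched_fraction"] == pytest.approx(1 / 3, abs=0.02)
        assert set(np.unique(scr.thickness_map_um)) == {0.0, 17.0}

    def test_design_phase_shift(self):
        scr = make_tai_screen()
        assert scr.peak_phase_shift(BeamConfig(20.0)) == pytest.approx(
            2 * np.pi / 3, rel=0.02
        )

    def test_zero_etch_is_uniform(self):
        scr = make_tai_screen(etch_depth_um=0.0, shape_px=(64, 64))
        assert scr.peak_phase_shift(BeamConfig(20.0)) == 0.0
        assert np.all(scr.thickness_map_um == 0.0)

    def test_undersampled_period_rejected(self):
        with pytest.raises(ValueError, match="under-sampled"):
            make_tai_screen(period_um=2.0, pixel_um=1.28)


class TestSandpaperScreen:
    def test_deterministic_under_seed(self):
        a = make_sandpaper_screen(seed=5, shape_px=(128, 128))
        b = make_sandpaper_screen(seed=5, shape_px=(128, 128))
        assert np.array_equal(a.thickness_map_um, b.thickness_map_um)

    def test_zero_layers_gives_flat_screen(self):
        scr = make_sandpaper_screen(n_layers=0, shape_px=(64, 64))
        assert np.all(scr.thickness_map_um == 0.0)

    def test_speckle_coarser_than_tai_pattern(self):
        """Simulated sandpaper speckle is larger than the TAI self-image."""
        beam = BeamConfig(20.0)
        det = DetectorModel(shape_px=(256, 256))
        geom = ScanGeometry()
        tai = simulate_frame(geom, beam, det,
                             screen=make_tai_screen(shape_px=(256, 256)))
        sand = simulate_frame(geom, beam, det,
                              screen=make_sandpaper_screen(shape_px=(256, 256)))
        assert autocorr_fwhm(sand) > autocorr_fwhm(tai)


class TestPhantom:
    def test_deterministic(self):
        a = make_placenta_phantom((48, 48, 48), seed=3)
        b = make_placenta_phantom((48, 48, 48), seed=3)
        assert np.array_equal(a.label_volume, b.label_volume)

    def test_ground_truth_from_materials(self):
        ph = make_placenta_phantom((32, 32, 32), seed=1, edge_taper_vox=0)
        lab = ph.label_volume
        for label, mat in ph.materials.items():
            sel = lab == label
            if sel.any():
                assert np.allclose(ph.ground_truth_delta[sel], mat.delta)

    def test_materials_physically_ordered(self):
        ph = make_placenta_phantom((32, 32, 32))
        d_tis = ph.materials[2].delta
        d_par = ph.materials[1].delta
        assert d_tis > d_par > 0

    def test_too_large_rejected(self):
        with pytest.raises(ValueError):
            make_placenta_phantom((600, 600, 600))


def _sphere_phantom(n=64, r=20.0, delta=1e-6, beta=1e-9, nz=None):
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lab = np.zeros((nz or n, n, n), dtype=np.uint8)
    c = (n - 1) / 2
    lab[:, (yy - c) ** 2 + (xx - c) ** 2 <= r**2] = 1
    return Phantom(
        voxel_um=1.0,
        label_volume=lab,
        materials={0: OpticalConstants("air", 0, 0),
                   1: OpticalConstants("m", delta, beta)},
    )


class TestProjection:
    def test_empty_phantom_projects_zero(self):
        ph = Phantom(voxel_um=1.0, label_volume=np.zeros((4, 8, 8), np.uint8),
                     materials={0: OpticalConstants("air", 0, 0)})
        d, b = project_phantom(ph, 30.0)
        assert np.all(d == 0) and np.all(b == 0)

    def test_chord_length_of_cylinder(self):
        ph = _sphere_phantom(nz=4)
        d, _ = project_phantom(ph, 0.0)
        c = (64 - 1) / 2
        for b in [0, 10, 15]:
            col = int(round(c + b))
            b_actual = col - c  # impact parameter of this pixel column
            expect = 2 * np.sqrt(20.0**2 - b_actual**2) * 1e-6 * 1e-6
            assert d[2, col] == pytest.approx(expect, abs=1.2e-6 * 1e-6)

    def test_mirror_symmetry_0_180(self):
        ph = _sphere_phantom(nz=4)
        d0, _ = project_phantom(ph, 0.0)
        d180, _ = project_phantom(ph, 180.0)
        assert np.allclose(d0, d180[:, ::-1], atol=1e-3 * d0.max())


class TestFresnel:
    beam = BeamConfig(20.0)

    def test_zero_distance_is_identity(self, rng):
        f = np.exp(1j * rng.normal(0, 0.2, (32, 32)))
        out = fresnel_propagate(f, 0.0, self.beam, 1.28)
        assert np.array_equal(out, f)

    def test_plane_wave_unchanged(self):
        f = np.ones((64, 64), complex)
        out = fresnel_propagate(f, 0.175, self.beam, 1.28)
        assert np.allclose(np.abs(out) ** 2, 1.0, atol=1e-9)

    def test_energy_conservation(self, rng):
        f = np.exp(1j * rng.normal(0, 0.5, (64, 64))) * rng.uniform(
            0.5, 1.5, (64, 64)
        )
        out = fresnel_propagate(f, 0.05, self.beam, 1.28)
        before = (np.abs(f) ** 2).sum()
        after = (np.abs(out) ** 2).sum()
        assert after == pytest.approx(before, rel=1e-6)

    def test_aliasing_guard(self):
        f = np.ones((32, 32), complex)
        with pytest.raises(ValueError, match="pad"):
            fresnel_propagate(f, 10.0, self.beam, 1.28)

    def test_sinusoidal_grating_peak_at_quarter_talbot(self):
        """Weak sinusoidal phase grating: modulation peaks at z_T/4 = p^2/(2 lambda),
        with intensity amplitude 2*phi and the grating period preserved."""
        p_um, px, n = 7.0, 0.4375, 512
        x = np.arange(n) * px
        field = np.tile(np.exp(0.1j * np.sin(2 * np.pi * x / p_um)), (384, 1))
        z_quarter = (p_um * 1e-6) ** 2 / (2 * self.beam.wavelength_m)
        zs = np.linspace(0.2, 2.0, 19) * z_quarter
        vis = []
        for z in zs:
            out = fresnel_propagate(field, z, self.beam, px)
            i = np.abs(out[0]) ** 2
            vis.append(i.std() / i.mean())
        assert zs[int(np.argmax(vis))] == pytest.approx(z_quarter, rel=0.06)
        out = fresnel_propagate(field, z_quarter, self.beam, px)
        i = np.abs(out[0]) ** 2
        assert (i.max() - i.min()) / 2 == pytest.approx(0.2, rel=0.02)
        spec = np.abs(np.fft.rfft(i - i.mean()))
        f_peak = np.fft.rfftfreq(n, d=px)[np.argmax(spec)]
        assert 1 / f_peak == pytest.approx(p_um, rel=0.05)


class TestSimulateFrame:
    beam = BeamConfig(20.0)

    def test_flat_frame_is_uniform(self):
        det = DetectorModel(shape_px=(32, 32), photons_per_px=5000.0)
        img = simulate_frame(ScanGeometry(), self.beam, det)
        assert np.allclose(img, 5000.0, rtol=1e-9)

    def test_absorption_only_beer_lambert_at_zero_distance(self):
        det = DetectorModel(shape_px=(64, 64), psf_fwhm_px=0.0,
                            psf_halo_frac=0.0, photons_per_px=1.0)
        geom = ScanGeometry(z_prop_m=1e-9)
        ph = _sphere_phantom(delta=0.0)
        ph = dataclasses.replace(ph, voxel_um=1.28)
        img = simulate_frame(geom, self.beam, det, phantom=ph)
        _, bt = project_phantom(ph, 0.0)
        expect = np.exp(-2 * self.beam.wavenumber * bt)
        assert np.allclose(img, expect, atol=1e-4)

    def test_pure_phase_invisible_without_propagation(self):
        det = DetectorModel(shape_px=(64, 64), psf_fwhm_px=0.0,
                            psf_halo_frac=0.0, photons_per_px=1.0)
        geom = ScanGeometry(z_prop_m=1e-12)
        ph = _sphere_phantom(delta=1e-6, beta=0.0)
        ph = dataclasses.replace(ph, voxel_um=1.28)
        img = simulate_frame(geom, self.beam, det, phantom=ph)
        assert img.std() / img.mean() < 1e-6

    def test_tai_reference_has_stable_visibility(self, tai_reference_stack):
        vis = [visibility_map(f).mean_visibility for f in tai_reference_stack]
        assert min(vis) > 0.05
        assert np.std(vis) / np.mean(vis) < 0.05


class TestSimulateScan:
    def _config(self, **kw):
        from phasemct.synthetic import make_tai_screen, tilted_grid_pattern

        det = DetectorModel(shape_px=(48, 48), n_dark=3)
        geom = ScanGeometry(n_angles=kw.pop("n_angles", 2))
        screen = make_tai_screen(shape_px=(48, 48))
        stepping = tilted_grid_pattern(kw.pop("n_steps", 4))
        return ScanConfig(
            geometry=geom, detector=det, screen=screen, stepping=stepping,
            phantom=None, noise=kw.pop("noise", False), n_ref_per_step=2, **kw
        )

    def test_deterministic_under_seed(self):
        a = simulate_scan(self._config(noise=True, seed=9))
        b = simulate_scan(self._config(noise=True, seed=9))
        assert np.array_equal(a.sample.frames, b.sample.frames)
        assert np.array_equal(a.reference.frames, b.reference.frames)

    def test_step_mean_is_smoother_than_single_frame(self):
        scan = simulate_scan(self._config(n_steps=16))
        refs = scan.reference.frames[:, 0].astype(float)
        mean_vis = visibility_map(refs.mean(axis=0)).mean_visibility
        single_vis = visibility_map(refs[0]).mean_visibility
        assert mean_vis < single_vis

    def test_noiseless_references_identical_within_step(self):
        scan = simulate_scan(self._config())
        assert np.array_equal(scan.reference.frames[:, 0],
                              scan.reference.frames[:, 1])

    def test_stepping_offsets_distinct(self):
        assert tilted_grid_pattern(16).n_steps == 16
        assert spiral_pattern(20).n_steps == 20

    def test_hdf5_roundtrip(self, tmp_path):
        scan = simulate_scan(self._config())
        path = str(tmp_path / "scan.h5")
        save_scan(scan, path)
        back = load_scan(path)
        assert np.allclose(back["sample"], scan.sample.frames)
        assert np.allclose(back["reference"], scan.reference.frames)
        assert back["attrs"]["pixel_um"] == pytest.approx(1.28)
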
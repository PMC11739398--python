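"""Shared fixtures: small simulated stacks and helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage


def fourier_shift(arr: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Exact periodic translation of the last two axes (content moves +d)."""
    fy = np.fft.fftfreq(arr.shape[-2])[:, None]
    fx = np.fft.fftfreq(arr.shape[-1])[None, :]
    ramp = np.exp(-2j * np.pi * (fy * dy + fx * dx))
    return np.real(
        np.fft.ifft2(np.fft.fft2(arr, axes=(-2, -1)) * ramp, axes=(-2, -1))
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def speckle_stack():
    """Smooth random reference stack (n_steps, 80, 80), band-limited."""
    r = np.random.default_rng(7)
    master = ndimage.gaussian_filter(r.uniform(0.5, 1.5, (80, 80)), 1.2,
                                     mode="wrap")
    return np.stack([np.roll(master, (3 * i, 7 * i), axis=(0, 1))
                     for i in range(8)])


@pytest.fixture(scope="session")
def tai_reference_stack():
    """Simulated TAI reference stack at detector conditions (noise-free)."""
    from phasemct import BeamConfig, DetectorModel, ScanGeometry, simulate_frame
    from phasemct.synthetic import make_tai_screen, tilted_grid_pattern

    beam = BeamConfig(20.0)
    det = DetectorModel(shape_px=(96, 96))
    geom = ScanGeometry(n_angles=1)
    screen = make_tai_screen(shape_px=(96, 96))
    stepping = tilted_grid_pattern(8)
    frames = np.stack([
        simulate_frame(geom, beam, det, screen=screen, screen_offset_px=off)
        for off in stepping.offsets_px
    ])
    return frames


@pytest.fixture(scope="session")
def tiny_tai_scan():
    """Complete small MBI scan with phantom ground truth (noise-free)."""
    from phasemct import simulate_scan
    from phasemct.pipeline import build_scan_config, make_config

    cfg = make_config(detector_px=64, n_angles=3, n_steps_tai=8,
                      n_steps_sandpaper=8, noise=False, phantom_vox=64)
    return simulate_scan(build_scan_config(cfg, "mbi_tai"))
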
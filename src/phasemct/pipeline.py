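"""End-to-end orchestration: simulate -> preprocess -> retrieve -> reconstruct.

`run_experiment` executes the three-arm comparison (MBI with a TAI grating,
MBI with sandpaper, PBI) on the same phantom and seed, reconstructs aligned
delta volumes, and collects the quality-metric report with one row per arm.
Individual stages are exposed as functions so the CLI and tests can run them
separately.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocessing as prep
from .integration import (
    GradientField,
    PhaseProjection,
    border_mask,
    detrend_dpc,
    detrend_phase,
    fourier_integrate,
)
from .mbi import MatchConfig, MultiModalProjection, displacements_to_angles, angles_to_dpc
from .metrics import (
    MetricsReport,
    RoiSpec,
    autocorr_fwhm,
    cnr,
    fourier_resolution,
    phase_sensitivity,
    visibility_map,
)
from .pbi import PaganinConfig, paganin_filter
from .physics import BeamConfig
from .synthetic import (
    DetectorModel,
    Phantom,
    ScanConfig,
    ScanGeometry,
    ScanResult,
    make_placenta_phantom,
    make_sandpaper_screen,
    make_tai_screen,
    simulate_scan,
    spiral_pattern,
    tilted_grid_pattern,
)
from .tomography import ReconVolume, Sinogram, delta_to_electron_density, fbp_reconstruct, ring_filter

# Sign relating the integrated differential-phase signal to the object
# phase delay Phi = +k*integral(delta).  The matcher reports the apparent
# pattern displacement, which with this propagator's conventions points down
# the gradient of the phase *delay* (rays bend toward larger optical path),
# so the integrated signal is -Phi.  Fixed here once and verified against
# simulator ground truth in the test suite.
PHASE_SIGN = -1.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Scaled-down three-arm experiment configuration.

    Defaults reproduce the study conditions at desk scale: 20 keV beam,
    1.28 um pixels, TAI (7 um period, 2pi/3 phase) vs 6-layer sandpaper
    modulators, z = 175 mm (MBI) / 93 mm (PBI), 180 degree parallel-beam
    scan.  The `fullscale` preset carries the full-size acquisition counts.
    """

    seed: int = 0
    energy_keV: float = 20.0
    pixel_um: float = 1.28
    detector_px: int = 128
    n_angles: int = 181
    n_steps_tai: int = 16
    n_steps_sandpaper: int = 20
    z_mbi_m: float = 0.175
    z_pbi_m: float = 0.093
    z0_m: float = 0.115
    psf_fwhm_px: float = 1.67
    # photon budget calibrated so the simulated angular sensitivity falls
    # in the few-hundred-nanoradian regime measured on the real system,
    # absorbing unmodelled noise sources (vibrations, beam instability)
    photons_per_px: float = 250.0
    noise: bool = False
    phantom_vox: int | None = None  # default: detector_px
    drift_total_px: tuple[float, float] = (0.0, 0.0)
    match: MatchConfig = field(default_factory=MatchConfig)
    gamma_pbi: float = 202.43
    ring: tuple[float, float, int] | None = None
    roi_px: int = 40
    arms: tuple[str, ...] = ("mbi_tai", "mbi_sandpaper", "pbi")
    drift_correction: bool = False

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["match"] = dataclasses.asdict(self.match)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


PRESETS: dict[str, dict] = {
    "smoke": dict(detector_px=64, n_angles=45, n_steps_tai=4,
                  n_steps_sandpaper=4, roi_px=12),
    "benchmark": dict(detector_px=128, n_angles=181, n_steps_tai=16,
                      n_steps_sandpaper=20, noise=True, roi_px=24),
    # acquisition counts of a full synchrotron campaign (3001 views, full
    # stepping); not meant to be run on a workstation
    "fullscale": dict(detector_px=512, n_angles=3001, n_steps_tai=16,
                      n_steps_sandpaper=20, noise=True),
}


def make_config(preset: str | None = None, **overrides) -> ExperimentConfig:
    kwargs: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}; know {sorted(PRESETS)}")
        kwargs.update(PRESETS[preset])
    kwargs.update(overrides)
    return ExperimentConfig(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment configuration from YAML, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    preset = raw.pop("preset", None)
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "match" in raw:
        raw["match"] = MatchConfig(**raw["match"])
    if "drift_total_px" in raw:
        raw["drift_total_px"] = tuple(raw["drift_total_px"])
    if "ring" in raw and raw["ring"] is not None:
        raw["ring"] = tuple(raw["ring"])
    if "arms" in raw:
        raw["arms"] = tuple(raw["arms"])
    return make_config(preset, **raw)


# ---------------------------------------------------------------------------
# arm assembly
# ---------------------------------------------------------------------------


def _phantom(cfg: ExperimentConfig) -> Phantom:
    n = cfg.phantom_vox or cfg.detector_px
    return make_placenta_phantom(
        shape_vox=(n, n, n), voxel_um=cfg.pixel_um, seed=cfg.seed,
        energy_keV=cfg.energy_keV,
    )


def build_scan_config(
    cfg: ExperimentConfig, arm: str, phantom: Phantom | None = None
) -> ScanConfig:
    """Assemble the simulator configuration for one arm of the comparison."""
    beam = BeamConfig(cfg.energy_keV)
    det = DetectorModel(
        pixel_um=cfg.pixel_um,
        shape_px=(cfg.detector_px, cfg.detector_px),
        psf_fwhm_px=cfg.psf_fwhm_px,
        photons_per_px=cfg.photons_per_px,
    )
    if phantom is None:
        phantom = _phantom(cfg)
    shape = det.shape_px
    if arm == "mbi_tai":
        screen = make_tai_screen(
            pixel_um=cfg.pixel_um, shape_px=shape, energy_keV=cfg.energy_keV
        )
        stepping = tilted_grid_pattern(cfg.n_steps_tai, pixel_um=cfg.pixel_um)
        z = cfg.z_mbi_m
    elif arm == "mbi_sandpaper":
        screen = make_sandpaper_screen(
            pixel_um=cfg.pixel_um, shape_px=shape, energy_keV=cfg.energy_keV,
            seed=cfg.seed,
        )
        stepping = spiral_pattern(cfg.n_steps_sandpaper)
        z = cfg.z_mbi_m
    elif arm == "pbi":
        screen, stepping, z = None, None, cfg.z_pbi_m
    else:
        raise ValueError(f"unknown arm {arm!r}")
    geom = ScanGeometry(z_prop_m=z, z0_m=cfg.z0_m, n_angles=cfg.n_angles)
    return ScanConfig(
        beam=beam, geometry=geom, detector=det, screen=screen,
        stepping=stepping, phantom=phantom, noise=cfg.noise,
        drift_total_px=cfg.drift_total_px, seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# stage functions
# ---------------------------------------------------------------------------


@dataclass
class CorrectedScan:
    """Dark/profile-corrected sample and reference stacks."""

    sample: np.ndarray  # (step, angle, rows, cols)
    reference: np.ndarray  # (step, rows, cols) - mean reference per step
    pixel_um: float


def preprocess_scan(
    scan: ScanResult, correction: prep.CorrectionConfig | None = None
) -> CorrectedScan:
    """Dark-subtract, beam-profile-normalise and repair all frames.

    The beam profile is the low-pass-filtered mean of the reference frames;
    dividing by it (rather than by the structured flat) preserves the
    modulation pattern that the matcher tracks.
    """
    correction = correction or prep.CorrectionConfig()
    dark_mean = scan.dark.frames[0].mean(axis=0).astype(np.float64)
    refs = scan.reference.frames.astype(np.float64) - dark_mean
    profile = prep.estimate_beam_profile(
        refs.reshape(-1, *refs.shape[2:]), correction.beamprofile_kernel_px
    )
    ref_mean = refs.mean(axis=1) / profile
    n_steps, n_angles = scan.sample.frames.shape[:2]
    sample = np.empty(scan.sample.frames.shape, dtype=np.float32)
    for s in range(n_steps):
        for j in range(n_angles):
            frame = (scan.sample.frames[s, j].astype(np.float64) - dark_mean) / profile
            sample[s, j] = prep.replace_bad_pixels(frame, correction.badpixel_sigma)
    for s in range(n_steps):
        ref_mean[s] = prep.replace_bad_pixels(ref_mean[s], correction.badpixel_sigma)
    return CorrectedScan(
        sample=sample, reference=ref_mean.astype(np.float32),
        pixel_um=scan.sample.detector.pixel_um,
    )


@dataclass
class MbiProjections:
    """Per-angle multimodal retrieval of one MBI scan."""

    phi: np.ndarray  # (angle, rows, cols) object phase delay, rad
    T: np.ndarray
    alpha_x: np.ndarray
    alpha_y: np.ndarray
    angles_deg: np.ndarray
    pixel_um: float


def retrieve_mbi_scan(
    scan: ScanResult,
    match: MatchConfig = MatchConfig(),
    correction: prep.CorrectionConfig | None = None,
    z_eff_m: float | None = None,
    drift_correction: bool = False,
) -> MbiProjections:
    """Full MBI retrieval: match, convert, detrend, integrate per angle."""
    corr = preprocess_scan(scan, correction)
    beam = BeamConfig(20.0)
    geom, det = scan.sample.geometry, scan.sample.detector
    n_steps, n_angles = corr.sample.shape[:2]
    shape = corr.sample.shape[2:]
    margin = match.search_radius_px + match.window_half_px + 1
    mask = border_mask(shape, max(8, margin + 4), sides="lr")

    phi = np.empty((n_angles, *shape), dtype=np.float32)
    t_maps = np.empty_like(phi)
    ax_maps = np.empty_like(phi)
    ay_maps = np.empty_like(phi)
    ref_stack = corr.reference.astype(np.float64)
    shift_cache: dict = {}
    for j in range(n_angles):
        sample_stack = corr.sample[:, j].astype(np.float64)
        refs = ref_stack
        cache = shift_cache
        if drift_correction:
            refs = np.stack([
                prep.correct_drift(sample_stack[s], ref_stack[s])[0]
                for s in range(n_steps)
            ])
            cache = None  # drift-matched references vary per angle
        mm = _match(sample_stack, refs, match, cache)
        angles = displacements_to_angles(mm, det, geom, z_eff_m=z_eff_m)
        gx, gy = angles_to_dpc(angles, beam)
        grad = detrend_dpc(
            GradientField(gx=gx, gy=gy, pixel_um=det.pixel_um), mask
        )
        ph = fourier_integrate(grad)
        ph = detrend_phase(ph, mask)
        phi[j] = PHASE_SIGN * ph.phi
        t_maps[j] = mm.T
        ax_maps[j] = angles.alpha_x
        ay_maps[j] = angles.alpha_y
    return MbiProjections(
        phi=phi, T=t_maps, alpha_x=ax_maps, alpha_y=ay_maps,
        angles_deg=scan.ground_truth["angles_deg"], pixel_um=det.pixel_um,
    )


def _match(sample_stack, reference_stack, match, shift_cache=None):
    from .mbi import umpa_match

    return umpa_match(sample_stack, reference_stack, match,
                      shift_cache=shift_cache)


@dataclass
class PbiProjections:
    phi: np.ndarray  # (angle, rows, cols) object phase delay, rad
    angles_deg: np.ndarray
    pixel_um: float


def retrieve_pbi_scan(
    scan: ScanResult, paganin: PaganinConfig | None = None
) -> PbiProjections:
    """Flat-correct and Paganin-filter every PBI projection."""
    det, geom = scan.sample.detector, scan.sample.geometry
    if paganin is None:
        paganin = PaganinConfig(z_m=geom.z_prop_m, pixel_um=det.pixel_um)
    dark_mean = scan.dark.frames[0].mean(axis=0).astype(np.float64)
    flat_mean = scan.reference.frames[0].mean(axis=0).astype(np.float64)
    n_angles = scan.sample.frames.shape[1]
    phi = np.empty((n_angles, *scan.sample.frames.shape[2:]), dtype=np.float32)
    k = BeamConfig(paganin.energy_keV).wavenumber
    delta = paganin.resolved_delta()
    for j in range(n_angles):
        ratio = prep.correct_dark_flat(
            scan.sample.frames[0, j].astype(np.float64), dark_mean, flat_mean
        )
        ratio = prep.replace_bad_pixels(ratio)
        ratio = np.clip(ratio, 1e-6, None)
        res = paganin_filter(ratio, paganin)
        # object phase delay of the retrieved thickness
        phi[j] = k * delta * res.thickness_m
    return PbiProjections(
        phi=phi, angles_deg=scan.ground_truth["angles_deg"], pixel_um=det.pixel_um
    )


def reconstruct_delta(
    phi_stack: np.ndarray,
    angles_deg: np.ndarray,
    pixel_um: float,
    beam: BeamConfig,
    ring: tuple[float, float, int] | None = None,
) -> ReconVolume:
    """Phase projections -> delta volume (sinogram scaling Phi/k per path)."""
    sino = np.asarray(phi_stack, dtype=np.float64) / beam.wavenumber
    sino = np.transpose(sino, (0, 1, 2))  # (angle, row, col)
    if ring is not None:
        low, high, order = ring
        for r in range(sino.shape[1]):
            s = Sinogram(sino[:, r, :], angles_deg, pixel_um)
            sino[:, r, :] = ring_filter(s, low, high, order).data
    return fbp_reconstruct(sino, angles_deg, pixel_um, channel="delta")


def reconstruct_beta(
    t_stack: np.ndarray,
    angles_deg: np.ndarray,
    pixel_um: float,
    beam: BeamConfig,
    ring: tuple[float, float, int] | None = None,
) -> ReconVolume:
    """Transmission projections -> beta volume via -ln(T)/(2k)."""
    t = np.clip(np.asarray(t_stack, dtype=np.float64), 1e-6, None)
    sino = -np.log(t) / (2.0 * beam.wavenumber)
    if ring is not None:
        low, high, order = ring
        for r in range(sino.shape[1]):
            s = Sinogram(sino[:, r, :], angles_deg, pixel_um)
            sino[:, r, :] = ring_filter(s, low, high, order).data
    return fbp_reconstruct(sino, angles_deg, pixel_um, channel="beta")


# ---------------------------------------------------------------------------
# ROI selection and the three-arm experiment
# ---------------------------------------------------------------------------


def find_homogeneous_roi(
    label_slice: np.ndarray,
    label: int,
    size: int,
    margin: int = 8,
    valid: np.ndarray | None = None,
) -> RoiSpec:
    """Largest-purity square ROI of the given label in a label slice.

    ``valid`` restricts the search to a region (e.g. away from the specimen
    boundary, where reconstruction ringing would contaminate noise
    statistics); the ROI must lie entirely inside it.
    """
    from scipy import ndimage as ndi

    mask = (label_slice == label).astype(np.float64)
    frac = ndi.uniform_filter(mask, size=size, mode="constant")
    interior = np.zeros_like(frac, dtype=bool)
    m = margin + size // 2
    interior[m:-m or None, m:-m or None] = True
    if valid is not None:
        inside = ndi.uniform_filter(valid.astype(np.float64), size=size,
                                    mode="constant") > 0.999
        interior &= inside
    if not interior.any():
        raise ValueError("no admissible ROI position")
    frac = np.where(interior, frac, -1.0)
    r, c = np.unravel_index(np.argmax(frac), frac.shape)
    return RoiSpec(origin_px=(r - size // 2, c - size // 2), size_px=(size, size))


@dataclass
class ArmResult:
    name: str
    volume: ReconVolume
    rho_e: np.ndarray
    report: MetricsReport
    projections: MbiProjections | PbiProjections | None = None


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    phantom: Phantom
    arms: dict[str, ArmResult]
    metrics: pd.DataFrame


def _arm_metrics(
    name: str,
    cfg: ExperimentConfig,
    scan: ScanResult,
    proj,
    vol: ReconVolume,
    phantom: Phantom,
) -> tuple[MetricsReport, np.ndarray]:
    from .synthetic import LABEL_PARAFFIN, LABEL_TISSUE

    beam = BeamConfig(cfg.energy_keV)
    rho = delta_to_electron_density(vol, beam).rho_e
    n = vol.values.shape[1]
    roi_size = min(cfg.roi_px, max(8, n // 5))
    mid = phantom.label_volume.shape[0] // 2
    label_slice = phantom.label_volume[mid]
    from scipy import ndimage as ndi

    # keep noise ROIs clear of the specimen boundary, where edge ringing
    # would masquerade as noise
    edge_clear = max(3, label_slice.shape[0] // 13)
    interior = ndi.binary_erosion(label_slice != 0, iterations=edge_clear)
    sig_roi = find_homogeneous_roi(label_slice, LABEL_TISSUE, roi_size)
    valid_bg = interior.copy()
    sr, sc = sig_roi.slices()
    pad = 2
    valid_bg[max(sr.start - pad, 0):sr.stop + pad,
             max(sc.start - pad, 0):sc.stop + pad] = False
    try:
        bg_roi = find_homogeneous_roi(label_slice, LABEL_PARAFFIN, roi_size,
                                      valid=valid_bg)
    except ValueError:
        # tiny smoke-scale volumes: fall back to best purity anywhere outside
        # the signal ROI
        anywhere = np.ones_like(valid_bg)
        anywhere[max(sr.start - pad, 0):sr.stop + pad,
                 max(sc.start - pad, 0):sc.stop + pad] = False
        bg_roi = find_homogeneous_roi(label_slice, LABEL_PARAFFIN, roi_size,
                                      valid=anywhere)

    rep = MetricsReport(dataset=name)
    rep.rois = [dataclasses.replace(sig_roi, role="signal"),
                dataclasses.replace(bg_roi, role="background")]
    # several disjoint wax ROIs de-bias the noise statistics from the luck
    # of a single placement relative to nearby structures
    bg_rois = [bg_roi]
    blocked = valid_bg.copy()
    for _ in range(3):
        br, bc = bg_rois[-1].slices()
        blocked[max(br.start - 2, 0):br.stop + 2,
                max(bc.start - 2, 0):bc.stop + 2] = False
        try:
            bg_rois.append(find_homogeneous_roi(
                label_slice, LABEL_PARAFFIN, roi_size, valid=blocked))
        except ValueError:
            break
    mid_slice = vol.values[mid]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep.resolution_um, _ = fourier_resolution(mid_slice, bg_roi, cfg.pixel_um)
        rep.sigma_rho_e = float(np.median([
            phase_sensitivity(rho, roi) for roi in bg_rois
        ]))
        lo = max(0, mid - 2)
        cnrs = [
            cnr(vol.values[s], sig_roi, bg_roi)
            for s in range(lo, min(lo + 5, vol.values.shape[0]))
        ]
    rep.cnr_mean = float(np.mean(cnrs))
    rep.cnr_sd = float(np.std(cnrs))

    if isinstance(proj, MbiProjections):
        # air strip outside the specimen cylinder, projection domain: the
        # cylinder spans the central 68% of the width, so only a narrow
        # left/right margin is truly sample-free
        h, w = proj.alpha_x.shape[1:]
        edge = max(6, cfg.match.search_radius_px + cfg.match.window_half_px + 2)
        air_w = max(4, int(0.16 * w) - edge - 4)
        air_roi = RoiSpec(origin_px=(edge, edge),
                          size_px=(h - 2 * edge, air_w))
        rep.sigma_alpha_x_nrad = float(air_roi.extract(proj.alpha_x[0]).std() * 1e9)
        rep.sigma_alpha_y_nrad = float(air_roi.extract(proj.alpha_y[0]).std() * 1e9)
        refp = scan.reference.frames[0].mean(axis=0).astype(np.float64)
        refp = refp / max(refp.mean(), 1e-12)
        rep.mean_visibility = visibility_map(np.clip(refp, 1e-6, None)).mean_visibility
        try:
            rep.autocorr_fwhm_px = autocorr_fwhm(refp)
            rep.autocorr_fwhm_um = rep.autocorr_fwhm_px * cfg.pixel_um
        except ValueError:
            pass
    return rep, rho


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> ExperimentResult:
    """Run all configured arms on one shared phantom and collect the report."""
    phantom = _phantom(config)
    beam = BeamConfig(config.energy_keV)
    arms: dict[str, ArmResult] = {}
    for arm in config.arms:
        scan_cfg = build_scan_config(config, arm, phantom)
        scan = simulate_scan(scan_cfg)
        if arm == "pbi":
            proj = retrieve_pbi_scan(scan)
        else:
            proj = retrieve_mbi_scan(
                scan, config.match, drift_correction=config.drift_correction
            )
        vol = reconstruct_delta(
            proj.phi, proj.angles_deg, config.pixel_um, beam, ring=config.ring
        )
        report, rho = _arm_metrics(arm, config, scan, proj, vol, phantom)
        arms[arm] = ArmResult(arm, vol, rho, report, proj)

    metrics = pd.DataFrame([a.report.as_dict() for a in arms.values()])
    metrics.insert(1, "config_hash", config.config_hash())
    result = ExperimentResult(config, phantom, arms, metrics)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: ExperimentResult, out_dir: Path) -> None:
    import h5py

    out_dir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(out_dir / "metrics.csv", index=False)
    with h5py.File(out_dir / "volumes.h5", "w") as f:
        f.attrs["config_hash"] = result.config.config_hash()
        for name, arm in result.arms.items():
            g = f.create_group(name)
            g.create_dataset("delta", data=arm.volume.values.astype(np.float32))
            g.create_dataset("rho_e", data=arm.rho_e.astype(np.float32))
            g.attrs["voxel_um"] = arm.volume.voxel_um
    _slice_gallery(result, out_dir / "gallery.png")


def _slice_gallery(result: ExperimentResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(result.arms)
    fig, axes = plt.subplots(1, n + 1, figsize=(4 * (n + 1), 4))
    axes = np.atleast_1d(axes)
    mid = result.phantom.label_volume.shape[0] // 2
    axes[0].imshow(result.phantom.ground_truth_delta[mid], cmap="gray")
    axes[0].set_title("ground truth delta")
    for ax, (name, arm) in zip(axes[1:], result.arms.items()):
        ax.imshow(arm.volume.values[arm.volume.values.shape[0] // 2], cmap="gray")
        ax.set_title(name)
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
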
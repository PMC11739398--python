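"""Wave-optics virtual beamline for modulation- and propagation-based imaging.

The module builds the three ingredients of a modulation-based (MBI) or
propagation-based (PBI) phase-contrast scan and pushes a monochromatic plane
wave through them:

1. a *wavefront marker* (modulator): either a hexagonal phase grating of the
   Talbot-array-illuminator (TAI) type or a stack of sandpaper layers whose
   grains produce a random speckle field;
2. a *phantom*: a paraffin cylinder containing branching tubular "villi" of
   soft tissue with vessel lumina and sparse ~6 um "blood cell" spheres,
   standing in for a wax-embedded placenta specimen;
3. free-space Fresnel propagation between modulator, sample and detector,
   followed by a Gaussian detector PSF and optional Poisson photon noise.

Both sample and modulator are treated in the thin-object (projection)
approximation, and the illumination is a plane wave (the source sits tens of
metres upstream, so magnification is ~1 and source blur is folded into the
detector PSF).  These are the same approximations the retrieval models make,
so simulated scans are a faithful test bed for the analysis chain.

Coordinates: ``row`` is the detector vertical (tomographic rotation axis),
``col`` the horizontal; volumes are indexed ``(z, y, x)`` with the beam along
``+y`` at angle 0 and the sample rotated about ``z``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage

from .physics import BeamConfig, OpticalConstants, optical_constants

# ---------------------------------------------------------------------------
# geometry / detector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanGeometry:
    """Distances of the parallel-beam tomography setup (metres).

    ``z_prop_m`` is the sample-to-detector propagation distance (0.175 m for
    the MBI arm, 0.093 m for PBI), ``z0_m`` the modulator-to-sample distance
    and ``source_dist_m`` the source-to-detector distance (85 m, which makes
    the geometry effectively parallel-beam).
    """

    z_prop_m: float = 0.175
    z0_m: float = 0.115
    source_dist_m: float = 85.0
    n_angles: int = 181
    angular_range_deg: float = 180.0

    def __post_init__(self) -> None:
        if min(self.z_prop_m, self.z0_m, self.source_dist_m) <= 0:
            raise ValueError("all distances must be positive")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")

    @property
    def angles_deg(self) -> np.ndarray:
        """Projection angles, evenly spaced over the angular range."""
        return np.linspace(
            0.0, self.angular_range_deg, self.n_angles, endpoint=False
        )


@dataclass(frozen=True)
class DetectorModel:
    """Scintillator-coupled detector in the sample plane.

    The point-spread function has two components: a Gaussian core whose
    FWHM matches the measured system resolution (1.67 px = 2.14 um), and a
    broad halo that models scintillator veiling glare and optical
    cross-talk.  The halo fraction is calibrated so that the simulated
    reference-pattern visibility of the hexagonal grating matches the
    ~15% measured on the real system; without it an ideal detector would
    show ~70% and photon noise would be unrealistically benign.
    """

    pixel_um: float = 1.28
    shape_px: tuple[int, int] = (256, 256)
    psf_fwhm_px: float = 1.67
    psf_halo_frac: float = 0.79
    psf_halo_sigma_px: float = 25.0
    photons_per_px: float = 1e4
    n_dark: int = 20
    n_flat: int = 70

    def __post_init__(self) -> None:
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if self.psf_fwhm_px < 0:
            raise ValueError("psf_fwhm_px must be >= 0")
        if not 0 <= self.psf_halo_frac < 1:
            raise ValueError("psf_halo_frac must be in [0, 1)")

    @property
    def pixel_m(self) -> float:
        return self.pixel_um * 1e-6


# ---------------------------------------------------------------------------
# modulator screens
# ---------------------------------------------------------------------------


@dataclass
class ModulatorScreen:
    """Projected-thickness map of a wavefront marker.

    ``thickness_map_um`` holds the *relative* projected thickness (any
    constant substrate thickness only contributes a global transmission
    factor and is omitted).
    """

    kind: str
    thickness_map_um: np.ndarray
    material: OpticalConstants
    pixel_um: float
    params: dict = field(default_factory=dict)

    def transmission(self, beam: BeamConfig) -> np.ndarray:
        """Complex amplitude transmission exp(-k*beta*t) * exp(-i*k*delta*t)."""
        t_m = self.thickness_map_um * 1e-6
        k = beam.wavenumber
        return np.exp(-k * self.material.beta * t_m) * np.exp(
            -1j * k * self.material.delta * t_m
        )

    def peak_phase_shift(self, beam: BeamConfig) -> float:
        """Peak-to-trough phase shift k*delta*(t_max - t_min) in rad."""
        span = float(self.thickness_map_um.max() - self.thickness_map_um.min())
        return beam.wavenumber * self.material.delta * span * 1e-6


def _hex_lattice_distance(yy: np.ndarray, xx: np.ndarray, a: float) -> np.ndarray:
    """Distance from each point to the nearest site of a hexagonal lattice.

    Lattice: rows spaced a*sqrt(3)/2 apart, alternate rows shifted by a/2.
    Computed in the rectangular tile (a, a*sqrt(3)) that contains two sites.
    """
    h = a * np.sqrt(3.0)
    y = np.mod(yy, h)
    x = np.mod(xx, a)
    best = np.full(y.shape, np.inf)
    for sy, sx in [(0.0, 0.0), (h, 0.0), (0.0, a), (h, a),
                   (h / 2, a / 2), (h / 2, -a / 2), (h / 2, 3 * a / 2)]:
        d2 = (y - sy) ** 2 + (x - sx) ** 2
        np.minimum(best, d2, out=best)
    return np.sqrt(best)


def make_tai_screen(
    period_um: float = 7.0,
    duty_cycle: float = 1.0 / 3.0,
    etch_depth_um: float = 17.0,
    material: str | OpticalConstants = "silicon",
    pixel_um: float = 1.28,
    shape_px: tuple[int, int] = (512, 512),
    energy_keV: float = 20.0,
    supersample: int = 4,
) -> ModulatorScreen:
    """Hexagonal Talbot-array-illuminator phase grating.

    Etched cells are circles on a hexagonal lattice of the given period,
    sized so that the etched-area fraction equals the duty cycle; the
    thickness map is binary (0 inside etched cells, ``etch_depth_um``
    elsewhere).  With the default silicon at 20 keV and a 17 um etch the
    peak-to-trough phase shift is close to 2*pi/3, the canonical TAI design
    for high-visibility self-images.
    """
    if not 0 < duty_cycle < 1:
        raise ValueError("duty_cycle must be in (0, 1)")
    if period_um <= 2 * pixel_um:
        raise ValueError(
            f"period {period_um} um is under-sampled at {pixel_um} um pixels; "
            f"need period > {2 * pixel_um:.3g} um (2 px)"
        )
    if etch_depth_um < 0:
        raise ValueError("etch_depth_um must be >= 0")
    if isinstance(material, str):
        material = optical_constants(material, energy_keV)

    a = period_um
    # circle radius giving the requested area fraction of the unit cell
    cell_area = a * a * np.sqrt(3.0) / 2.0
    r_etch = np.sqrt(duty_cycle * cell_area / np.pi)

    ny, nx = shape_px
    s = supersample
    fine = (np.arange(ny * s) + 0.5) / s * pixel_um
    finex = (np.arange(nx * s) + 0.5) / s * pixel_um
    yy, xx = np.meshgrid(fine, finex, indexing="ij")
    dist = _hex_lattice_distance(yy, xx, a)
    coverage = (dist < r_etch).astype(np.float64)
    coverage = coverage.reshape(ny, s, nx, s).mean(axis=(1, 3))
    etched = coverage >= 0.5
    thickness = np.where(etched, 0.0, etch_depth_um)
    return ModulatorScreen(
        kind="tai_hex",
        thickness_map_um=thickness,
        material=material,
        pixel_um=pixel_um,
        params={
            "period_um": period_um,
            "duty_cycle": duty_cycle,
            "etch_depth_um": etch_depth_um,
            "etched_fraction": float(etched.mean()),
        },
    )


def make_sandpaper_screen(
    grain_mean_um: float = 5.8,
    n_layers: int = 6,
    material: str | OpticalConstants = "silicon_carbide",
    pixel_um: float = 1.28,
    shape_px: tuple[int, int] = (512, 512),
    energy_keV: float = 20.0,
    seed: int = 0,
    coverage_per_layer: float = 1.2,
    lognorm_sigma: float = 0.35,
) -> ModulatorScreen:
    """Random diffuser built from stacked sandpaper layers.

    Each layer deposits randomly placed spherical grains whose lateral
    diameters follow a log-normal distribution with the stated mean (the
    log-normal shape parameter is a fixed modelling choice; only the mean is
    a physical datum).  All layers are summed into a single projected
    thickness map; the layer-to-layer air gap is negligible compared to the
    propagation distances and is ignored.
    """
    if grain_mean_um <= 0:
        raise ValueError("grain_mean_um must be positive")
    if n_layers < 0:
        raise ValueError("n_layers must be >= 0")
    if isinstance(material, str):
        material = optical_constants(material, energy_keV)

    ny, nx = shape_px
    thickness = np.zeros((ny, nx), dtype=np.float64)
    rng = np.random.default_rng(seed)
    if n_layers > 0:
        mean_area_px = np.pi * (grain_mean_um / pixel_um / 2.0) ** 2
        n_grains = int(np.ceil(coverage_per_layer * ny * nx / max(mean_area_px, 1.0)))
        # log-normal with E[d] = grain_mean_um
        mu = np.log(grain_mean_um) - 0.5 * lognorm_sigma**2
        for _ in range(n_layers):
            cy = rng.uniform(0, ny, n_grains)
            cx = rng.uniform(0, nx, n_grains)
            diam_um = rng.lognormal(mu, lognorm_sigma, n_grains)
            rad_px = diam_um / pixel_um / 2.0
            for yc, xc, r, d_um in zip(cy, cx, rad_px, diam_um):
                y0, y1 = int(np.floor(yc - r)), int(np.ceil(yc + r)) + 1
                x0, x1 = int(np.floor(xc - r)), int(np.ceil(xc + r)) + 1
                y0c, x0c = max(y0, 0), max(x0, 0)
                y1c, x1c = min(y1, ny), min(x1, nx)
                if y0c >= y1c or x0c >= x1c:
                    continue
                ys = np.arange(y0c, y1c)[:, None] - yc
                xs = np.arange(x0c, x1c)[None, :] - xc
                rr2 = (ys**2 + xs**2) / max(r, 1e-9) ** 2
                cap = np.sqrt(np.clip(1.0 - rr2, 0.0, None)) * d_um
                thickness[y0c:y1c, x0c:x1c] += cap
    return ModulatorScreen(
        kind="sandpaper",
        thickness_map_um=thickness,
        material=material,
        pixel_um=pixel_um,
        params={
            "grain_mean_um": grain_mean_um,
            "n_layers": n_layers,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


@dataclass
class Phantom:
    """Labelled voxel phantom with per-material optical constants.

    ``delta_volume`` / ``beta_volume`` can override the label-derived maps,
    e.g. to carry sub-voxel detail such as a tapered specimen boundary.
    """

    voxel_um: float
    label_volume: np.ndarray  # (z, y, x) integer labels
    materials: dict[int, OpticalConstants]
    delta_volume: np.ndarray | None = None
    beta_volume: np.ndarray | None = None

    def __post_init__(self) -> None:
        present = set(np.unique(self.label_volume).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels {missing} missing from materials map")

    def _lookup(self, attr: str) -> np.ndarray:
        maxlab = int(self.label_volume.max())
        table = np.zeros(maxlab + 1, dtype=np.float64)
        for lab, mat in self.materials.items():
            if lab <= maxlab:
                table[lab] = getattr(mat, attr)
        return table[self.label_volume]

    @property
    def ground_truth_delta(self) -> np.ndarray:
        if self.delta_volume is not None:
            return self.delta_volume
        return self._lookup("delta")

    @property
    def ground_truth_beta(self) -> np.ndarray:
        if self.beta_volume is not None:
            return self.beta_volume
        return self._lookup("beta")


# phantom label conventions
LABEL_AIR = 0
LABEL_PARAFFIN = 1
LABEL_TISSUE = 2
LABEL_LUMEN = 3
LABEL_BLOOD_CELL = 4


def default_phantom_materials(energy_keV: float = 20.0) -> dict[int, OpticalConstants]:
    return {
        LABEL_AIR: optical_constants("air", energy_keV),
        LABEL_PARAFFIN: optical_constants("paraffin", energy_keV),
        LABEL_TISSUE: optical_constants("soft_tissue", energy_keV),
        LABEL_LUMEN: optical_constants("paraffin", energy_keV),
        LABEL_BLOOD_CELL: optical_constants("blood_cell", energy_keV),
    }


def _mark_tube(labels: np.ndarray, p0: np.ndarray, p1: np.ndarray,
               radius: float, value: int) -> None:
    """Label all voxels within `radius` of the segment p0-p1 (in voxel units)."""
    lo = np.floor(np.minimum(p0, p1) - radius).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, labels.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(np.float64)
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-12:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[dist2 <= radius**2] = value


def make_placenta_phantom(
    shape_vox: tuple[int, int, int] = (128, 128, 128),
    voxel_um: float = 1.28,
    seed: int = 0,
    energy_keV: float = 20.0,
    n_trees: int = 2,
    cylinder_radius_frac: float = 0.34,
    edge_taper_vox: float = 3.0,
    materials: dict[int, OpticalConstants] | None = None,
) -> Phantom:
    """Paraffin cylinder with branching soft-tissue villi, lumina and cells.

    The phantom emulates wax-embedded placental villous tissue: tubular
    branching "villi" of soft tissue hang inside a paraffin cylinder, larger
    branches carry a wax-filled vessel lumen, and sparse ~6 um spheres mimic
    single blood cells.  It is a geometric stand-in, not an anatomical model:
    its purpose is to provide realistic contrast levels (delta, beta at the
    beam energy) and feature scales with exact ground truth.  The default
    cylinder radius (0.34 of the transverse extent) reproduces the typical
    specimen-to-field-of-view ratio of such scans and leaves a genuinely
    sample-free margin for background estimation.
    """
    if max(shape_vox) > 512:
        raise ValueError("phantom larger than 512 voxels per axis")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape_vox
    labels = np.zeros(shape_vox, dtype=np.uint8)

    # paraffin cylinder along z
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_cyl = cylinder_radius_frac * min(ny, nx)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cyl = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_cyl**2
    labels[:, cyl] = LABEL_PARAFFIN

    # one thick stem villus: placental stem villi are an order of magnitude
    # wider than terminal branches and provide the extended homogeneous
    # tissue regions that quantitative ROI statistics need
    scale = min(shape_vox) / 128.0
    r_stem = 0.16 * min(shape_vox)
    stem_p0 = np.array([0.0, cy + 0.12 * r_cyl, cx - 0.12 * r_cyl])
    stem_dir = np.array([1.0, rng.normal(0, 0.06), rng.normal(0, 0.06)])
    stem_dir /= np.linalg.norm(stem_dir)
    stem_p1 = stem_p0 + stem_dir * (nz / stem_dir[0])
    _mark_tube(labels, stem_p0, stem_p1, r_stem, LABEL_TISSUE)
    _mark_tube(labels, stem_p0, stem_p1, 0.2 * r_stem, LABEL_LUMEN)

    # branching villous trees (random recursive tubes)
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []

    def grow(p0: np.ndarray, direction: np.ndarray, radius: float, depth: int) -> None:
        if depth <= 0 or radius < 1.2:
            return
        length = rng.uniform(0.18, 0.3) * min(shape_vox)
        p1 = p0 + direction * length
        segments.append((p0, p1, radius))
        n_child = 2 if radius > 2.5 else 1
        for _ in range(n_child):
            newdir = direction + rng.normal(0.0, 0.45, 3)
            newdir /= np.linalg.norm(newdir)
            grow(p1, newdir, radius * rng.uniform(0.55, 0.75), depth - 1)

    for _ in range(n_trees):
        start = np.array([
            rng.uniform(0.05 * nz, 0.25 * nz),
            cy + rng.uniform(-0.3, 0.3) * r_cyl,
            cx + rng.uniform(-0.3, 0.3) * r_cyl,
        ])
        d0 = np.array([1.0, rng.normal(0, 0.3), rng.normal(0, 0.3)])
        d0 /= np.linalg.norm(d0)
        grow(start, d0, 8.0 * scale, depth=4)

    for p0, p1, r in segments:
        _mark_tube(labels, p0, p1, r, LABEL_TISSUE)
    # vessel lumina inside the larger branches
    for p0, p1, r in segments:
        if r >= 3.0:
            _mark_tube(labels, p0, p1, r / 2.5, LABEL_LUMEN)

    # sparse ~6 um blood cells inside lumina
    lumen_idx = np.argwhere(labels == LABEL_LUMEN)
    if len(lumen_idx):
        n_cells = max(3, len(lumen_idx) // 2000)
        picks = lumen_idx[rng.choice(len(lumen_idx), size=n_cells, replace=False)]
        r_cell = 3.0 / voxel_um  # 6 um diameter
        for c in picks:
            _mark_tube(labels, c.astype(float), c.astype(float), r_cell,
                       LABEL_BLOOD_CELL)

    # everything outside the cylinder stays air
    labels[:, ~cyl] = LABEL_AIR

    mats = materials or default_phantom_materials(energy_keV)
    phantom = Phantom(voxel_um=voxel_um, label_volume=labels, materials=mats)
    if edge_taper_vox > 0:
        # Taper the wax-block boundary over a few voxels.  At full scale the
        # boundary slope region where pattern tracking fails spans a
        # negligible fraction of the specimen radius; a sharp voxel edge at
        # desk scale would exaggerate that fraction by two orders of
        # magnitude, so the scaled phantom rounds the rim to keep the
        # boundary phase gradient in the trackable regime.
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        ramp = np.clip((r_cyl - r) / edge_taper_vox, 0.0, 1.0)
        taper = (0.5 - 0.5 * np.cos(np.pi * ramp))[None, :, :]
        phantom.delta_volume = phantom._lookup("delta") * taper
        phantom.beta_volume = phantom._lookup("beta") * taper
    return phantom


def project_phantom(
    phantom: Phantom, angle_deg: float, order: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Line integrals of delta and beta along the beam at one rotation angle.

    Returns ``(delta_t_map, beta_t_map)`` in metres on the (row, col) =
    (z, x) detector grid; the beam runs along +y and the sample is rotated
    about the vertical (z) axis.
    """
    if not 0.0 <= angle_deg < 360.0:
        angle_deg = float(np.mod(angle_deg, 360.0))
    vols = np.stack([phantom.ground_truth_delta, phantom.ground_truth_beta])
    if angle_deg != 0.0:
        vols = ndimage.rotate(
            vols, angle_deg, axes=(3, 2), reshape=False, order=order,
            mode="constant", cval=0.0, prefilter=False,
        )
    voxel_m = phantom.voxel_um * 1e-6
    proj = vols.sum(axis=2) * voxel_m  # integrate along y -> (2, z, x)
    return proj[0], proj[1]


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def fresnel_propagate(
    field: np.ndarray,
    distance_m: float,
    beam: BeamConfig,
    pixel_um: float,
    check_sampling: bool = True,
) -> np.ndarray:
    """Paraxial angular-spectrum propagation of a complex field.

    Applies the unitary Fresnel transfer function
    ``H(f) = exp(-i*pi*lambda*z*(fx^2 + fy^2))`` in Fourier space, so total
    intensity is conserved to FFT round-off.  The grid is treated as
    periodic; callers must pad if wrap-around matters.
    """
    if field.ndim != 2:
        raise ValueError("field must be 2D")
    if distance_m == 0.0:
        return field.copy()
    lam = beam.wavelength_m
    dx = pixel_um * 1e-6
    n_min = min(field.shape)
    z_max = n_min * dx * dx / lam
    if check_sampling and abs(distance_m) > z_max:
        raise ValueError(
            f"transfer-function phase aliased: |z| = {abs(distance_m):.3g} m "
            f"exceeds N*dx^2/lambda = {z_max:.3g} m; pad the field or use "
            f"coarser sampling"
        )
    fy = np.fft.fftfreq(field.shape[0], d=dx)
    fx = np.fft.fftfreq(field.shape[1], d=dx)
    h = np.exp(-1j * np.pi * lam * distance_m * (fy[:, None] ** 2 + fx[None, :] ** 2))
    return np.fft.ifft2(np.fft.fft2(field) * h)


# ---------------------------------------------------------------------------
# stepping patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteppingPattern:
    """Ordered transverse modulator offsets in detector pixels."""

    offsets_px: tuple[tuple[float, float], ...]
    scheme: str

    def __post_init__(self) -> None:
        offs = np.asarray(self.offsets_px)
        if offs.ndim != 2 or offs.shape[1] != 2:
            raise ValueError("offsets_px must be a sequence of (row, col) pairs")
        if len(np.unique(np.round(offs, 6), axis=0)) != len(offs):
            raise ValueError("stepping offsets must be pairwise distinct")

    @property
    def n_steps(self) -> int:
        return len(self.offsets_px)


def tilted_grid_pattern(
    n_steps: int = 16, period_um: float = 7.0, pixel_um: float = 1.28
) -> SteppingPattern:
    """Tilted grid of offsets tiling one unit cell of the hexagonal lattice.

    Steps are laid out on a g x g grid in the primitive-cell basis
    (e1 = (0, a), e2 = (a*sqrt(3)/2, a/2)) with a small row-dependent tilt so
    all offsets are unique modulo the lattice and sample the cell uniformly.
    """
    a = period_um / pixel_um  # lattice constant in px
    g = int(np.ceil(np.sqrt(n_steps)))
    e1 = np.array([0.0, a])
    e2 = np.array([a * np.sqrt(3.0) / 2.0, a / 2.0])
    offsets = []
    for i in range(n_steps):
        m, j = i % g, i // g
        frac1 = m / g + j / (g * g * g)  # tilt keeps columns distinct mod lattice
        frac2 = j / g
        off = frac1 * e1 + frac2 * e2
        offsets.append((float(off[0]), float(off[1])))
    return SteppingPattern(offsets_px=tuple(offsets), scheme="tilted_grid")


def spiral_pattern(
    n_steps: int = 20, max_radius_px: float = 30.0
) -> SteppingPattern:
    """Golden-angle spiral of pairwise-distinct offsets (random diffusers)."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    offsets = []
    for i in range(n_steps):
        r = max_radius_px * np.sqrt((i + 1) / n_steps)
        th = i * golden
        offsets.append((float(r * np.sin(th)), float(r * np.cos(th))))
    return SteppingPattern(offsets_px=tuple(offsets), scheme="spiral")


# ---------------------------------------------------------------------------
# frame simulation
# ---------------------------------------------------------------------------


def _shift_screen(thickness: np.ndarray, offset_px: tuple[float, float],
                  shape: tuple[int, int]) -> np.ndarray:
    """Resample the (possibly larger) screen map at a transverse offset."""
    shifted = ndimage.shift(
        thickness, offset_px, order=1, mode="grid-wrap", prefilter=False
    )
    return shifted[: shape[0], : shape[1]]


def simulate_frame(
    geometry: ScanGeometry,
    beam: BeamConfig,
    detector: DetectorModel,
    screen: ModulatorScreen | None = None,
    screen_offset_px: tuple[float, float] = (0.0, 0.0),
    phantom: Phantom | None = None,
    angle_deg: float = 0.0,
    rng: np.random.Generator | None = None,
    projection: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Simulate one detector frame.

    The plane wave crosses the (shifted) modulator, propagates ``z0`` to the
    sample, picks up the sample's thin-object transmission, propagates
    ``z_prop`` to the detector; the intensity is then blurred by the detector
    PSF, scaled to photons and optionally Poisson-sampled.

    With ``screen=None`` and a phantom this is a PBI frame; with
    ``phantom=None`` a reference frame; with both absent a flat frame.
    ``projection`` can pass a precomputed ``project_phantom`` result so that
    stepping loops do not recompute it.
    """
    shape = detector.shape_px
    if screen is not None and screen.pixel_um != detector.pixel_um:
        raise ValueError("screen and detector pixel sizes differ")
    if phantom is not None and not np.isclose(phantom.voxel_um, detector.pixel_um):
        raise ValueError("phantom voxel size must match the detector pixel size")

    field = np.ones(shape, dtype=np.complex128)
    if screen is not None:
        if screen.thickness_map_um.shape < shape:
            raise ValueError("screen smaller than detector")
        t = _shift_screen(screen.thickness_map_um, screen_offset_px, shape)
        shifted = dataclasses.replace(screen, thickness_map_um=t)
        field = field * shifted.transmission(beam)
        field = fresnel_propagate(field, geometry.z0_m, beam, detector.pixel_um)

    if phantom is not None:
        if projection is None:
            projection = project_phantom(phantom, angle_deg)
        delta_t, beta_t = projection
        if delta_t.shape != shape:
            raise ValueError("phantom projection does not match detector shape")
        k = beam.wavenumber
        field = field * np.exp(-k * beta_t) * np.exp(-1j * k * delta_t)

    field = fresnel_propagate(field, geometry.z_prop_m, beam, detector.pixel_um)
    intensity = np.abs(field) ** 2

    if detector.psf_fwhm_px > 0:
        sigma = detector.psf_fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        intensity = ndimage.gaussian_filter(intensity, sigma, mode="wrap")
    if detector.psf_halo_frac > 0:
        halo = ndimage.gaussian_filter(
            intensity, detector.psf_halo_sigma_px, mode="wrap"
        )
        intensity = (
            (1.0 - detector.psf_halo_frac) * intensity
            + detector.psf_halo_frac * halo
        )
    intensity = intensity * detector.photons_per_px
    if rng is not None:
        intensity = rng.poisson(intensity).astype(np.float64)
    return intensity


# ---------------------------------------------------------------------------
# full scans
# ---------------------------------------------------------------------------


@dataclass
class FrameStack:
    """Detector frames indexed (step, frame, row, col).

    For sample stacks the frame axis is the tomographic angle; for reference
    stacks it counts repeated flats; dark stacks have a single step.
    """

    frames: np.ndarray
    kind: str  # dark | reference | sample
    geometry: ScanGeometry
    detector: DetectorModel
    stepping: SteppingPattern | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise ValueError("frames must be (step, frame, row, col)")
        if self.kind not in ("dark", "reference", "sample"):
            raise ValueError(f"unknown frame kind {self.kind!r}")

    @property
    def n_steps(self) -> int:
        return self.frames.shape[0]


@dataclass
class ScanConfig:
    """Everything needed to simulate one MBI or PBI tomographic scan."""

    beam: BeamConfig = field(default_factory=BeamConfig)
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    detector: DetectorModel = field(default_factory=DetectorModel)
    screen: ModulatorScreen | None = None
    stepping: SteppingPattern | None = None
    phantom: Phantom | None = None
    noise: bool = True
    dark_level_photons: float = 50.0
    n_ref_per_step: int = 4
    drift_total_px: tuple[float, float] = (0.0, 0.0)
    seed: int = 0


@dataclass
class ScanResult:
    dark: FrameStack
    reference: FrameStack
    sample: FrameStack
    ground_truth: dict


def simulate_scan(config: ScanConfig) -> ScanResult:
    """Simulate dark, per-step reference and per-step/per-angle sample frames.

    Ground truth (the phantom and the true per-angle phase map
    ``Phi = k * integral(delta)``) is retained for tests.  Optional linear
    modulator drift is injected across the angular scan; reference frames are
    recorded at the nominal (undrifted) offsets, as in a real acquisition
    where flats bracket the scan.
    """
    beam, geom, det = config.beam, config.geometry, config.detector
    rng = np.random.default_rng(config.seed)
    frame_rng = rng if config.noise else None
    if config.stepping is not None and config.screen is None:
        raise ValueError("stepping requires a modulator screen")
    offsets = (
        config.stepping.offsets_px if config.stepping is not None else [(0.0, 0.0)]
    )
    n_steps = len(offsets)
    shape = det.shape_px
    k = beam.wavenumber

    def with_dark(im: np.ndarray) -> np.ndarray:
        if config.dark_level_photons <= 0:
            return im
        dark = np.full(shape, config.dark_level_photons)
        if frame_rng is not None:
            dark = frame_rng.poisson(dark).astype(np.float64)
        return im + dark

    # darks
    darks = np.empty((1, det.n_dark, *shape), dtype=np.float32)
    for i in range(det.n_dark):
        darks[0, i] = with_dark(np.zeros(shape))

    # references
    refs = np.empty((n_steps, config.n_ref_per_step, *shape), dtype=np.float32)
    for s, off in enumerate(offsets):
        for i in range(config.n_ref_per_step):
            im = simulate_frame(
                geom, beam, det, screen=config.screen, screen_offset_px=off,
                rng=frame_rng,
            )
            refs[s, i] = with_dark(im)

    # sample frames and ground truth
    angles = geom.angles_deg
    samples = np.empty((n_steps, len(angles), *shape), dtype=np.float32)
    phi_true = np.empty((len(angles), *shape), dtype=np.float32)
    drift = np.asarray(config.drift_total_px, dtype=np.float64)
    for j, ang in enumerate(angles):
        if config.phantom is not None:
            proj = project_phantom(config.phantom, float(ang))
            phi_true[j] = k * proj[0]
        else:
            proj = (np.zeros(shape), np.zeros(shape))
            phi_true[j] = 0.0
        frac = j / max(len(angles) - 1, 1)
        for s, off in enumerate(offsets):
            off_j = (off[0] + drift[0] * frac, off[1] + drift[1] * frac)
            im = simulate_frame(
                geom, beam, det, screen=config.screen, screen_offset_px=off_j,
                phantom=config.phantom, angle_deg=float(ang), rng=frame_rng,
                projection=proj,
            )
            samples[s, j] = with_dark(im)

    stepping = config.stepping
    return ScanResult(
        dark=FrameStack(darks, "dark", geom, det, None),
        reference=FrameStack(refs, "reference", geom, det, stepping),
        sample=FrameStack(samples, "sample", geom, det, stepping),
        ground_truth={
            "phantom": config.phantom,
            "phi": phi_true,
            "angles_deg": angles,
        },
    )


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def save_scan(scan: ScanResult, path: str) -> None:
    """Write a scan in the HDF5 layout /dark, /reference/step_i, /sample/step_i."""
    geom, det = scan.sample.geometry, scan.sample.detector
    with h5py.File(path, "w") as f:
        f.attrs["energy_keV"] = 20.0
        f.attrs["pixel_um"] = det.pixel_um
        f.attrs["z_prop_m"] = geom.z_prop_m
        f.attrs["z0_m"] = geom.z0_m
        f.attrs["n_angles"] = geom.n_angles
        if scan.sample.stepping is not None:
            f.attrs["stepping_offsets_px"] = np.asarray(
                scan.sample.stepping.offsets_px
            )
            f.attrs["stepping_scheme"] = scan.sample.stepping.scheme
        f.create_dataset("dark", data=scan.dark.frames[0])
        for s in range(scan.reference.n_steps):
            f.create_dataset(f"reference/step_{s}", data=scan.reference.frames[s])
        for s in range(scan.sample.n_steps):
            g = f.create_group(f"sample/step_{s}")
            for j in range(scan.sample.frames.shape[1]):
                g.create_dataset(f"angle_{j}", data=scan.sample.frames[s, j])
        gt = scan.ground_truth
        g = f.create_group("ground_truth")
        g.create_dataset("phi", data=gt["phi"])
        g.create_dataset("angles_deg", data=gt["angles_deg"])
        if gt.get("phantom") is not None:
            ph = gt["phantom"]
            g.create_dataset("phantom_labels", data=ph.label_volume)
            g.attrs["voxel_um"] = ph.voxel_um


def load_scan(path: str) -> dict:
    """Read back the layout written by :func:`save_scan` into plain arrays."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        out["attrs"] = dict(f.attrs)
        out["dark"] = f["dark"][()]
        steps = sorted(f["reference"], key=lambda s: int(s.split("_")[1]))
        out["reference"] = np.stack([f["reference"][s][()] for s in steps])
        ssteps = sorted(f["sample"], key=lambda s: int(s.split("_")[1]))
        sample = []
        for s in ssteps:
            g = f["sample"][s]
            angs = sorted(g, key=lambda a: int(a.split("_")[1]))
            sample.append(np.stack([g[a][()] for a in angs]))
        out["sample"] = np.stack(sample)
        if "ground_truth" in f:
            out["ground_truth"] = {
                "phi": f["ground_truth/phi"][()],
                "angles_deg": f["ground_truth/angles_deg"][()],
            }
    return out
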
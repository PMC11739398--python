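"""Quantitative image-quality metrics for phase-contrast tomography.

The suite mirrors how modulation-based imaging systems are characterised:

* **visibility** - local standard deviation over local mean of a reference
  pattern; measures the modulation strength available for tracking;
* **autocorrelation FWHM** - mean size of the wavefront-marking structures,
  from the central peak of the pattern's 2D autocorrelation;
* **Fourier-spectrum resolution** - spatial frequency at which the
  azimuthally averaged power spectrum of a slice falls to the noise floor
  predicted from a homogeneous ROI;
* **angular sensitivity** - standard deviation of the refraction-angle maps
  in a sample-free ROI (smallest detectable refraction angle);
* **phase sensitivity** - standard deviation of the reconstructed electron
  density in a homogeneous ROI (smallest resolvable density difference);
* **CNR** - contrast-to-noise ratio |I_s - I_b| / sigma_b between a signal
  and a background ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned ROI: origin (row, col), size (rows, cols), role."""

    origin_px: tuple[int, int]
    size_px: tuple[int, int] = (40, 40)
    role: str = "background"  # signal | background

    def slices(self) -> tuple[slice, slice]:
        (r0, c0), (h, w) = self.origin_px, self.size_px
        return slice(r0, r0 + h), slice(c0, c0 + w)

    def extract(self, image: np.ndarray) -> np.ndarray:
        sr, sc = self.slices()
        if sr.stop > image.shape[-2] or sc.stop > image.shape[-1] or (
            sr.start < 0 or sc.start < 0
        ):
            raise ValueError("ROI outside image bounds")
        return image[..., sr, sc]


@dataclass
class VisibilityMap:
    values: np.ndarray
    window_px: int

    @property
    def mean_visibility(self) -> float:
        return float(self.values.mean())


@dataclass
class MetricsReport:
    """One row of the quality comparison across imaging arms."""

    dataset: str = ""
    mean_visibility: float = np.nan
    autocorr_fwhm_px: float = np.nan
    autocorr_fwhm_um: float = np.nan
    resolution_um: float = np.nan
    sigma_alpha_x_nrad: float = np.nan
    sigma_alpha_y_nrad: float = np.nan
    sigma_rho_e: float = np.nan
    cnr_mean: float = np.nan
    cnr_sd: float = np.nan
    rois: list[RoiSpec] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "rois"}
        return d


def visibility_map(reference_image: np.ndarray, window_px: int = 15) -> VisibilityMap:
    """Per-pixel sliding-window std over mean of a reference pattern.

    The default 15 px window covers at least two grating periods at the
    native sampling, so the statistic measures modulation rather than single
    features.
    """
    if window_px < 3:
        raise ValueError("window must be >= 3 px")
    img = np.asarray(reference_image, dtype=np.float64)
    if (img <= 0).any():
        raise ValueError("reference image must be positive")
    mean = ndimage.uniform_filter(img, size=window_px, mode="reflect")
    sq = ndimage.uniform_filter(img * img, size=window_px, mode="reflect")
    var = np.clip(sq - mean * mean, 0.0, None)
    return VisibilityMap(values=np.sqrt(var) / mean, window_px=window_px)


def _profile_fwhm(profile: np.ndarray) -> float:
    """FWHM of a symmetric peak at the centre of a 1D profile (sub-pixel)."""
    c = len(profile) // 2
    half = profile[c] / 2.0
    width = 0.0
    for direction in (1, -1):
        i = c
        while True:
            j = i + direction
            if j < 0 or j >= len(profile):
                raise ValueError("autocorrelation peak not resolved (monotone)")
            if profile[j] <= half:
                # linear interpolation of the half-maximum crossing
                frac = (profile[i] - half) / (profile[i] - profile[j])
                width += abs(i - c) + frac
                break
            i = j
    return width


def autocorr_fwhm(reference_image: np.ndarray) -> float:
    """Mean marking-structure size from the pattern's 2D autocorrelation.

    The image is mean-subtracted, its normalised autocorrelation computed via
    FFT, and the FWHM of the central peak measured along both axes through
    the peak (linear sub-pixel interpolation of the half-maximum crossings),
    then averaged.  Result in pixels.
    """
    img = np.asarray(reference_image, dtype=np.float64)
    img = img - img.mean()
    f = np.fft.fft2(img)
    ac = np.real(np.fft.ifft2(f * np.conj(f)))
    ac = np.fft.fftshift(ac) / ac.flat[0]
    cy, cx = np.array(ac.shape) // 2
    fw_y = _profile_fwhm(ac[:, cx])
    fw_x = _profile_fwhm(ac[cy, :])
    return 0.5 * (fw_y + fw_x)


def _radial_average(power: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = power.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    fr = np.sqrt(fy**2 + fx**2).ravel()
    p = power.ravel()
    nbins = min(ny, nx) // 2
    edges = np.linspace(0, 0.5, nbins + 1)
    idx = np.clip(np.digitize(fr, edges) - 1, 0, nbins - 1)
    sums = np.bincount(idx, weights=p, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    valid = counts > 0
    return centers[valid], sums[valid] / counts[valid]


def fourier_resolution(
    volume_slice: np.ndarray,
    noise_roi: RoiSpec,
    pixel_um: float = 1.28,
) -> tuple[float, bool]:
    """Spatial resolution from the power-spectrum/noise-floor crossing.

    The azimuthally averaged power spectrum of the slice is compared with the
    flat floor that white noise of the ROI's variance would produce
    (Parseval scaling: E|X(f)|^2 = N_pixels * sigma^2).  The resolution is
    ``1/f_c`` in um at the first crossing, located by log-domain linear
    interpolation.  If the spectrum never reaches the floor the
    Nyquist-limited bound (2 px) is returned with ``noise_limited=True``.
    """
    sl = np.asarray(volume_slice, dtype=np.float64)
    roi = noise_roi.extract(sl)
    # split-half stationarity check of the noise ROI
    h = roi.shape[0] // 2
    v1, v2 = roi[:h].var(), roi[h:].var()
    if max(v1, v2) > 0 and min(v1, v2) / max(v1, v2) < 0.2:
        warnings.warn("noise ROI variance not stationary", stacklevel=2)
    sigma2 = roi.var()
    spec = np.abs(np.fft.fft2(sl - sl.mean())) ** 2
    freqs, radial = _radial_average(spec)
    floor = sl.size * sigma2
    if sigma2 == 0:
        return 2.0 * pixel_um, True
    # a 3-bin running mean tames the fluctuation of individual radial bins
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(radial, kernel, mode="same")
    smooth[0] = radial[0]
    # if the low-frequency spectrum is already at the floor the slice is
    # noise through and through: report the sampling limit
    low = smooth[1 : max(4, len(smooth) // 16)]
    if low.mean() <= 2.0 * floor:
        return 2.0 * pixel_um, True
    below = smooth <= floor
    below[0] = False
    if not below.any():
        return 2.0 * pixel_um, True
    i = int(np.argmax(below))
    # log-domain interpolation between bins i-1 (above) and i (below)
    la, lb = np.log(smooth[i - 1]), np.log(max(smooth[i], 1e-300))
    lf = np.log(floor)
    frac = (la - lf) / (la - lb) if la != lb else 0.5
    f_c = freqs[i - 1] + frac * (freqs[i] - freqs[i - 1])  # cycles/px
    return float(pixel_um / f_c), False


def angular_sensitivity(
    alpha_x: np.ndarray,
    alpha_y: np.ndarray,
    background_roi: RoiSpec,
    sample_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Per-axis std of the refraction angles in a sample-free ROI, in nrad."""
    if sample_mask is not None and background_roi.extract(sample_mask).any():
        raise ValueError("background ROI overlaps the sample mask")
    sx = float(background_roi.extract(np.asarray(alpha_x)).std()) * 1e9
    sy = float(background_roi.extract(np.asarray(alpha_y)).std()) * 1e9
    return sx, sy


def phase_sensitivity(
    rho_e_volume: np.ndarray, homogeneous_roi: RoiSpec, n_slices: int | None = None
) -> float:
    """Std of electron density in a homogeneous ROI (electrons/A^3).

    For a 3D volume the ROI is taken in each of the central slices (default
    5) and the voxel population pooled.
    """
    vol = np.asarray(rho_e_volume, dtype=np.float64)
    if vol.ndim == 2:
        vol = vol[None]
    if n_slices is None:
        n_slices = min(5, vol.shape[0])
    c = vol.shape[0] // 2
    lo = max(0, c - n_slices // 2)
    sel = vol[lo : lo + n_slices]
    roi = homogeneous_roi.extract(sel)
    if roi.size < 1000:
        warnings.warn("homogeneous ROI has fewer than 1000 voxels", stacklevel=2)
    return float(roi.std())


def cnr(
    slice_image: np.ndarray, signal_roi: RoiSpec, background_roi: RoiSpec
) -> float:
    """Contrast-to-noise ratio |I_s - I_b| / sigma_b between two ROIs."""
    sr, sc = signal_roi.slices()
    br, bc = background_roi.slices()
    if not (
        sr.stop <= br.start or br.stop <= sr.start
        or sc.stop <= bc.start or bc.stop <= sc.start
    ):
        raise ValueError("signal and background ROIs must be disjoint")
    sl = np.asarray(slice_image, dtype=np.float64)
    i_s = signal_roi.extract(sl).mean()
    bg = background_roi.extract(sl)
    sigma_b = bg.std()
    if sigma_b == 0:
        raise ValueError("background ROI has zero standard deviation")
    return float(abs(i_s - bg.mean()) / sigma_b)
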
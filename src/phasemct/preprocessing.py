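"""Raw-frame conditioning: dark/flat correction, bad pixels, beam profile, drift.

All operations act on single 2D frames or small stacks of them and are
deliberately conservative: pixels that are not flagged are returned
bit-identical, and every correction is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation


@dataclass(frozen=True)
class CorrectionConfig:
    """Knobs of the preprocessing stage.

    ``beamprofile_kernel_px`` is the low-pass kernel used to estimate the
    smooth illumination profile from reference frames (default 50 px, large
    compared to any modulation period so the pattern averages out).
    """

    badpixel_sigma: float = 8.0
    beamprofile_kernel_px: int = 50
    drift_correction: bool = True
    drift_upsample: int = 20

    def __post_init__(self) -> None:
        if self.badpixel_sigma <= 0:
            raise ValueError("badpixel_sigma must be positive")
        if self.beamprofile_kernel_px < 3:
            raise ValueError("beamprofile kernel must be >= 3 px")


def correct_dark_flat(
    raw: np.ndarray, dark_mean: np.ndarray, flat_mean: np.ndarray
) -> np.ndarray:
    """Dark-current and flat-field correction (raw - dark) / (flat - dark).

    Pixels where the denominator is non-positive are set to NaN so that
    :func:`replace_bad_pixels` can repair them; if more than 5% of the frame
    is invalid the dark/flat pair is considered wrong and an error is raised.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape != dark_mean.shape or raw.shape != flat_mean.shape:
        raise ValueError("raw, dark and flat shapes must match")
    denom = flat_mean - dark_mean
    bad = denom <= 0
    if bad.mean() > 0.05:
        raise ValueError(
            f"{bad.mean():.1%} of pixels have non-positive flat-dark "
            "denominator; check dark/flat frames"
        )
    out = np.empty_like(raw)
    np.divide(raw - dark_mean, denom, out=out, where=~bad)
    out[bad] = np.nan
    return out


def _median_of_neighbours(image: np.ndarray) -> np.ndarray:
    """8-neighbour median, ignoring NaNs; ties resolved toward the lower value."""
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    padded = np.pad(image, 1, mode="reflect")
    stacks = []
    offs = [(i, j) for i in range(3) for j in range(3) if not (i == 1 and j == 1)]
    h, w = image.shape
    for i, j in offs:
        stacks.append(padded[i : i + h, j : j + w])
    neigh = np.stack(stacks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(neigh, axis=0)
    # nanmedian of an even count averages the two central values; round ties
    # toward the lower neighbour value by preferring the low-order statistic
    # when exactly between two distinct values is not required for repair
    return med


def replace_bad_pixels(image: np.ndarray, badpixel_sigma: float = 8.0) -> np.ndarray:
    """Replace outlier and non-finite pixels by the median of their neighbours.

    A pixel is flagged when its deviation from the local 3x3 median exceeds
    ``badpixel_sigma`` robust standard deviations (1.4826 * MAD of the
    deviation map).  Unflagged pixels are returned bit-identical, which makes
    the operation idempotent.
    """
    image = np.asarray(image, dtype=np.float64)
    nonfinite = ~np.isfinite(image)
    work = image.copy()
    if nonfinite.any():
        work[nonfinite] = np.nan
    local_med = ndimage.median_filter(
        np.nan_to_num(work, nan=0.0), size=3, mode="reflect"
    )
    dev = np.where(nonfinite, np.inf, work - local_med)
    finite_dev = dev[np.isfinite(dev)]
    mad = np.median(np.abs(finite_dev - np.median(finite_dev)))
    # floor the robust scale at 1% of the image magnitude so that smooth,
    # noise-free structure (where the MAD collapses) is never flagged
    image_scale = np.median(np.abs(work[np.isfinite(work)])) if np.isfinite(
        work
    ).any() else 1.0
    robust_sigma = max(1.4826 * mad, 0.01 * image_scale, 1e-300)
    flagged = nonfinite | (np.abs(dev) > badpixel_sigma * robust_sigma)
    if flagged.mean() > 0.10:
        raise ValueError(
            f"{flagged.mean():.1%} of pixels flagged as bad; "
            "this suggests a wrong dark/flat correction"
        )
    if not flagged.any():
        return image.copy()
    repaired = image.copy()
    repaired[flagged] = np.nan
    med = _median_of_neighbours(repaired)
    repaired[flagged] = med[flagged]
    return repaired


def estimate_beam_profile(
    reference_frames: np.ndarray, kernel_px: int = 50
) -> np.ndarray:
    """Smooth illumination profile: mean of the references, then a low-pass.

    The low-pass is a uniform (boxcar) kernel of the stated size; a kernel
    larger than the frame degenerates to the global mean.  The result must be
    strictly positive to serve as a flat field.
    """
    frames = np.asarray(reference_frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 1:
        raise ValueError("need at least one reference frame")
    mean = frames.mean(axis=0)
    size = int(round(kernel_px))
    if size % 2 == 0:
        size += 1
    if size >= max(mean.shape):
        profile = np.full_like(mean, mean.mean())
    else:
        profile = ndimage.uniform_filter(mean, size=size, mode="reflect")
    if (profile <= 0).any():
        raise ValueError("beam profile has non-positive pixels")
    return profile


def correct_drift(
    sample_frame: np.ndarray,
    reference_frames_for_step: np.ndarray,
    upsample: int = 20,
    peak_threshold: float = 0.05,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Register the modulator pattern of a frame against its stored reference.

    Estimates the rigid transverse shift between the current pattern and the
    mean reference by cross-correlation with sub-pixel (upsampled) peak
    localisation, then resamples the reference by that shift.  Returns the
    matched reference and the (row, col) shift in pixels; if the correlation
    peak is too weak, a warning is issued and the unshifted reference is
    returned.
    """
    refs = np.asarray(reference_frames_for_step, dtype=np.float64)
    if refs.ndim == 2:
        refs = refs[None]
    ref_mean = refs.mean(axis=0)
    sample = np.asarray(sample_frame, dtype=np.float64)
    shift, error, _ = phase_cross_correlation(
        ref_mean, sample, upsample_factor=upsample, normalization=None
    )
    # normalised correlation quality: 1 - error is ~ the correlation peak
    quality = 1.0 - float(error)
    if not np.isfinite(quality) or quality < peak_threshold:
        warnings.warn(
            "drift correlation peak below threshold; returning unshifted "
            "reference",
            stacklevel=2,
        )
        return ref_mean, (0.0, 0.0)
    # ref_mean shifted by -shift aligns with the sample pattern
    matched = ndimage.shift(ref_mean, -shift, order=1, mode="reflect")
    return matched, (float(-shift[0]), float(-shift[1]))
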
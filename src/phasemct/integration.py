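"""From differential phase to absolute phase projections.

The two orthogonal differential-phase channels measured by the pattern
matcher are turned into an absolute phase map in three steps: a first-order
polynomial background detrend of each gradient channel, least-squares
integration in Fourier space (the Frankot-Chellappa projection onto
integrable fields), and a second-order polynomial detrend of the integrated
phase to suppress residual low frequencies.  The DC term of the phase is
unrecoverable from gradients and is fixed to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class GradientField:
    """Two orthogonal phase-gradient channels in rad/m."""

    gx: np.ndarray
    gy: np.ndarray
    pixel_um: float

    def __post_init__(self) -> None:
        if self.gx.shape != self.gy.shape:
            raise ValueError("gx and gy must have equal shapes")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def pixel_m(self) -> float:
        return self.pixel_um * 1e-6


@dataclass
class PhaseProjection:
    """Integrated phase map (rad) with the mask of sample-free pixels."""

    phi: np.ndarray
    pixel_um: float
    background_mask: np.ndarray | None = None


def border_mask(
    shape: tuple[int, int], width_px: int = 32, sides: str = "all"
) -> np.ndarray:
    """Frame-border background mask of the given width.

    ``sides="lr"`` restricts the mask to the left/right margins - the
    appropriate choice for a specimen that extends through the full detector
    height, where only the horizontal margins are sample-free.
    """
    mask = np.zeros(shape, dtype=bool)
    w = min(width_px, min(shape) // 2)
    if sides not in ("all", "lr"):
        raise ValueError("sides must be 'all' or 'lr'")
    if sides == "all":
        mask[:w, :] = mask[-w:, :] = True
    mask[:, :w] = mask[:, -w:] = True
    return mask


def _poly_design(shape: tuple[int, int], order: int) -> np.ndarray:
    ny, nx = shape
    y = np.linspace(-1.0, 1.0, ny)
    x = np.linspace(-1.0, 1.0, nx)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [np.ones_like(yy)]
    for total in range(1, order + 1):
        for py in range(total + 1):
            px = total - py
            cols.append(yy**py * xx**px)
    return np.stack([c.ravel() for c in cols], axis=1)


def _fit_subtract_poly(
    image: np.ndarray, mask: np.ndarray, order: int
) -> np.ndarray:
    if mask.sum() == 0:
        raise ValueError("background mask is empty")
    if mask.sum() < 100:
        warnings.warn("background mask has fewer than 100 pixels", stacklevel=3)
    design = _poly_design(image.shape, order)
    sel = mask.ravel()
    a = design[sel]
    if np.linalg.matrix_rank(a) < design.shape[1]:
        raise ValueError(
            "degenerate (collinear) background mask geometry for polynomial fit"
        )
    coef, *_ = np.linalg.lstsq(a, image.ravel()[sel], rcond=None)
    return image - (design @ coef).reshape(image.shape)


def detrend_dpc(
    gradient_field: GradientField, background_mask: np.ndarray | None = None
) -> GradientField:
    """Subtract a first-order 2D polynomial fitted on background pixels.

    Removes slowly varying instrumental offsets (beam drifts, residual
    wavefront curvature) from each differential channel before integration.
    If no mask is given, a 32 px frame border is used.
    """
    mask = (
        background_mask
        if background_mask is not None
        else border_mask(gradient_field.gx.shape)
    )
    return GradientField(
        gx=_fit_subtract_poly(gradient_field.gx, mask, order=1),
        gy=_fit_subtract_poly(gradient_field.gy, mask, order=1),
        pixel_um=gradient_field.pixel_um,
    )


def fourier_integrate(gradient_field: GradientField) -> PhaseProjection:
    """Least-squares integration of a gradient field in Fourier space.

    Solves ``min ||grad(phi) - g||^2`` via

        phi_hat(f) = -i * (fx*gx_hat + fy*gy_hat) / (2*pi*(fx^2 + fy^2)),

    with frequencies in cycles/m and ``phi_hat(0) = 0``.  The field is
    mirror-extended (with the sign flips that keep the extension the gradient
    of an even phase) before the transform to suppress wrap-around.
    """
    gx, gy = gradient_field.gx, gradient_field.gy
    ny, nx = gx.shape
    # even extension of phi => gx flips sign across the x-mirror, gy across y
    gx_e = np.block(
        [[gx, -gx[:, ::-1]], [gx[::-1, :], -gx[::-1, ::-1]]]
    )
    gy_e = np.block(
        [[gy, gy[:, ::-1]], [-gy[::-1, :], -gy[::-1, ::-1]]]
    )
    d = gradient_field.pixel_m
    fy = np.fft.fftfreq(2 * ny, d=d)[:, None]
    fx = np.fft.fftfreq(2 * nx, d=d)[None, :]
    gxh = np.fft.fft2(gx_e)
    gyh = np.fft.fft2(gy_e)
    denom = fx**2 + fy**2
    denom[0, 0] = 1.0
    phi_hat = -1j * (fx * gxh + fy * gyh) / (2.0 * np.pi * denom)
    phi_hat[0, 0] = 0.0
    phi = np.real(np.fft.ifft2(phi_hat))[:ny, :nx]
    return PhaseProjection(phi=phi, pixel_um=gradient_field.pixel_um)


def detrend_phase(
    phase: PhaseProjection, background_mask: np.ndarray | None = None
) -> PhaseProjection:
    """Subtract a second-order 2D polynomial fitted on background pixels."""
    mask = (
        background_mask
        if background_mask is not None
        else (
            phase.background_mask
            if phase.background_mask is not None
            else border_mask(phase.phi.shape)
        )
    )
    return PhaseProjection(
        phi=_fit_subtract_poly(phase.phi, mask, order=2),
        pixel_um=phase.pixel_um,
        background_mask=mask,
    )
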
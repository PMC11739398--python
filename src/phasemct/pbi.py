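"""Single-distance propagation-based phase retrieval (Paganin-type filter).

For a single-material (or two-material interface) object the transport-of-
intensity equation links the flat-corrected intensity at one propagation
distance to the projected thickness through a low-pass filter,

    t(x, y) = -(1/mu) * ln( invF[ F[I_z/I_0] / (1 + pi*lambda*z*gamma*|f|^2) ] ),

with spatial frequencies ``f`` in cycles per metre, ``gamma = delta/beta``
the material ratio and ``mu = 4*pi*beta/lambda = 4*pi*delta/(gamma*lambda)``.
The retrieval is qualitative by construction - it assumes a fixed
composition - so quantitative claims are routed through the modulation-based
chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .integration import PhaseProjection
from .physics import BeamConfig, OpticalConstants, optical_constants, wavelength_from_energy


@dataclass(frozen=True)
class PaganinConfig:
    """Filter parameters.

    ``gamma`` defaults to 202.43, a tabulated soft-tissue-in-wax interface
    value; ``delta_eff`` is the refractive decrement used to express ``mu``
    and the phase channel (default: the soft-tissue/paraffin contrast at the
    beam energy).
    """

    gamma: float = 202.43
    z_m: float = 0.093
    energy_keV: float = 20.0
    pixel_um: float = 1.28
    delta_eff: float | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.z_m <= 0:
            raise ValueError("z_m must be positive")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    def resolved_delta(self) -> float:
        if self.delta_eff is not None:
            return self.delta_eff
        d_t = optical_constants("soft_tissue", self.energy_keV).delta
        d_p = optical_constants("paraffin", self.energy_keV).delta
        return d_t - d_p


@dataclass
class PaganinResult:
    """Projected thickness (m) and the corresponding phase channel."""

    thickness_m: np.ndarray
    phase: PhaseProjection
    n_clipped: int = 0


def paganin_filter(
    intensity_ratio_image: np.ndarray, config: PaganinConfig = PaganinConfig()
) -> PaganinResult:
    """Retrieve projected thickness from a flat-corrected intensity image.

    The input must be ``I_z / I_0`` (strictly positive).  Non-positive
    pixels after filtering are clipped to a tiny positive value before the
    logarithm; their count is reported.  The phase channel is
    ``Phi = -k * delta_eff * t``, the wavefront phase of the retrieved
    thickness.
    """
    img = np.asarray(intensity_ratio_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("input must be a 2D image")
    if (img <= 0).any():
        raise ValueError("intensity ratio must be strictly positive")
    lam = wavelength_from_energy(config.energy_keV)
    k = 2.0 * np.pi / lam
    d = config.pixel_um * 1e-6
    fy = np.fft.fftfreq(img.shape[0], d=d)[:, None]
    fx = np.fft.fftfreq(img.shape[1], d=d)[None, :]
    denom = 1.0 + np.pi * lam * config.z_m * config.gamma * (fx**2 + fy**2)
    filtered = np.real(np.fft.ifft2(np.fft.fft2(img) / denom))
    n_clipped = int((filtered <= 0).sum())
    if n_clipped:
        warnings.warn(
            f"{n_clipped} non-positive pixels clipped after Paganin filtering",
            stacklevel=2,
        )
        filtered = np.clip(filtered, 1e-12, None)
    delta = config.resolved_delta()
    mu = 4.0 * np.pi * delta / (config.gamma * lam)
    thickness = -np.log(filtered) / mu
    phi = -k * delta * thickness
    return PaganinResult(
        thickness_m=thickness,
        phase=PhaseProjection(phi=phi, pixel_um=config.pixel_um),
        n_clipped=n_clipped,
    )


def tune_gamma(
    material_a: str | OpticalConstants,
    material_b: str | OpticalConstants,
    energy_keV: float = 20.0,
) -> float:
    """delta/beta ratio for a two-material interface from tabulated constants.

    For distinct materials the differential ratio
    ``(delta_a - delta_b) / (beta_a - beta_b)`` is returned - the quantity
    governing edge contrast at the interface; for identical materials the
    plain ``delta/beta`` of that material.  Note the result is sensitive to
    the assumed compositions and densities (a few percent density change
    moves the differential ratio by tens of percent), so printed literature
    values are matched only to that tolerance.
    """
    oa = (
        optical_constants(material_a, energy_keV)
        if isinstance(material_a, str)
        else material_a
    )
    ob = (
        optical_constants(material_b, energy_keV)
        if isinstance(material_b, str)
        else material_b
    )
    if oa.material_name == ob.material_name:
        if oa.beta == 0:
            raise ValueError("pure-phase material: delta/beta is infinite")
        return oa.delta / ob.beta
    dbeta = oa.beta - ob.beta
    ddelta = oa.delta - ob.delta
    if abs(dbeta) < 1e-300 or not np.isfinite(ddelta / dbeta):
        raise ValueError(
            "degenerate interface: beta contrast vanishes, gamma is infinite"
        )
    return ddelta / dbeta
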
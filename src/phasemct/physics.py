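"""Beam physics, optical constants and unit conversions.

X-ray refraction and absorption of a material enter through the complex
refractive index ``n = 1 - delta + i*beta``.  Away from absorption edges
(valid for the light elements used here at 20 keV) the decrement is fixed by
the electron density,

    delta = r0 * lambda**2 * n_e / (2 * pi),

with ``r0`` the classical electron radius, while ``beta`` follows from the
linear attenuation coefficient, ``mu = 4*pi*beta/lambda``.  A small table of
material compositions (density, electrons per gram, mass attenuation
coefficient at 20 keV) replaces an external optical-constants library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# -- fundamental constants ---------------------------------------------------

#: classical electron radius (m)
R0_M = 2.8179403262e-15
#: Avogadro constant (1/mol)
N_AVOGADRO = 6.02214076e23
#: h*c in keV*m; lambda_m = HC_KEV_M / E_keV
HC_KEV_M = 1.2398419843320026e-09


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants used in density conversions."""

    r0_m: float = R0_M


def wavelength_from_energy(energy_keV: float) -> float:
    """Photon wavelength (m) for a photon energy in keV."""
    if energy_keV <= 0:
        raise ValueError("energy_keV must be positive")
    return HC_KEV_M / energy_keV


@dataclass(frozen=True)
class BeamConfig:
    """Monochromatic beam description.

    Parameters
    ----------
    energy_keV:
        Photon energy in keV (default 20, hard X-ray regime typical of
        synchrotron micro-CT of soft tissue).
    """

    energy_keV: float = 20.0

    def __post_init__(self) -> None:
        if self.energy_keV <= 0:
            raise ValueError("energy_keV must be positive")

    @property
    def wavelength_m(self) -> float:
        return wavelength_from_energy(self.energy_keV)

    @property
    def wavenumber(self) -> float:
        """k = 2*pi/lambda in 1/m."""
        return 2.0 * np.pi / self.wavelength_m


@dataclass(frozen=True)
class OpticalConstants:
    """Complex refractive index n = 1 - delta + i*beta of one material."""

    material_name: str
    delta: float
    beta: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.beta < 0:
            raise ValueError("delta and beta must be non-negative")

    @property
    def refractive_index(self) -> complex:
        return 1.0 - self.delta + 1j * self.beta


@dataclass(frozen=True)
class MaterialComposition:
    """Bulk composition entry: density, electrons/gram, mu/rho at 20 keV."""

    name: str
    density_g_cm3: float
    electrons_per_gram: float
    mu_rho_20keV_cm2_g: float


def _e_per_g(z_over_a: float) -> float:
    return N_AVOGADRO * z_over_a


# Compositions: Z/A from stoichiometry; mass attenuation coefficients are
# tabulated totals (with coherent) at 20 keV.  Paraffin modelled as C25H52,
# soft tissue as ICRU-44 average soft tissue, red blood cells as slightly
# denser protein/iron-rich tissue.
MATERIALS: dict[str, MaterialComposition] = {
    "vacuum": MaterialComposition("vacuum", 0.0, 0.0, 0.0),
    "air": MaterialComposition("air", 0.0, 0.0, 0.0),  # negligible at mm paths
    "silicon": MaterialComposition("silicon", 2.33, _e_per_g(14.0 / 28.0855), 4.464),
    "silicon_carbide": MaterialComposition(
        "silicon_carbide", 3.21, _e_per_g(20.0 / 40.0962), 3.259
    ),
    "paraffin": MaterialComposition("paraffin", 0.93, _e_per_g(202.0 / 352.691), 0.431),
    "soft_tissue": MaterialComposition("soft_tissue", 1.06, _e_per_g(0.54996), 0.8205),
    "blood_cell": MaterialComposition("blood_cell", 1.10, _e_per_g(0.5500), 0.850),
    "water": MaterialComposition("water", 1.00, _e_per_g(0.55508), 0.8096),
}


def optical_constants(material: str, energy_keV: float = 20.0) -> OpticalConstants:
    """Look up delta and beta of a named material at the given energy.

    delta scales exactly as lambda**2 through the electron density; beta is
    anchored at 20 keV and scaled with the photoelectric-dominated
    approximation mu/rho ~ E**-3 (adequate for the light elements here in the
    15-40 keV range).
    """
    try:
        comp = MATERIALS[material]
    except KeyError:
        raise KeyError(
            f"unknown material {material!r}; known: {sorted(MATERIALS)}"
        ) from None
    lam = wavelength_from_energy(energy_keV)
    n_e_m3 = comp.density_g_cm3 * comp.electrons_per_gram * 1e6  # electrons / m^3
    delta = R0_M * lam**2 * n_e_m3 / (2.0 * np.pi)
    mu_rho = comp.mu_rho_20keV_cm2_g * (20.0 / energy_keV) ** 3
    mu_m = mu_rho * comp.density_g_cm3 * 1e2  # 1/m
    beta = mu_m * lam / (4.0 * np.pi)
    return OpticalConstants(material, delta, beta)


# -- unit layer --------------------------------------------------------------


def px_to_um(value_px: float | np.ndarray, pixel_um: float) -> float | np.ndarray:
    """Detector pixels -> micrometres in the sample plane."""
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    return value_px * pixel_um


def um_to_px(value_um: float | np.ndarray, pixel_um: float) -> float | np.ndarray:
    """Micrometres in the sample plane -> detector pixels."""
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    return value_um / pixel_um


def fov_mm(shape_px: tuple[int, int], pixel_um: float) -> tuple[float, float]:
    """Field of view (rows_mm, cols_mm) of a detector."""
    return tuple(s * pixel_um * 1e-3 for s in shape_px)  # type: ignore[return-value]


def phase_shift_rad(
    material: str, thickness_um: float, energy_keV: float = 20.0
) -> float:
    """Phase delay k*delta*t accumulated through a slab of given thickness."""
    oc = optical_constants(material, energy_keV)
    beam = BeamConfig(energy_keV)
    return beam.wavenumber * oc.delta * thickness_um * 1e-6
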
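"""Optical geometry, Stokes-Einstein conversion and the thin-shell vesicle mass model.

Unit conventions used throughout the package: wavelength in nm (in vacuo),
scattering angle in degrees, temperature in K, viscosity in mPa*s, decay
rates in 1/us, scattering vector in 1/um, diameters in nm, concentrations
in mg/mL, volumes in mL, masses in mg (vesicle masses in Da).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN_J_PER_K",
    "OpticalConfig",
    "ShellModel",
    "scattering_vector",
    "diameter_from_decay_rate",
    "stokes_einstein_diameter",
    "gamma_from_diameter",
    "shell_mass",
    "detection_limit",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and solvent parameters of a light-scattering measurement.

    Parameters
    ----------
    wavelength_nm : float
        Laser wavelength in vacuo, nm.
    angle_deg : float
        Scattering angle, degrees, in (0, 180).
    refractive_index : float
        Solvent refractive index n0 (>= 1).
    temperature_K : float
        Absolute temperature of the scattering cell, K.
    viscosity_mPas : float
        Solvent dynamic viscosity, mPa*s. The default is water at 20 C.
    """

    wavelength_nm: float = 532.0
    angle_deg: float = 90.0
    refractive_index: float = 1.333
    temperature_K: float = 293.15
    viscosity_mPas: float = 1.002

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ValueError(f"wavelength_nm must be positive, got {self.wavelength_nm}")
        if not 0.0 < self.angle_deg < 180.0:
            raise ValueError(
                f"angle_deg must lie strictly between 0 and 180, got {self.angle_deg}"
            )
        if not self.refractive_index >= 1.0:
            raise ValueError(f"refractive_index must be >= 1, got {self.refractive_index}")
        if not self.temperature_K > 0:
            raise ValueError(f"temperature_K must be positive, got {self.temperature_K}")
        if not self.viscosity_mPas > 0:
            raise ValueError(f"viscosity_mPas must be positive, got {self.viscosity_mPas}")


@dataclass(frozen=True)
class ShellModel:
    """Thin spherical shell mass model of a unilamellar vesicle.

    All the lipid mass is taken to sit in an infinitely thin shell of
    diameter D, so the vesicle mass is (number of lipids) x (lipid mass)
    = (2 * 4pi(D/2)^2 / head_area) * lipid_mass, the factor 2 counting
    both leaflets of the bilayer.

    Parameters
    ----------
    lipid_mass_Da : float
        Mass of a single lipid molecule, Da.  Default is POPC (760.1 Da).
    head_area_nm2 : float
        Average area per lipid head group in the membrane, nm^2.
        Default 0.63 nm^2 (POPC).
    """

    lipid_mass_Da: float = 760.1
    head_area_nm2: float = 0.63

    def __post_init__(self) -> None:
        if not self.lipid_mass_Da > 0:
            raise ValueError("lipid_mass_Da must be positive")
        if not self.head_area_nm2 > 0:
            raise ValueError("head_area_nm2 must be positive")


def scattering_vector(cfg: OpticalConfig) -> float:
    """Magnitude of the scattering vector q = (4 pi n0 / lambda) sin(theta/2).

    Returns
    -------
    float
        q in 1/um.
    """
    wavelength_um = cfg.wavelength_nm * 1e-3
    return (
        4.0
        * math.pi
        * cfg.refractive_index
        / wavelength_um
        * math.sin(math.radians(cfg.angle_deg) / 2.0)
    )


def diameter_from_decay_rate(
    gamma_bar_per_us: float,
    q_per_um: float,
    temperature_K: float,
    viscosity_mPas: float,
) -> float:
    """Hydrodynamic diameter from a mean decay rate via Stokes-Einstein.

    D_h = kB * T * q^2 / (3 pi eta Gamma_bar), i.e. the diffusion
    coefficient Gamma_bar / q^2 mapped to the diameter of the equivalent
    sphere.

    Parameters
    ----------
    gamma_bar_per_us : float
        Mean decay rate of the field correlation function, 1/us.
    q_per_um : float
        Scattering vector magnitude, 1/um.
    temperature_K, viscosity_mPas : float
        Solvent temperature and dynamic viscosity.

    Returns
    -------
    float
        Hydrodynamic diameter in nm.
    """
    if not gamma_bar_per_us > 0:
        raise ValueError(f"decay rate must be positive, got {gamma_bar_per_us}")
    if not q_per_um > 0:
        raise ValueError(f"scattering vector must be positive, got {q_per_um}")
    q_per_m = q_per_um * 1e6
    gamma_per_s = gamma_bar_per_us * 1e6
    eta_Pas = viscosity_mPas * 1e-3
    d_m = (
        BOLTZMANN_J_PER_K
        * temperature_K
        * q_per_m**2
        / (3.0 * math.pi * eta_Pas * gamma_per_s)
    )
    return d_m * 1e9


def stokes_einstein_diameter(gamma_bar_per_us: float, cfg: OpticalConfig) -> float:
    """Hydrodynamic diameter (nm) from a decay rate (1/us) under ``cfg``."""
    return diameter_from_decay_rate(
        gamma_bar_per_us, scattering_vector(cfg), cfg.temperature_K, cfg.viscosity_mPas
    )


def gamma_from_diameter(diameter_nm: float, cfg: OpticalConfig) -> float:
    """Decay rate (1/us) of a sphere of hydrodynamic diameter ``diameter_nm``.

    Exact algebraic inverse of :func:`stokes_einstein_diameter`.
    """
    if not diameter_nm > 0:
        raise ValueError(f"diameter must be positive, got {diameter_nm}")
    q_per_m = scattering_vector(cfg) * 1e6
    eta_Pas = cfg.viscosity_mPas * 1e-3
    gamma_per_s = (
        BOLTZMANN_J_PER_K
        * cfg.temperature_K
        * q_per_m**2
        / (3.0 * math.pi * eta_Pas * diameter_nm * 1e-9)
    )
    return gamma_per_s * 1e-6


def shell_mass(diameter_nm: float, model: ShellModel | None = None) -> float:
    """Mass (Da) of a thin-shell vesicle of diameter ``diameter_nm``.

    M(D) = (2 pi M_lip / dA_lip) * D^2: the bilayer surface 2 * pi D^2
    (both leaflets) divided by the area per head group, times the lipid
    mass.  Scales exactly as D^2.
    """
    if not diameter_nm > 0:
        raise ValueError(f"diameter must be positive, got {diameter_nm}")
    model = model if model is not None else ShellModel()
    return 2.0 * math.pi * model.lipid_mass_Da / model.head_area_nm2 * diameter_nm**2


def detection_limit(c_lim_ref_mg_ml: float, d_ref_nm: float, d_nm: float) -> float:
    """Minimum detectable weight concentration at diameter ``d_nm``.

    At a fixed scattered-intensity threshold, I = k * Mw * C with the
    shell model Mw ~ D^2 gives a detectable-concentration floor scaling
    as 1/D^2: c_lim(D) = c_lim_ref * (d_ref / D)^2.

    Parameters
    ----------
    c_lim_ref_mg_ml : float
        Known concentration limit at the reference diameter, mg/mL.
    d_ref_nm : float
        Reference diameter, nm.
    d_nm : float
        Diameter at which the limit is requested, nm.
    """
    if not c_lim_ref_mg_ml > 0:
        raise ValueError("reference concentration limit must be positive")
    if not d_ref_nm > 0 or not d_nm > 0:
        raise ValueError("diameters must be positive")
    return c_lim_ref_mg_ml * (d_ref_nm / d_nm) ** 2
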
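"""Classical and modified Stokes-Einstein diffusion coefficients.

The classical relation ``D = k_B T / (6 pi eta0 a)`` treats the particle as
a sphere in a solvent of fixed viscosity.  The modified model replaces the
solvent viscosity with the concentration-dependent effective viscosity of
the whole suspension and the sphere drag with the orientation-resolved
prolate-spheroid drag, giving per-species upper (parallel motion) and
lower (perpendicular motion) limits of the diffusion coefficient:

    k_upper = k_B T / f_par(shape, eta_e),
    k_lower = k_B T / f_perp(shape, eta_e).

As the solute fractions vanish, eta_e -> eta0 and a spherical species
recovers the classical value exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._constants import AVOGADRO, BOLTZMANN, ROOM_TEMPERATURE
from .geometry import (
    RodShape,
    SphereShape,
    SpeciesGeometry,
    SpheroidShape,
    eccentricity,
)
from .hydrodynamics import (
    rod_shape_factor,
    sphere_drag,
    spheroid_drag_parallel,
    spheroid_drag_perpendicular,
)
from .kinetics import KineticState
from .viscosity import (
    MixtureComposition,
    QuemadaParams,
    mixture_effective_viscosity,
    quemada_relative,
)

__all__ = [
    "ThermoParams",
    "DiffusionEstimate",
    "SedimentationParams",
    "classical_stokes_einstein",
    "sedimentation_coefficient",
    "concentrations_to_volume_fractions",
    "effective_diffusion_bounds",
    "one_species_limit",
    "sphere_rod_diffusion",
]


@dataclass(frozen=True)
class ThermoParams:
    """Absolute temperature (K); Boltzmann constant fixed at CODATA value."""

    temperature: float = ROOM_TEMPERATURE
    k_B: float = BOLTZMANN

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def thermal_energy(self) -> float:
        return self.k_B * self.temperature


@dataclass(frozen=True)
class DiffusionEstimate:
    """Lower/upper effective diffusion bounds (m^2/s) for one species."""

    species: int
    k_lower: float
    k_upper: float
    time: float = 0.0  # h

    def __post_init__(self) -> None:
        if not 0 < self.k_lower <= self.k_upper:
            raise ValueError(
                f"bounds must satisfy 0 < k_lower <= k_upper, got "
                f"({self.k_lower}, {self.k_upper})"
            )


@dataclass(frozen=True)
class SedimentationParams:
    """Inputs of the sedimentation-coefficient formula.

    Molecular mass in g/mol, partial specific volume in mL/g, buffer
    density in g/mL, buffer viscosity in Pa*s, particle radius in m.
    """

    molecular_mass: float
    partial_specific_volume: float
    buffer_density: float
    buffer_viscosity: float
    radius: float
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        for name in (
            "molecular_mass",
            "partial_specific_volume",
            "buffer_density",
            "buffer_viscosity",
            "radius",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def classical_stokes_einstein(
    radius: float, thermo: ThermoParams, eta0: float
) -> float:
    """Classical Stokes-Einstein coefficient ``k_B T / (6 pi eta0 a)`` (m^2/s)."""
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if not eta0 > 0:
        raise ValueError(f"viscosity must be positive, got {eta0}")
    return thermo.thermal_energy / (6.0 * math.pi * eta0 * radius)


def sedimentation_coefficient(params: SedimentationParams) -> float:
    """Sedimentation coefficient ``s = M (1 - vbar rho) / (N 6 pi eta a)`` (s).

    ``M`` in g/mol is converted to kg/mol so the result is in SI seconds;
    neutral buoyancy (``vbar * rho = 1``) gives zero.
    """
    mass_kg_per_mol = params.molecular_mass * 1e-3
    buoyancy = 1.0 - params.partial_specific_volume * params.buffer_density
    drag = 6.0 * math.pi * params.buffer_viscosity * params.radius
    return mass_kg_per_mol * buoyancy / (params.avogadro * drag)


def concentrations_to_volume_fractions(
    state: KineticState,
    geometries: list[SpeciesGeometry],
    mode: str = "absolute",
) -> MixtureComposition:
    """Convert species concentrations (mM) to a volume-fraction composition.

    ``phi_i = N_A * C_i * V_i`` with ``C_i`` in mol/m^3 (numerically equal
    to mM) and ``V_i`` the species' particle volume; the solvent takes the
    remainder.  ``mode`` is stored on the composition and selects the
    averaging-weight convention used later by the effective viscosity.
    """
    if len(state.concentrations) != len(geometries):
        raise ValueError(
            f"state has {len(state.concentrations)} species, geometries "
            f"describe {len(geometries)}"
        )
    phi = tuple(
        AVOGADRO * max(c, 0.0) * g.particle_volume
        for c, g in zip(state.concentrations, geometries)
    )
    total = sum(phi)
    if total > 1.0:
        raise ValueError(
            f"solute volume fractions sum to {total:.4g} > 1; "
            "concentrations or particle volumes are unphysical"
        )
    return MixtureComposition(phi0=1.0 - total, phi=phi, mode=mode)


def effective_diffusion_bounds(
    composition: MixtureComposition,
    geometries: list[SpeciesGeometry],
    thermo: ThermoParams,
    visc_params: QuemadaParams,
    time: float = 0.0,
) -> list[DiffusionEstimate]:
    """Per-species diffusion bounds at one composition.

    The effective viscosity of the whole suspension is evaluated once and
    enters every species' drag.  Spheroidal species get orientation-split
    bounds; spherical species (or degenerate spheroids with zero
    eccentricity) get the single isotropic value reported as both bounds.
    """
    eta_e = mixture_effective_viscosity(composition, visc_params)
    kT = thermo.thermal_energy
    out = []
    for g in geometries:
        shape = g.shape
        if isinstance(shape, SpheroidShape) and eccentricity(shape) > 0.0:
            upper = kT / spheroid_drag_parallel(shape, eta_e).value
            lower = kT / spheroid_drag_perpendicular(shape, eta_e).value
        else:
            radius = (
                shape.radius
                if isinstance(shape, SphereShape)
                else shape.semi_major
            )
            iso = kT / sphere_drag(radius, eta_e).value
            upper = lower = iso
        out.append(
            DiffusionEstimate(
                species=g.multiplicity, k_lower=lower, k_upper=upper, time=time
            )
        )
    return out


def one_species_limit(
    phi: float,
    phi0: float,
    radius: float,
    thermo: ThermoParams,
    eta0: float,
    phi_m: float = 0.6,
    expansion: bool = False,
) -> float:
    """Single-species modified coefficient and its small-fraction expansion.

    Full form: ``D = k_B T / (6 pi eta0 a (phi0 + phi (1-phi/phi_m)^-2))``,
    the one-species reduction of the mixture model in absolute-weight mode.
    With ``expansion=True`` the first-order form in ``eps = phi/phi0`` is
    returned, ``D = k_B T / (6 pi eta0 a phi0 (1 + eps))``; the two agree
    to O(eps^2).  At ``phi = 0, phi0 = 1`` both equal the classical value.
    """
    if phi < 0 or phi0 <= 0:
        raise ValueError("need phi >= 0 and phi0 > 0")
    if expansion:
        factor = phi0 * (1.0 + phi / phi0)
    else:
        factor = phi0 + phi * quemada_relative(phi, phi_m)
    return classical_stokes_einstein(radius, thermo, eta0) / factor


def sphere_rod_diffusion(
    phi_r: float,
    phi_s: float,
    rod: RodShape,
    sphere: SphereShape,
    params: QuemadaParams,
    thermo: ThermoParams,
    orientation: str = "perpendicular",
) -> float:
    """Rod diffusion coefficient in the sphere-rod suspension (m^2/s).

    Below the dilute-rod boundary ``phi_r <= 0.125`` the rod senses only
    the solvent-plus-spheres continuum; above it rod crowding is included
    through the full sphere-rod effective viscosity.  The boundary itself
    takes the dilute branch.
    """
    from .viscosity import sphere_rod_effective_viscosity

    if phi_r <= 0.125:
        phi_s_hat = phi_s / (1.0 - phi_r) if phi_s > 0 else 0.0
        eta_bg = params.eta0 * quemada_relative(phi_s_hat, params.phi_m)
    else:
        eta_bg = sphere_rod_effective_viscosity(phi_r, phi_s, rod, sphere, params)
    factor = rod_shape_factor(rod, orientation)
    return thermo.thermal_energy / (factor * eta_bg * rod.length)
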
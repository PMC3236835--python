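"""Concentration-dependent effective viscosity of protofibril suspensions.

Two models are provided.

**Quemada mixture model** (the core of the package).  A single hard-particle
suspension at volume fraction ``phi`` has relative viscosity
``(1 - phi/phi_m)**-2`` (Quemada), diverging at the maximum packing
fraction ``phi_m`` (default 0.6, the midpoint of the literature range
0.58-0.69).  For an n-species suspension the effective viscosity is a
weighted average of component viscosities,

    eta_e = phi_0 * eta_0 + sum_j w_j * eta_j,

where ``eta_j`` is the viscosity of the whole suspension viewed with
species ``j`` outermost: species ``j`` suspended in a background made of
the solvent plus all other species, that background itself built by the
same rule following the cyclic order ``j, j+1, ..., n, 1, ..., j-1``.
Peeling the chain inward, the species at position ``p`` contributes a
Quemada factor evaluated at its volume fraction *relative to the part of
the suspension that still contains it*, i.e. ``phi_k / (1 - sum of
fractions peeled off before it)``; the outermost relative fraction is the
plain ``phi_j``, which makes the per-species definitions even under
relabelling.  Averaging weights ``w_j`` are the absolute fractions
(``absolute`` mode, solvent weighted by ``phi_0``) or the solute-normalised
fractions summing to one with the solvent dropped (``solute_normalized``
mode).

**Sphere-rod empirical model.**  For a bidisperse suspension of small
spheres and long rods (rod half-length more than 20x the sphere radius)
the small spheres are treated as part of the continuous phase sensed by the
rods, so relative viscosities compose multiplicatively:

    eta = eta_rel_rod(phi_r) * eta_rel_sphere(phi_s_hat) * eta_0.

The sphere factor uses the Quemada/Maron-Pierce form; the rod factor uses
the same form with an aspect-ratio-dependent packing fraction
``phi_m(p) = 0.53 - 0.013 p`` (Kitano-Kataoka), which confines the model
to moderately slender rods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .geometry import RodShape, SphereShape

__all__ = [
    "QuemadaParams",
    "MixtureComposition",
    "ViscositySingularityError",
    "quemada_viscosity",
    "quemada_relative",
    "relative_solute_fraction",
    "mixture_effective_viscosity",
    "sphere_rod_effective_viscosity",
]

FRACTION_MODES = ("absolute", "solute_normalized")


class ViscositySingularityError(ValueError):
    """A volume fraction reached the maximum packing fraction."""


@dataclass(frozen=True)
class QuemadaParams:
    """Solvent viscosity (Pa*s) and maximum packing fraction."""

    eta0: float = 0.89e-3
    phi_m: float = 0.6

    def __post_init__(self) -> None:
        if not self.eta0 > 0:
            raise ValueError(f"solvent viscosity must be positive, got {self.eta0}")
        if not 0.0 < self.phi_m <= 1.0:
            raise ValueError(f"phi_m must lie in (0, 1], got {self.phi_m}")


@dataclass(frozen=True)
class MixtureComposition:
    """Solvent plus per-species solute volume fractions.

    ``phi`` holds the absolute solute fractions (they always sum with
    ``phi0`` to one); ``mode`` records which averaging-weight convention
    the effective-viscosity computation should use.
    """

    phi0: float
    phi: tuple[float, ...]
    mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.mode not in FRACTION_MODES:
            raise ValueError(
                f"mode must be one of {FRACTION_MODES}, got {self.mode!r}"
            )
        if self.phi0 < 0 or any(p < 0 for p in self.phi):
            raise ValueError("volume fractions must be nonnegative")
        total = self.phi0 + sum(self.phi)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"volume fractions must sum to 1, got {total!r}"
            )

    @property
    def n_species(self) -> int:
        return len(self.phi)

    @property
    def solute_fraction(self) -> float:
        return sum(self.phi)

    def solute_normalized(self) -> tuple[float, ...]:
        """Solute fractions rescaled to sum to one (the Phi_0 = 1 convention)."""
        s = self.solute_fraction
        if s == 0.0:
            return tuple(0.0 for _ in self.phi)
        return tuple(p / s for p in self.phi)


def quemada_relative(phi: float, phi_m: float) -> float:
    """Quemada relative viscosity ``(1 - phi/phi_m)**-2``."""
    if phi < 0:
        raise ValueError(f"volume fraction must be nonnegative, got {phi}")
    if phi >= phi_m:
        raise ViscositySingularityError(
            f"volume fraction {phi:.6g} reached the packing fraction {phi_m}"
        )
    x = 1.0 - phi / phi_m
    return 1.0 / (x * x)


def quemada_viscosity(phi: float, params: QuemadaParams) -> float:
    """Suspension viscosity ``eta0 * (1 - phi/phi_m)**-2`` (Pa*s)."""
    return params.eta0 * quemada_relative(phi, params.phi_m)


def relative_solute_fraction(
    composition: MixtureComposition,
    j: int,
    excluded: Sequence[int] = (),
) -> float:
    """Volume fraction of solute ``j`` relative to the sub-suspension holding it.

    ``j`` is 1-based.  ``excluded`` lists the 1-based indices of solutes
    already peeled off the mixture (treated as absent); the fraction is
    then ``phi_j / (1 - sum(phi_k for k in excluded))``.  With nothing
    excluded this is the plain absolute fraction.
    """
    n = composition.n_species
    if not 1 <= j <= n:
        raise ValueError(f"species index must be in 1..{n}, got {j}")
    if j in excluded:
        raise ValueError(f"species {j} cannot be excluded from its own fraction")
    removed = 0.0
    for k in excluded:
        if not 1 <= k <= n:
            raise ValueError(f"excluded index {k} out of range 1..{n}")
        removed += composition.phi[k - 1]
    remaining = 1.0 - removed
    if remaining <= 0:
        raise ValueError("excluded fractions exhaust the suspension")
    return composition.phi[j - 1] / remaining


def _component_viscosity(
    composition: MixtureComposition, j: int, params: QuemadaParams
) -> float:
    """Viscosity eta_j of the suspension with species j outermost.

    Walks the cyclic chain j, j+1, ..., n, 1, ..., j-1, multiplying the
    solvent viscosity by one Quemada factor per species, each evaluated at
    the species' fraction relative to the sub-suspension that still
    contains it.
    """
    n = composition.n_species
    chain = [(j - 1 + k) % n + 1 for k in range(n)]
    eta = params.eta0
    peeled: list[int] = []
    for k in chain:
        phi_hat = relative_solute_fraction(composition, k, excluded=peeled)
        eta *= quemada_relative(phi_hat, params.phi_m)
        peeled.append(k)
    return eta


def mixture_effective_viscosity(
    composition: MixtureComposition, params: QuemadaParams
) -> float:
    """Effective viscosity of the n-species suspension (Pa*s).

    Weighted average of the solvent viscosity and the per-species component
    viscosities; see the module docstring for both conventions.  Raises
    :class:`ViscositySingularityError` if any relative fraction reaches
    ``phi_m``.
    """
    if composition.solute_fraction == 0.0:
        return params.eta0
    components = [
        _component_viscosity(composition, j, params)
        for j in range(1, composition.n_species + 1)
    ]
    if composition.mode == "absolute":
        return composition.phi0 * params.eta0 + sum(
            w * eta for w, eta in zip(composition.phi, components)
        )
    weights = composition.solute_normalized()
    return sum(w * eta for w, eta in zip(weights, components))


def sphere_rod_effective_viscosity(
    phi_r: float,
    phi_s: float,
    rod: RodShape,
    sphere: SphereShape,
    params: QuemadaParams,
) -> float:
    """Effective viscosity of a sphere-rod suspension (Pa*s).

    The spheres are sensed by the rods as part of the continuous phase:
    the sphere factor is evaluated at the sphere fraction relative to the
    solvent-plus-spheres sub-suspension, the rod factor at the rod fraction
    in the whole suspension, and the two compose multiplicatively on the
    solvent viscosity.  Requires rod half-length > 20x sphere radius, and a
    rod aspect ratio small enough that the fibre packing fraction
    ``0.53 - 0.013 L/d`` stays positive.
    """
    if phi_r < 0 or phi_s < 0:
        raise ValueError("volume fractions must be nonnegative")
    if phi_r + phi_s >= 1:
        raise ValueError("solute fractions must leave room for the solvent")
    a_r = rod.length / 2.0
    if not a_r / sphere.radius > 20.0:
        raise ValueError(
            "sphere-rod model applies only for rod half-length > 20x sphere "
            f"radius; got ratio {a_r / sphere.radius:.3g}"
        )
    p = rod.aspect_ratio
    phi_m_rod = 0.53 - 0.013 * p
    if phi_m_rod <= 0:
        raise ValueError(
            f"rod aspect ratio {p:.3g} exceeds the fibre-packing validity "
            "limit of the empirical model"
        )
    phi_s_hat = phi_s / (1.0 - phi_r) if phi_s > 0 else 0.0
    rel_s = quemada_relative(phi_s_hat, params.phi_m)
    rel_r = quemada_relative(phi_r, phi_m_rod)
    return rel_r * rel_s * params.eta0
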
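"""Particle shape models for protofibrils and their lateral aggregates.

An Abeta42 protofibril is modelled as a prolate spheroid with semi-major
axis ``c`` (half the fibril length) and semi-minor axis ``b`` (half the
fibril width).  Lateral (side-by-side) association of ``n`` protofibrils is
represented by an enveloping spheroid of the same length whose minor
semi-axis grows to ``n*b``; the enveloping volume therefore grows as
``n**2`` while the monomer content only grows as ``n``.  Three volume
conventions are provided for converting concentrations to volume fractions:

``envelope``
    each species occupies its enveloping spheroid volume (default);
``mass``
    each species occupies ``n`` times the base protofibril volume, so the
    total solute volume is exactly conserved along an association
    trajectory;
``count``
    every particle occupies the base protofibril volume regardless of size,
    so the total solute volume tracks the particle count and falls as
    protofibrils merge.  This is the convention under which the effective
    viscosity rises and falls with the protofibril concentration (the
    behaviour seen in suspensions when solute particles coalesce).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SphereShape",
    "SpheroidShape",
    "RodShape",
    "SpeciesGeometry",
    "MONOMERS_PER_PROTOFIBRIL",
    "VOLUME_MODES",
    "spheroid_volume",
    "sphere_volume",
    "eccentricity",
    "laterally_associate",
    "build_species_geometries",
]

#: Number of Abeta42 monomers in one protofibril.
MONOMERS_PER_PROTOFIBRIL = 1600

VOLUME_MODES = ("envelope", "mass", "count")


@dataclass(frozen=True)
class SphereShape:
    """Rigid sphere of radius ``a`` (m)."""

    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class SpheroidShape:
    """Prolate spheroid with semi-axes ``c >= b > 0`` (m).

    ``semi_major`` is half the particle length, ``semi_minor`` half its
    width; equal axes describe a sphere.
    """

    semi_major: float
    semi_minor: float

    def __post_init__(self) -> None:
        if not self.semi_minor > 0:
            raise ValueError(
                f"semi-minor axis must be positive, got {self.semi_minor}"
            )
        if self.semi_major < self.semi_minor:
            raise ValueError(
                "prolate spheroid requires semi_major >= semi_minor, got "
                f"c={self.semi_major} < b={self.semi_minor}"
            )


@dataclass(frozen=True)
class RodShape:
    """Rigid rod of length ``L`` and diameter ``d`` (m), ``L > d``."""

    length: float
    diameter: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"rod diameter must be positive, got {self.diameter}")
        if not self.length > self.diameter:
            raise ValueError(
                f"rod requires length > diameter, got L={self.length}, "
                f"d={self.diameter}"
            )

    @property
    def aspect_ratio(self) -> float:
        return self.length / self.diameter


def sphere_volume(shape: SphereShape) -> float:
    """Volume of a sphere, m^3."""
    return 4.0 / 3.0 * math.pi * shape.radius**3


def spheroid_volume(shape: SpheroidShape) -> float:
    """Volume of a prolate spheroid, ``(4/3) pi c b^2``, m^3."""
    return 4.0 / 3.0 * math.pi * shape.semi_major * shape.semi_minor**2


def eccentricity(shape: SpheroidShape) -> float:
    """Eccentricity ``e = sqrt(1 - b^2/c^2)`` of a prolate spheroid.

    Lies in ``[0, 1)``; zero for a sphere, approaching one for a slender
    filament.
    """
    ratio = shape.semi_minor / shape.semi_major
    return math.sqrt(max(0.0, 1.0 - ratio * ratio))


def laterally_associate(base: SpheroidShape, n: int) -> SpheroidShape:
    """Enveloping spheroid of ``n`` laterally associated base spheroids.

    Side-by-side association preserves the major axis and stacks the minor
    axis: the n-fold aggregate is enveloped by a spheroid with semi-axes
    ``(c, n*b)``.  Requires ``n*b <= c`` so the result stays prolate.
    """
    if n < 1:
        raise ValueError(f"association number must be >= 1, got {n}")
    return SpheroidShape(base.semi_major, n * base.semi_minor)


@dataclass(frozen=True)
class SpeciesGeometry:
    """Geometry of the n-fold laterally associated protofibril species.

    ``multiplicity`` n means the species is an (n*1600)-mer.  The
    ``particle_volume`` used for volume-fraction bookkeeping depends on the
    volume convention (see module docstring); ``shape`` is always the
    enveloping spheroid, which is what enters the drag calculation.
    """

    multiplicity: int
    shape: SpheroidShape | SphereShape
    particle_volume: float
    monomer_count: int = field(init=False)

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")
        if not self.particle_volume > 0:
            raise ValueError(
                f"particle volume must be positive, got {self.particle_volume}"
            )
        object.__setattr__(
            self, "monomer_count", MONOMERS_PER_PROTOFIBRIL * self.multiplicity
        )


def build_species_geometries(
    n_max: int,
    base: SpheroidShape,
    volume_mode: str = "envelope",
) -> list[SpeciesGeometry]:
    """Geometries of species ``F_1600 .. F_{n_max*1600}``.

    Species ``n`` has the enveloping shape ``laterally_associate(base, n)``
    and a particle volume set by ``volume_mode`` (see module docstring).
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    if volume_mode not in VOLUME_MODES:
        raise ValueError(
            f"volume_mode must be one of {VOLUME_MODES}, got {volume_mode!r}"
        )
    base_volume = spheroid_volume(base)
    out = []
    for n in range(1, n_max + 1):
        shape = laterally_associate(base, n)
        if volume_mode == "envelope":
            volume = spheroid_volume(shape)
        elif volume_mode == "mass":
            volume = n * base_volume
        else:  # count
            volume = base_volume
        out.append(SpeciesGeometry(n, shape, volume))
    return out
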
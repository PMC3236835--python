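"""Stokes drag coefficients for spheres, prolate spheroids and slender rods.

Prolate-spheroid translation is orientation dependent; the closed forms of
Chwang & Wu (singularity-method Stokes flow) are used for motion parallel
and perpendicular to the symmetry axis:

    f_par  = 16 pi eta c e^3 / [ (1 + e^2) Lambda - 2 e ]
    f_perp = 32 pi eta c e^3 / [ (3 e^2 - 1) Lambda + 2 e ]

with ``Lambda = ln((1+e)/(1-e))`` and eccentricity ``e``.  Both reduce to
the Stokes sphere drag ``6 pi eta c`` as ``e -> 0`` and to the slender-body
asymptotes ``4 pi eta c / (ln(2c/b) - 1/2)`` (parallel) as ``e -> 1``.
Near the sphere limit the closed forms lose precision to cancellation, so a
Taylor expansion in ``e**2`` is substituted below ``e = 1e-4``.

Slender rods use the Tirado & Garcia de la Torre shape factors with
end-effect corrections; the perpendicular factor always exceeds the
parallel one and their ratio tends to 2 for long rods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import RodShape, SphereShape, SpheroidShape, eccentricity

__all__ = [
    "DragCoefficient",
    "sphere_drag",
    "spheroid_drag_parallel",
    "spheroid_drag_perpendicular",
    "rod_shape_factor",
    "equivalent_radius",
]

# below this eccentricity the closed forms lose ~1e-6 relative precision to
# cancellation, so the denominators are evaluated by series (trunc. error
# O(e^6) < 1e-12 at the boundary); the e^3 prefactor cancels analytically,
# making the sphere limit exact at e = 0
_SERIES_ECCENTRICITY = 1e-2


@dataclass(frozen=True)
class DragCoefficient:
    """Translational drag f (N*s/m) with its orientation tag."""

    value: float
    orientation: str  # "isotropic" | "parallel" | "perpendicular"

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"drag coefficient must be positive, got {self.value}")
        if self.orientation not in ("isotropic", "parallel", "perpendicular"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


def sphere_drag(radius: float, eta: float) -> DragCoefficient:
    """Stokes drag ``6 pi eta a`` of a rigid sphere."""
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if not eta > 0:
        raise ValueError(f"viscosity must be positive, got {eta}")
    return DragCoefficient(6.0 * math.pi * eta * radius, "isotropic")


def _check_spheroid(shape: SpheroidShape, eta: float) -> float:
    if not eta > 0:
        raise ValueError(f"viscosity must be positive, got {eta}")
    return eccentricity(shape)


def spheroid_drag_parallel(shape: SpheroidShape, eta: float) -> DragCoefficient:
    """Drag for translation along the spheroid's major axis."""
    e = _check_spheroid(shape, eta)
    c = shape.semi_major
    if e < _SERIES_ECCENTRICITY:
        # ((1+e^2) Lambda - 2e) / e^3 = 8/3 + (16/15) e^2 + (24/35) e^4 + ...
        denom = 8.0 / 3.0 + 16.0 / 15.0 * e**2 + 24.0 / 35.0 * e**4
        f = 16.0 * math.pi * eta * c / denom
    else:
        lam = math.log((1.0 + e) / (1.0 - e))
        f = 16.0 * math.pi * eta * c * e**3 / ((1.0 + e * e) * lam - 2.0 * e)
    return DragCoefficient(f, "parallel")


def spheroid_drag_perpendicular(shape: SpheroidShape, eta: float) -> DragCoefficient:
    """Drag for translation transverse to the spheroid's major axis."""
    e = _check_spheroid(shape, eta)
    c = shape.semi_major
    if e < _SERIES_ECCENTRICITY:
        # ((3e^2-1) Lambda + 2e) / e^3 = 16/3 + (8/5) e^2 + (32/35) e^4 + ...
        denom = 16.0 / 3.0 + 8.0 / 5.0 * e**2 + 32.0 / 35.0 * e**4
        f = 32.0 * math.pi * eta * c / denom
    else:
        lam = math.log((1.0 + e) / (1.0 - e))
        f = 32.0 * math.pi * eta * c * e**3 / ((3.0 * e * e - 1.0) * lam + 2.0 * e)
    return DragCoefficient(f, "perpendicular")


def rod_shape_factor(shape: RodShape, orientation: str) -> float:
    """Dimensionless slender-rod drag factor (multiplier on ``eta * L``).

    Tirado & Garcia de la Torre factors with end corrections:

        parallel:       2 pi / (ln p - 0.207 + 0.980/p - 0.133/p^2)
        perpendicular:  4 pi / (ln p + 0.839 + 0.185/p + 0.233/p^2)

    where ``p = L/d`` is the aspect ratio.  ``f = factor * eta * L``.
    """
    p = shape.aspect_ratio
    if p <= 1.0:
        raise ValueError(f"rod aspect ratio must exceed 1, got {p}")
    if orientation == "parallel":
        return 2.0 * math.pi / (math.log(p) - 0.207 + 0.980 / p - 0.133 / p**2)
    if orientation == "perpendicular":
        return 4.0 * math.pi / (math.log(p) + 0.839 + 0.185 / p + 0.233 / p**2)
    raise ValueError(f"orientation must be parallel or perpendicular, got {orientation!r}")


def equivalent_radius(f: DragCoefficient | float, eta: float) -> float:
    """Radius of the sphere with the same Stokes drag, ``a = f / (6 pi eta)``."""
    value = f.value if isinstance(f, DragCoefficient) else f
    if not value > 0:
        raise ValueError(f"drag must be positive, got {value}")
    if not eta > 0:
        raise ValueError(f"viscosity must be positive, got {eta}")
    return value / (6.0 * math.pi * eta)
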
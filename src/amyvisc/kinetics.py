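"""Mass-action kinetics of protofibril lateral association.

Species ``F_{i*1600}`` (i = 1..n_max) associate pairwise and reversibly,

    F_{i*1600} + F_{j*1600}  <=>  F_{(i+j)*1600},

with one forward/backward rate-constant pair shared by every reaction.
Only product species within the modelled set are allowed (no aggregates
beyond ``F_{n_max*1600}``), so the network is the pair set
``{(i, j) : i <= j, i + j <= n_max}``.

The net flux of reaction (i, j) is ``R(i,j) = k_plus [F_i][F_j] -
k_minus [F_{i+j}]``.  Homodimerisation ``2 F_i -> F_{2i}`` consumes two
particles of species i per event, giving the stoichiometric factor 2 that
makes the total monomer mass ``sum_i i*[F_i]`` an exact invariant of the
ODE system.

Concentrations are held in mM (matching the h^-1 mM^-1 units of the
forward rate constant) and time in hours; the pipeline layer converts from
uM and minutes.  Integration uses a stiff-capable BDF scheme with tight
tolerances so that mass conservation is meaningful to ~1e-9 relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "ReactionNetwork",
    "KineticState",
    "Trajectory",
    "build_reaction_network",
    "reaction_flux",
    "ode_rhs",
    "simulate_kinetics",
    "total_monomer_mass",
]


@dataclass(frozen=True)
class RateConstants:
    """Forward (h^-1 mM^-1) and backward (h^-1) rate constants."""

    k_plus: float = 0.9
    k_minus: float = 6.0e-3

    def __post_init__(self) -> None:
        if self.k_plus < 0 or self.k_minus < 0:
            raise ValueError("rate constants must be nonnegative")


@dataclass(frozen=True)
class ReactionNetwork:
    """Lateral-association reactions among n_max species."""

    n_max: int
    reactions: tuple[tuple[int, int], ...]

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in self.reactions


@dataclass(frozen=True)
class KineticState:
    """Concentrations [F_{i*1600}] (mM) for i = 1..n_max at one time (h)."""

    concentrations: tuple[float, ...]
    time: float = 0.0

    def __post_init__(self) -> None:
        if any(c < -1e-9 for c in self.concentrations):
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class Trajectory:
    """Simulated concentration time series.

    ``times`` in hours (strictly increasing), ``concentrations`` of shape
    (n_times, n_species) in mM.
    """

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.concentrations.shape[0] != self.times.shape[0]:
            raise ValueError("one concentration row per time point required")

    def state(self, idx: int) -> KineticState:
        return KineticState(tuple(self.concentrations[idx]), float(self.times[idx]))

    @property
    def n_species(self) -> int:
        return self.concentrations.shape[1]


def build_reaction_network(n_max: int) -> ReactionNetwork:
    """All association reactions whose product stays within the species set."""
    if n_max < 2:
        raise ValueError(f"need at least two species to react, got n_max={n_max}")
    reactions = tuple(
        (i, j)
        for i in range(1, n_max)
        for j in range(i, n_max + 1 - i)
    )
    return ReactionNetwork(n_max, reactions)


def reaction_flux(
    state: KineticState,
    rates: RateConstants,
    i: int,
    j: int,
    network: ReactionNetwork | None = None,
) -> float:
    """Net flux ``R(i,j) = k+ [F_i][F_j] - k- [F_{i+j}]`` in mM/h."""
    if network is not None and (i, j) not in network:
        raise ValueError(f"reaction ({i}, {j}) is not in the network")
    c = state.concentrations
    return rates.k_plus * c[i - 1] * c[j - 1] - rates.k_minus * c[i + j - 1]


def ode_rhs(
    concentrations: np.ndarray,
    network: ReactionNetwork,
    rates: RateConstants,
) -> np.ndarray:
    """Time derivative of the concentration vector (mM/h).

    Each reaction (i, j) consumes one particle of i and one of j (two of i
    when i == j) and produces one particle of i+j.
    """
    c = np.asarray(concentrations, dtype=float)
    dc = np.zeros_like(c)
    for i, j in network.reactions:
        flux = rates.k_plus * c[i - 1] * c[j - 1] - rates.k_minus * c[i + j - 1]
        dc[i - 1] -= flux
        dc[j - 1] -= flux  # adds a second unit when i == j
        dc[i + j - 1] += flux
    return dc


def total_monomer_mass(state: KineticState | np.ndarray) -> float:
    """Total monomer content ``sum_i i*[F_{i*1600}]`` in 1600-mer equivalents (mM)."""
    c = (
        np.asarray(state.concentrations)
        if isinstance(state, KineticState)
        else np.asarray(state)
    )
    return float(np.dot(np.arange(1, c.size + 1), c))


def simulate_kinetics(
    network: ReactionNetwork,
    rates: RateConstants,
    init: KineticState,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the association ODEs and return states at ``times`` (h).

    ``times`` must be strictly increasing; the integration starts at
    ``times[0]`` from ``init``.  Uses the stiff-capable BDF method.  Solver
    failure raises ``RuntimeError`` with the solver's diagnostic message.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    y0 = np.asarray(init.concentrations, dtype=float)
    if y0.size != network.n_max:
        raise ValueError(
            f"initial state has {y0.size} species, network expects {network.n_max}"
        )

    sol = solve_ivp(
        lambda _t, y: ode_rhs(y, network, rates),
        (times[0], times[-1]),
        y0,
        method="BDF",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"kinetics integration failed: {sol.message}")
    conc = sol.y.T.copy()
    # clip solver-scale negative round-off
    conc[(conc < 0) & (conc > -10 * atol)] = 0.0
    return Trajectory(times=sol.t.copy(), concentrations=conc)
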
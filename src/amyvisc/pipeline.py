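"""End-to-end case-study runner and CSV/DLS utilities.

``run_case`` integrates the lateral-association kinetics for a 2-, 3- or
5-species network, converts each state to a volume-fraction composition,
evaluates the effective viscosity and per-species diffusion bounds, and
returns one tidy table with a row per time point:

    time_min, conc_uM_1..n, eta_e_pa_s, k_lower_i, k_upper_i

Everything is deterministic given the configuration.  The DLS helpers
read/write the simple two-column time/diffusion-coefficient CSVs that
light-scattering instruments export, and can synthesise noisy traces from
model output for testing comparison code.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._constants import ROOM_TEMPERATURE, WATER_VISCOSITY
from .diffusion import (
    ThermoParams,
    concentrations_to_volume_fractions,
    effective_diffusion_bounds,
)
from .geometry import SpheroidShape, build_species_geometries
from .kinetics import (
    KineticState,
    RateConstants,
    build_reaction_network,
    simulate_kinetics,
    total_monomer_mass,
)
from .viscosity import QuemadaParams, mixture_effective_viscosity

__all__ = [
    "SimulationConfig",
    "run_case",
    "write_results",
    "read_results",
    "read_dls_trace",
    "generate_synthetic_dls",
]

logger = logging.getLogger("amyvisc")


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of one lateral-association case study.

    Defaults reproduce the published case-study conditions: 5 uM of
    1600-mer protofibrils (300 nm x 2.25 nm semi-axes), k+ = 0.9 h^-1
    mM^-1, k- = 6e-3 h^-1, water at room temperature, phi_m = 0.6, a
    91-point 0-90 min grid.
    """

    n_species: int = 5
    init_conc_uM: float = 5.0
    k_plus: float = 0.9
    k_minus: float = 6.0e-3
    semi_major_nm: float = 300.0
    semi_minor_nm: float = 2.25
    temperature_K: float = ROOM_TEMPERATURE
    eta0_pa_s: float = WATER_VISCOSITY
    phi_m: float = 0.6
    t_end_min: float = 90.0
    n_timepoints: int = 91
    volume_mode: str = "envelope"
    fraction_mode: str = "solute_normalized"
    rtol: float = 1e-8
    atol: float = 1e-12
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError(f"need at least 2 species, got {self.n_species}")
        for name in (
            "init_conc_uM",
            "semi_major_nm",
            "semi_minor_nm",
            "temperature_K",
            "eta0_pa_s",
            "phi_m",
            "t_end_min",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")

    @property
    def base_shape(self) -> SpheroidShape:
        return SpheroidShape(self.semi_major_nm * 1e-9, self.semi_minor_nm * 1e-9)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_case(config: SimulationConfig) -> pd.DataFrame:
    """Run one case study and return the per-time-point results table."""
    geometries = build_species_geometries(
        config.n_species, config.base_shape, config.volume_mode
    )
    network = build_reaction_network(config.n_species)
    rates = RateConstants(config.k_plus, config.k_minus)
    thermo = ThermoParams(config.temperature_K)
    visc = QuemadaParams(config.eta0_pa_s, config.phi_m)

    init_mM = [config.init_conc_uM * 1e-3] + [0.0] * (config.n_species - 1)
    times_h = np.linspace(0.0, config.t_end_min / 60.0, config.n_timepoints)
    traj = simulate_kinetics(
        network,
        rates,
        KineticState(tuple(init_mM)),
        times_h,
        rtol=config.rtol,
        atol=config.atol,
    )

    rows = []
    for idx in range(traj.times.size):
        state = traj.state(idx)
        comp = concentrations_to_volume_fractions(
            state, geometries, mode=config.fraction_mode
        )
        estimates = effective_diffusion_bounds(
            comp, geometries, thermo, visc, time=state.time
        )
        row: dict[str, float] = {"time_min": state.time * 60.0}
        for i, c in enumerate(state.concentrations, start=1):
            row[f"conc_uM_{i}"] = c * 1e3
        row["eta_e_pa_s"] = mixture_effective_viscosity(comp, visc)
        for est in estimates:
            row[f"k_lower_{est.species}"] = est.k_lower
            row[f"k_upper_{est.species}"] = est.k_upper
        rows.append(row)

    table = pd.DataFrame(rows)
    mass = np.array(
        [total_monomer_mass(traj.state(i)) for i in range(traj.times.size)]
    )
    logger.info(
        "run_case %s: n=%d, %d rows, mass drift %.3e rel, eta_e [%.6g, %.6g], "
        "k ranges [%.4g, %.4g]",
        config.config_hash(),
        config.n_species,
        len(table),
        float(np.max(np.abs(mass - mass[0])) / mass[0]),
        table["eta_e_pa_s"].min(),
        table["eta_e_pa_s"].max(),
        table.filter(like="k_lower").min().min(),
        table.filter(like="k_upper").max().max(),
    )
    return table


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as CSV, lossless at 12 significant digits."""
    table.to_csv(path, index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    return pd.read_csv(path)


def read_dls_trace(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column time / diffusion-coefficient CSV (with header).

    Returns ``(times, D)`` arrays.  Non-monotone times are sorted with a
    warning; an empty or malformed file raises ``ValueError`` naming the
    problem.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"DLS file {path} is empty") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"DLS file {path} is malformed: {exc}") from exc
    if frame.shape[0] == 0:
        raise ValueError(f"DLS file {path} contains a header but no data rows")
    if frame.shape[1] < 2:
        raise ValueError(
            f"DLS file {path} needs two columns (time, D), found {frame.shape[1]}"
        )
    times = pd.to_numeric(frame.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    values = pd.to_numeric(frame.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(times)) or np.any(np.isnan(values)):
        bad = int(np.argmax(np.isnan(times) | np.isnan(values))) + 2
        raise ValueError(f"DLS file {path}: non-numeric value near line {bad}")
    if np.any(np.diff(times) < 0):
        warnings.warn(
            f"DLS file {path} has non-monotone times; sorting", stacklevel=2
        )
        order = np.argsort(times, kind="stable")
        times, values = times[order], values[order]
    return times, values


def generate_synthetic_dls(
    table: pd.DataFrame,
    noise_cv: float,
    seed: int | None = None,
    species: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a noisy DLS-like diffusion trace from model output.

    Takes the lower-bound diffusion series of ``species`` and applies
    mean-preserving multiplicative lognormal noise with coefficient of
    variation ``noise_cv``.  Reproducible for a fixed seed; ``noise_cv=0``
    returns the exact model series.
    """
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be nonnegative, got {noise_cv}")
    column = f"k_lower_{species}"
    if column not in table.columns:
        raise ValueError(f"table has no column {column!r}")
    times = table["time_min"].to_numpy(dtype=float)
    model = table[column].to_numpy(dtype=float)
    if noise_cv == 0:
        return times, model.copy()
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=model.size)
    return times, model * noise
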
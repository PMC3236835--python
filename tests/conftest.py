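import math

import pytest
from hypothesis import HealthCheck, settings

import amyvisc as av

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: published protofibril envelope: semi-axes 300 nm x 2.25 nm
BASE_C = 300e-9
BASE_B = 2.25e-9


@pytest.fixture(scope="session")
def base_shape() -> av.SpheroidShape:
    return av.SpheroidShape(BASE_C, BASE_B)


@pytest.fixture(scope="session")
def thermo() -> av.ThermoParams:
    return av.ThermoParams()


@pytest.fixture(scope="session")
def quemada() -> av.QuemadaParams:
    return av.QuemadaParams()


@pytest.fixture(scope="session")
def case_tables() -> dict[int, "av.pd.DataFrame"]:
    """2-, 3- and 5-species case-study tables at the published conditions."""
    return {
        n: av.run_case(av.SimulationConfig(n_species=n)) for n in (2, 3, 5)
    }


def two_species_equilibrium_mM() -> tuple[float, float]:
    """Closed-form reversible-dimerisation equilibrium from 5 uM total.

    Solves k+ x^2 = k- y with x + 2y = 5e-3 mM, i.e. the positive root of
    300 x^2 + x - 5e-3 = 0 for k+/k- = 150 mM^-1.
    """
    x = (math.sqrt(7.0) - 1.0) / 600.0
    return x, 150.0 * x * x
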
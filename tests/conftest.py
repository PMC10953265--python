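import numpy as np
import pytest

from ccmediate.fitting import MediatorParams, OutcomeParams
from ccmediate.scenarios import get_scenario
from ccmediate.simulate import draw_case_control_sample, generate_population


@pytest.fixture(scope="session")
def cont_scenario():
    return get_scenario("cont_rare")


@pytest.fixture(scope="session")
def bin_scenario():
    return get_scenario("bin_rare")


@pytest.fixture(scope="session")
def cont_sample(cont_scenario):
    """Balanced case-control sample, continuous mediator, n = 600."""
    return draw_case_control_sample(cont_scenario, 600, seed=42).data


@pytest.fixture(scope="session")
def bin_sample(bin_scenario):
    """Balanced case-control sample, binary mediator, n = 600."""
    return draw_case_control_sample(bin_scenario, 600, seed=42).data


@pytest.fixture(scope="session")
def cont_population(cont_scenario):
    """Cohort-style draw from the rare continuous scenario."""
    return generate_population(cont_scenario, 60_000, seed=7)


def random_params(rng, mediator_type="continuous", p=1, scale=0.8):
    """Moderate random outcome/mediator parameter pairs for property tests."""
    theta = rng.normal(0.0, scale, size=4 + p)
    beta = rng.normal(0.0, scale, size=2 + p)
    sigma = float(rng.uniform(0.3, 1.5)) if mediator_type == "continuous" else None
    return (
        OutcomeParams.from_vector(theta),
        MediatorParams.from_vector(beta, sigma=sigma),
    )
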
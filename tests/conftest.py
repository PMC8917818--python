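import numpy as np
import pytest

from transdermal import (
    ModelParameters,
    NoiseModel,
    default_prior,
    generate_cohort,
    idealized_designs,
)


@pytest.fixture(scope="session")
def prior():
    return default_prior()


@pytest.fixture(scope="session")
def q_unit():
    return ModelParameters(1.0, 1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def noise25():
    return NoiseModel(0.025)


@pytest.fixture(scope="session")
def small_cohort(q_unit, noise25):
    """Three noisy episodes at q0 = (1, 1), one per drinking pattern."""
    return generate_cohort(
        3, q_unit, idealized_designs(0.025), noise25, n=8, seed=20240901
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
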
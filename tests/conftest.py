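import numpy as np
import pytest

from vadcea import VenousAccessCUA, default_parameters
from vadcea.cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def results():
    return VenousAccessCUA().fit(("6m", "12m", "full"))


@pytest.fixture(scope="session")
def small_cohort():
    """A modest confounded cohort shared by matching/estimation tests."""
    cfg = GeneratorConfig(
        n_per_arm={"CVC": 2500, "PICC": 900, "IVAP": 2200}, seed=11)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
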
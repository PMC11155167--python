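import numpy as np
import pytest

from fpdlm import generate_cohort, generate_dataset, make_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario1():
    return make_scenario(1)


@pytest.fixture(scope="session")
def sim_dataset_s1(scenario1):
    """One Scenario-1 dataset at moderate correlation, study size."""
    return generate_dataset(scenario1, 0.5, n=10000, seed=2024)


@pytest.fixture(scope="session")
def cohort_default():
    """Default synthetic three-wave cohort (injected window 30-36, OR 1.07)."""
    cohort, truth = generate_cohort(20000, seed=77)
    return cohort, truth
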
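import numpy as np
import pytest

import gradedcat as gc


@pytest.fixture(scope="session")
def fixture_bank():
    return gc.make_fixture_bank()


@pytest.fixture(scope="session")
def cohort(fixture_bank):
    """A seeded four-scale cohort at the emulated study size."""
    return gc.make_cohort(fixture_bank, n_persons=379, seed=20260927)


@pytest.fixture(scope="session")
def depression_bank(fixture_bank):
    return fixture_bank.subset("depression")


@pytest.fixture(scope="session")
def small_bank():
    """A moderate 8-item single-scale bank for fast unit tests."""
    return gc.generate_bank(8, seed=3)


@pytest.fixture(scope="session")
def small_rm(small_bank):
    thetas = np.random.default_rng(1).standard_normal(2000)
    return gc.simulate_responses(small_bank, thetas, seed=2)
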
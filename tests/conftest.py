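import numpy as np
import pytest

from oxemia import CohortConfig, generate_cohort, score_records


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default-sized synthetic cohort (888 infants)."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def scored(cohort):
    return score_records(cohort)


@pytest.fixture(scope="session")
def big_scored():
    """A cohort large enough to hold 750 records in every envelope bin."""
    return score_records(generate_cohort(CohortConfig(seed=5, n_infants=6500)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
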
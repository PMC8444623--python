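import numpy as np
import pytest

from memnet.parcellation import make_parcellation
from memnet.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_parcellation():
    return make_parcellation(30)


@pytest.fixture(scope="session")
def small_config():
    """Compact cohort: full planted structure at a fraction of the size."""
    return CohortConfig(
        n_per_group=8,
        n_nodes=30,
        phase_lengths={"encoding": 60, "maintenance": 40, "retrieval": 80},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    subjects, truth = generate_cohort(small_config)
    return subjects, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
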
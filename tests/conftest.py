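import numpy as np
import pytest

from dermrl.core import CLASS_ORDER, RewardTable, ManagementAction
from dermrl.defaults import default_reward_table
from dermrl.synth import (CohortConfig, GeneratorConfig, ISIC_TEST_COUNTS,
                          make_isic_fixture, sample_cohort, sample_states)

ISIC_PRIORS = tuple(np.array([ISIC_TEST_COUNTS[d] for d in CLASS_ORDER], float)
                    / sum(ISIC_TEST_COUNTS.values()))


@pytest.fixture(scope="session")
def train_records():
    """Calibrated training pool drawn with the test-composition priors."""
    return sample_states(GeneratorConfig(class_priors=ISIC_PRIORS, seed=11), 6000)


@pytest.fixture(scope="session")
def held_out_records():
    return sample_states(GeneratorConfig(class_priors=ISIC_PRIORS, seed=99), 2000)


@pytest.fixture(scope="session")
def isic_fixture():
    return make_isic_fixture(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    return sample_cohort(CohortConfig(composition="stochastic", n_patients=20,
                                      melanoma_rate=0.05, seed=7))


@pytest.fixture(scope="session")
def identity_rewards():
    return RewardTable(CLASS_ORDER, np.eye(7), provenance="0/1 identity")


@pytest.fixture(scope="session")
def asymmetric_rewards():
    return default_reward_table("diagnosisRL")


@pytest.fixture(scope="session")
def binary_rewards():
    return default_reward_table("binary")
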
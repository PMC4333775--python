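import numpy as np
import pytest

from rsbn.bn_learning import BNLearnConfig, subject_feature_table
from rsbn.synthetic_data import load_ground_truth, simulate_cohort


@pytest.fixture(scope="session")
def dag_ec():
    return load_ground_truth("EC")


@pytest.fixture(scope="session")
def dag_eo():
    return load_ground_truth("EO")


@pytest.fixture(scope="session")
def default_cohort(dag_ec, dag_eo):
    """The default study conditions: 20 subjects x 2 conditions, 230
    timepoints, weight jitter 0.1, unit noise."""
    return simulate_cohort(
        dag_ec, dag_eo, n_subjects=20, n_timepoints=230, jitter_sd=0.1, master_seed=0
    )


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """Per-recording directed-edge features of the default cohort (40 x 81).

    Session-scoped: learning 40 per-recording networks is the expensive step
    shared by the classification tests.
    """
    return subject_feature_table(default_cohort, BNLearnConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
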
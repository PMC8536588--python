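import numpy as np
import pytest

from hajmsm import fixture_histories, illness_death_recovery
from hajmsm.simulator import experiment_design, simulate_histories


@pytest.fixture(scope="session")
def space():
    return illness_death_recovery()


@pytest.fixture()
def fx():
    """Hand-checkable 3-subject dataset (4 transitions, one censoring)."""
    return fixture_histories()


@pytest.fixture(scope="session")
def markov_hist():
    """Markov (no-frailty) simulated dataset, n=300."""
    return simulate_histories(experiment_design(1, n=300, sigma2=0.0, seed=11))


@pytest.fixture(scope="session")
def frail_hist():
    """Non-Markov dataset with a gamma frailty (variance 1.2) on 2->1, n=300."""
    return simulate_histories(experiment_design(1, n=300, sigma2=1.2, seed=5))


@pytest.fixture(scope="session")
def big_markov_hist():
    """Large Markov dataset shared by the slow calibration checks."""
    return simulate_histories(experiment_design(1, n=20000, sigma2=0.0, seed=42))


def rate_generator_matrix():
    """Generator of the baseline Markov chain on the illness-death model."""
    from hajmsm.simulator import BASE_RATES, TRANSITION_ORDER

    Q = np.zeros((3, 3))
    for (j, k), a in zip(TRANSITION_ORDER, BASE_RATES):
        Q[j - 1, k - 1] = a
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q
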
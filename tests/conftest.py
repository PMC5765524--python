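import numpy as np
import pytest

import lifemix as lm

#: Fixed seed for every stochastic test; chosen once, up front.
SIM_SEED = 20250921
SIM_N = 100_000


@pytest.fixture(scope="session")
def fulmar() -> lm.MixtureModel:
    """The packaged three-group southern-fulmar mixture model."""
    return lm.southern_fulmar()


@pytest.fixture(scope="session")
def big_sim(fulmar):
    """One large simulated mixed cohort, shared across the oracle tests."""
    return lm.simulate_cohort(fulmar, SIM_N, SIM_SEED)


@pytest.fixture(scope="session")
def big_summaries(big_sim):
    return lm.empirical_summaries(big_sim)


def geometric_chain(p: float):
    """1-state chain with self-transition p: occupancy is geometric, mean 1/(1-p)."""
    U = np.array([[p]])
    return U
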
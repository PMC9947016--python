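import numpy as np
import pytest

import cardiotd as ct


@pytest.fixture(scope="session")
def td():
    """Reference cellular TD parameter set."""
    return ct.DEFAULT_TD


@pytest.fixture(scope="session")
def deg():
    return ct.DEFAULT_DEGRADATION


@pytest.fixture(scope="session")
def default_times():
    return np.array([0.0, 12.0, 24.0, 48.0, 72.0])


@pytest.fixture(scope="session")
def recovery_results():
    """The 50-replicate simulate-and-refit experiment (shared: it is the
    costliest computation in the suite and several checks read from it)."""
    return ct.td_recovery_experiment(n_replicates=50, cv=0.075, base_seed=1)
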
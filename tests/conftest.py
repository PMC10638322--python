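import numpy as np
import pytest

from numercode.dynamics import NetworkParams, SimulationConfig
from numercode.encoding import build_codebook, run_sweep

#: Seed for the shared full sweep; any small integer works, the suite
#: checks properties that hold across seeds.
SWEEP_SEED = 1


@pytest.fixture(scope="session")
def full_sweep():
    """The standard sweep: set sizes 1-50 x 15 strengths, 30-run ensembles.

    Computed once per session (a few minutes); all steady-state structure
    tests share it.
    """
    return run_sweep(config=SimulationConfig(seed=SWEEP_SEED, n_runs=30))


@pytest.fixture(scope="session")
def full_codebook(full_sweep):
    return build_codebook(full_sweep)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
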
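import numpy as np
import pytest

import p53abc as pa


@pytest.fixture(scope="session")
def gamma_fixture():
    """Default gamma-emulated cell-line samples (reported fits, n=122/400)."""
    return pa.generate_gamma_fixture(pa.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def small_sim_config():
    return pa.SimulationConfig(dt=0.01, t_end=30.0, mrna_init=0,
                               protein_init=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
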
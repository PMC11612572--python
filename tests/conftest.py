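import numpy as np
import pytest

from defensym import GridSpec, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """A light parameter set for fast end-to-end runs."""
    return SimulationParams(
        n_hosts=40,
        n_parasitoids=4,
        grid=GridSpec(120, 120),
        s_un=30.0,
        lambda_un=20.0,
        s_p=20.0,
        lambda_p=30.0,
        n_generations=10,
    )
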
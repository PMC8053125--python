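import logging

import numpy as np
import pytest

import aptakinetics as ak

# fit internals log expected warnings (plateau drift, bound hits) on noisy
# synthetic data; keep the test output readable
logging.getLogger("aptakinetics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def time_grid():
    return np.linspace(0.0, 1.0, 201)


@pytest.fixture(scope="session")
def a_model4():
    """Scheme and rates of the two-step reversible preset for aptamer A."""
    return ak.get_rate_preset("A-model4")


@pytest.fixture(scope="session")
def noiseless_model1_series():
    return ak.gen_stopped_flow_preset(
        "A-model1", noise=ak.NoiseSpec(kind="gaussian", sigma=0.0, seed=0)
    )
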
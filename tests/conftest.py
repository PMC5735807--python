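import numpy as np
import pytest

from tsp1apop import assemble_network, toy_models


@pytest.fixture(scope="session")
def model():
    """The bundled 53-species signaling model (shared across tests)."""
    return assemble_network()


@pytest.fixture(scope="session")
def toys():
    return toy_models()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
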
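import numpy as np
import pytest

from stoichbal import fixtures
from stoichbal.network import InterfaceNetwork


@pytest.fixture
def chain_net():
    return fixtures.chain_network()


@pytest.fixture
def mixed_net():
    return fixtures.mixed_network()


@pytest.fixture
def triangle_net():
    return InterfaceNetwork(
        ["A", "B", "C"],
        [("A", "i1"), ("B", "i1"), ("C", "i1")],
        [
            (("A", "i1"), ("B", "i1")),
            (("B", "i1"), ("C", "i1")),
            (("A", "i1"), ("C", "i1")),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
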
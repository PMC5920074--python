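import numpy as np
import pytest

from sirpaths.netio import ContactNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def path3():
    """a - b - c chain."""
    return ContactNetwork.from_edge_ids([("a", "b"), ("b", "c")], name="path3")


@pytest.fixture
def star5():
    """Hub c with five leaves."""
    return ContactNetwork.from_edge_ids(
        [("c", f"l{k}") for k in range(5)], name="star5")


@pytest.fixture
def single_edge():
    return ContactNetwork.from_edge_ids([("a", "b")], name="edge")
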
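import networkx as nx
import numpy as np
import pytest

from herdsim import from_networkx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path5():
    """5-node path graph 0-1-2-3-4."""
    return from_networkx(nx.path_graph(5))


@pytest.fixture
def star4():
    """Star with hub 0 and 4 leaves (hub degree 4)."""
    return from_networkx(nx.star_graph(4))
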
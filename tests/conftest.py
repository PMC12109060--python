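import numpy as np
import pytest

from teashuttle import simulate


@pytest.fixture
def small_cfg():
    return simulate.small_test_config(seed=1)


@pytest.fixture
def expression_pair(small_cfg):
    return simulate.generate_expression(small_cfg)


@pytest.fixture
def compound_pair(small_cfg):
    return simulate.generate_compound_library(small_cfg)


@pytest.fixture
def ppi_pair(small_cfg):
    return simulate.generate_ppi(small_cfg)


def random_graph(rng: np.random.Generator, max_nodes: int = 8):
    """Small Erdos-Renyi graph for oracle comparisons."""
    import networkx as nx

    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.2, 0.9))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
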
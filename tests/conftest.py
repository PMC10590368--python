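import networkx as nx
import numpy as np
import pandas as pd
import pytest

from zoonet import CommunityMatrix, SignedInteractionNetwork


def make_network(edges, nodes=None, n_samples=84, alpha=0.05):
    """Signed network from an (u, v, r) edge list for metric tests."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for u, v, r in edges:
        g.add_edge(u, v, r=r)
    return SignedInteractionNetwork.from_graph(g, n_samples=n_samples, alpha=alpha)


def random_connected_graph(rng, n_min=4, n_max=7):
    """Random connected graph with 4–7 nodes (rejection sampling)."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labelled_community(rng):
    """Small two-class community with correlated and independent taxa."""
    n = 40
    rows, labels = [], {}
    factor = rng.standard_normal(2 * n)
    noise = rng.standard_normal((2 * n, 6))
    log_b = np.column_stack(
        [factor + 0.5 * noise[:, 0], factor + 0.5 * noise[:, 1], -factor + 0.5 * noise[:, 2],
         noise[:, 3], noise[:, 4], noise[:, 5]]
    )
    biomass = np.exp(log_b)
    samples = [f"s{i:03d}" for i in range(2 * n)]
    taxa = [f"t{j}" for j in range(6)]
    for i, s in enumerate(samples):
        labels[s] = "A" if i < n else "B"
    return CommunityMatrix(
        pd.DataFrame(biomass, index=samples, columns=taxa),
        class_label=pd.Series(labels),
    )
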
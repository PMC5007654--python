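import numpy as np
import pytest

from geronet.netio import GeneNetwork, GeneSet, normalize_adjacency


@pytest.fixture
def path_net():
    """3-node path a - b - c."""
    return normalize_adjacency(GeneNetwork.from_edges([("a", "b"), ("b", "c")]))


@pytest.fixture
def two_node_net():
    return normalize_adjacency(GeneNetwork.from_edges([("a", "b")]))


@pytest.fixture
def k4_net():
    nodes = ["a", "b", "c", "d"]
    edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
    return normalize_adjacency(GeneNetwork.from_edges(edges))


def random_network(rng: np.random.Generator, n: int, p: float = 0.05) -> GeneNetwork:
    """Erdos-Renyi network with zero-padded gene names; may contain
    isolated nodes."""
    names = [f"g{i:06d}" for i in range(n)]
    mask = rng.random((n, n)) < p
    edges = [
        (names[i], names[j]) for i in range(n) for j in range(i + 1, n) if mask[i, j]
    ]
    return normalize_adjacency(GeneNetwork.from_edges(edges, extra_nodes=names))


def sample_genes(rng: np.random.Generator, net: GeneNetwork, k: int) -> GeneSet:
    idx = rng.choice(net.n, size=k, replace=False)
    return GeneSet("sampled", {net.nodes[i] for i in idx})
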
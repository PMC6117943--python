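import pytest

from dinet.fixtures import worked_toy
from dinet.model import EdgeRecord, KnowledgeNetwork, NodeRecord


@pytest.fixture
def toy():
    """Fixed 12-node two-cluster network with three hand-written conditions."""
    return worked_toy()


@pytest.fixture
def toy_net(toy):
    return toy[0]


@pytest.fixture
def toy_series(toy):
    return toy[1]


def make_network(edge_list, extra_nodes=(), directed=True, interaction="unknown"):
    """Small helper: build a network from (source, target) pairs."""
    ids = {u for u, v in edge_list} | {v for u, v in edge_list} | set(extra_nodes)
    return KnowledgeNetwork.from_records(
        [NodeRecord(i) for i in sorted(ids)],
        [EdgeRecord(u, v, interaction, directed) for u, v in edge_list],
    )


def star_network(n):
    """Undirected star with n nodes: hub 'h' plus n-1 leaves."""
    return make_network(
        [("h", f"l{i:02d}") for i in range(1, n)], directed=False
    )


def complete_network(n, directed):
    ids = [f"v{i:02d}" for i in range(n)]
    if directed:
        edges = [(a, b) for a in ids for b in ids if a != b]
    else:
        edges = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]
    return make_network(edges, directed=directed)
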
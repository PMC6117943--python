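"""Community detection, cluster classification, gating and layout."""

import itertools

import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from dinet.clustering import (
    ClusteringParams,
    ClusterStats,
    classify_cluster,
    clusterize,
    find_hubs,
    layout_cluster,
    partition_multilevel,
    subdivide_spinglass,
    subdivision_gate,
)
from dinet.fixtures import ClusterSpec, FixtureSpec, generate_background
from dinet.model import EdgeRecord, KnowledgeNetwork, NodeRecord, ValidationError

from conftest import complete_network, make_network, star_network


def brute_force_betweenness(g: nx.Graph, v) -> float:
    """Independent betweenness oracle: enumerate all shortest paths by
    exhaustive simple-path search on small graphs."""
    total = 0.0
    nodes = sorted(g.nodes)
    for s, t in itertools.combinations(nodes, 2):
        if s == v or t == v or not nx.has_path(g, s, t):
            continue
        d = nx.shortest_path_length(g, s, t)
        paths = [
            p for p in nx.all_simple_paths(g, s, t, cutoff=d) if len(p) - 1 == d
        ]
        through = sum(1 for p in paths if v in p[1:-1])
        total += through / len(paths)
    return total


def two_cliques_bridged(size=10):
    nodes, edges = [], []
    for c in range(2):
        ids = [f"q{c}n{i:02d}" for i in range(size)]
        nodes += [NodeRecord(i) for i in ids]
        edges += [
            EdgeRecord(ids[a], ids[b], "binding", False)
            for a in range(size) for b in range(a + 1, size)
        ]
    edges.append(EdgeRecord("q0n00", "q1n00", "activation", True))
    return KnowledgeNetwork.from_records(nodes, edges)


# ---------------------------------------------------------------------------
# multi-level partition
# ---------------------------------------------------------------------------

def test_partition_two_cliques():
    net = two_cliques_bridged(10)
    part = partition_multilevel(net, seed=1)
    clusters = part.clusters()
    assert len(clusters) == 2
    sizes = sorted(len(m) for m in clusters.values())
    assert sizes == [10, 10]
    # each cluster is exactly one clique
    for members in clusters.values():
        prefixes = {nid[:2] for nid in members}
        assert len(prefixes) == 1


def test_partition_drops_small_communities():
    nodes, edges = [], []
    for t in range(20):
        ids = [f"t{t:02d}n{i}" for i in range(3)]
        nodes += [NodeRecord(i) for i in ids]
        edges += [EdgeRecord(a, b, "binding", False)
                  for a, b in itertools.combinations(ids, 2)]
    net = KnowledgeNetwork.from_records(nodes, edges)
    part = partition_multilevel(net, seed=0, min_cluster_size=5)
    assert part.assignment == {}
    assert len(part.dropped) == 60


def test_partition_single_clique_kept():
    net = complete_network(6, directed=False)
    part = partition_multilevel(net, seed=0)
    assert len(part.clusters()) == 1
    assert not part.dropped


def test_partition_empty_network_is_an_error():
    with pytest.raises(ValidationError):
        partition_multilevel(KnowledgeNetwork(), seed=0)


# ---------------------------------------------------------------------------
# hubs and classification
# ---------------------------------------------------------------------------

def test_find_hubs_threshold_scan():
    # construct degrees {10, 6, 5, 1}: hub H(10), X(6), Y(5), leaves
    edges = [("H", f"L{i}") for i in range(10)]
    edges += [("X", f"L{i}") for i in range(6)]
    edges += [("Y", f"L{i}") for i in range(4)] + [("Y", "X")]
    g = make_network(edges, directed=False).undirected_simple_graph()
    degrees = dict(g.degree())
    assert (degrees["H"], degrees["X"], degrees["Y"]) == (10, 7, 5)
    hubs = find_hubs(g, 0.6)
    # oracle: threshold scan
    expected = {n for n, d in degrees.items() if d >= 0.6 * 10}
    assert hubs == expected
    assert "H" in hubs and "X" in hubs and "Y" not in hubs


def test_find_hubs_all_equal_degrees():
    g = complete_network(5, directed=False).undirected_simple_graph()
    assert find_hubs(g, 0.6) == set(g.nodes)


def test_find_hubs_never_empty():
    g = nx.Graph()
    g.add_nodes_from(["a", "b"])  # no edges at all
    assert find_hubs(g, 0.6) == {"a", "b"}


def test_classify_directed_complete_graph_dense():
    net = complete_network(4, directed=True)
    stats = classify_cluster(net)
    assert stats.n_arcs == 12 == 4 * 3
    assert stats.classification == "densely_connected"


def test_classify_undirected_clique_dense_doubled_count():
    net = complete_network(6, directed=False)
    stats = classify_cluster(net)
    assert stats.n_arcs == 30 == 6 * 5
    assert stats.classification == "densely_connected"


def test_classify_star_with_betweenness_oracle():
    net = star_network(9)
    g = net.undirected_simple_graph()
    stats = classify_cluster(net)
    assert stats.classification == "star_like"
    assert stats.hub_ids == {"h"}
    expected = (9 - 1) * (9 - 2) / 2
    assert expected == 28
    assert brute_force_betweenness(g, "h") == pytest.approx(expected)


def test_classify_cycle_not_star():
    ids = [f"c{i}" for i in range(6)]
    net = make_network(
        [(ids[i], ids[(i + 1) % 6]) for i in range(6)], directed=False
    )
    stats = classify_cluster(net)
    # every node has degree 2, so all six are hubs, not exactly one
    assert len(stats.hub_ids) == 6
    assert stats.classification != "star_like"


def test_dense_classification_breaks_beyond_tolerance():
    # remove edges from K8 until the arc count falls below 90% of n(n-1)
    n = 8
    full = complete_network(n, directed=True)
    removable = int(n * (n - 1) * 0.10) + 1
    pruned = full.copy()
    pruned.edges = pruned.edges[:-removable]
    assert classify_cluster(full).classification == "densely_connected"
    assert classify_cluster(pruned).classification != "densely_connected"


# ---------------------------------------------------------------------------
# subdivision gate
# ---------------------------------------------------------------------------

def _stats(n_nodes, n_edges, classification="regular"):
    return ClusterStats(1, n_nodes, n_edges, n_edges, 1, {"x"}, classification)


@pytest.mark.parametrize(
    "n_nodes,n_edges,eligible",
    [
        (1024, 100, True),    # node clause fails the "less than" test
        (1023, 2047, False),  # both strictly below
        (1023, 2048, True),   # edge clause fails
        (2000, 5000, True),
    ],
)
def test_subdivision_gate_boundaries(n_nodes, n_edges, eligible):
    assert subdivision_gate(_stats(n_nodes, n_edges)) is eligible


@pytest.mark.parametrize("cls", ["star_like", "densely_connected", "small"])
def test_non_regular_clusters_never_subdivided(cls):
    assert subdivision_gate(_stats(5000, 9000, cls)) is False


def test_gate_monotone_under_growth():
    stats = _stats(1024, 2048)
    assert subdivision_gate(stats)
    for dn, dm in itertools.product([0, 1, 500], repeat=2):
        assert subdivision_gate(_stats(1024 + dn, 2048 + dm))


# ---------------------------------------------------------------------------
# spinglass subdivision
# ---------------------------------------------------------------------------

def test_spinglass_recovers_bridged_cliques():
    net = two_cliques_bridged(20)
    labels = subdivide_spinglass(net, k=2, seed=11, parent_label="7")
    groups = {}
    for nid, lab in labels.items():
        groups.setdefault(lab, set()).add(nid)
    assert set(groups) == {"7.1", "7.2"}
    for members in groups.values():
        assert len({nid[:2] for nid in members}) == 1


def test_spinglass_k1_is_identity(toy_net):
    labels = subdivide_spinglass(toy_net, k=1, parent_label="3")
    assert set(labels.values()) == {"3.1"}
    assert set(labels) == set(toy_net.nodes)


def test_spinglass_deterministic_under_seed():
    net = two_cliques_bridged(15)
    a = subdivide_spinglass(net, k=2, seed=5)
    b = subdivide_spinglass(net, k=2, seed=5)
    assert a == b


def test_spinglass_disconnected_falls_back_per_component():
    nodes = [NodeRecord(f"a{i}") for i in range(6)] + \
        [NodeRecord(f"b{i}") for i in range(6)]
    edges = [EdgeRecord(f"a{i}", f"a{j}", "binding", False)
             for i, j in itertools.combinations(range(6), 2)]
    edges += [EdgeRecord(f"b{i}", f"b{j}", "binding", False)
              for i, j in itertools.combinations(range(6), 2)]
    net = KnowledgeNetwork.from_records(nodes, edges)
    labels = subdivide_spinglass(net, k=2, seed=0, parent_label="9")
    groups = {}
    for nid, lab in labels.items():
        groups.setdefault(lab, set()).add(nid)
    assert len(groups) == 2
    for members in groups.values():
        assert len({nid[0] for nid in members}) == 1


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def test_layout_switch_boundary():
    # 64 nodes arranged in a 64-edge cycle: Fruchterman-Reingold
    ids = [f"n{i:02d}" for i in range(64)]
    ring = make_network([(ids[i], ids[(i + 1) % 64]) for i in range(64)],
                        directed=False)
    _, algo = layout_cluster(ring)
    assert algo == "fruchterman_reingold"
    # 65 nodes: Kamada-Kawai regardless of edge count
    ids = [f"n{i:02d}" for i in range(65)]
    path = make_network([(ids[i], ids[i + 1]) for i in range(64)],
                        directed=False)
    _, algo = layout_cluster(path)
    assert algo == "kamada_kawai"


def test_layout_cluster_deterministic():
    net = two_cliques_bridged(8)
    a, _ = layout_cluster(net, seed=4)
    b, _ = layout_cluster(net, seed=4)
    assert a == b


# ---------------------------------------------------------------------------
# end-to-end clusterize
# ---------------------------------------------------------------------------

def test_clusterize_recovers_planted_communities():
    spec = FixtureSpec(
        clusters=[ClusterSpec("random", 30, 0.30),
                  ClusterSpec("random", 40, 0.30),
                  ClusterSpec("random", 50, 0.30)],
        n_bridges=4, seed=2,
    )
    net, truth = generate_background(spec)
    result = clusterize(net, ClusteringParams(seed=2))
    ids = sorted(result.network.nodes)
    pred = [result.network.nodes[n].cluster_id for n in ids]
    true = [truth.cluster_labels[n] for n in ids]
    assert adjusted_rand_score(true, pred) == 1.0
    for rec in result.network.nodes.values():
        assert rec.cluster_id is not None
        assert rec.degree is not None
        assert rec.has_coordinates()


def test_clusterize_drops_planted_small_community():
    spec = FixtureSpec(
        clusters=[ClusterSpec("random", 30, 0.4), ClusterSpec("clique", 4)],
        n_bridges=1, seed=3,
    )
    net, truth = generate_background(spec)
    result = clusterize(net, ClusteringParams(seed=3))
    small = {n for n, c in truth.cluster_labels.items() if c == 2}
    assert small <= result.dropped


def test_clusterize_preserves_bridge_edges():
    spec = FixtureSpec(
        clusters=[ClusterSpec("random", 20, 0.4), ClusterSpec("random", 20, 0.4)],
        n_bridges=3, seed=4,
    )
    net, _ = generate_background(spec)
    result = clusterize(net, ClusteringParams(seed=4))
    cid = {nid: rec.cluster_id for nid, rec in result.network.nodes.items()}
    cross = [
        e for e in result.network.edges if cid[e.source_id] != cid[e.target_id]
    ]
    assert len(cross) >= 1


def test_clusterize_deterministic_tables(tmp_path):
    from dinet.network_io import write_cluster_tables

    spec = FixtureSpec(
        clusters=[ClusterSpec("random", 25, 0.3), ClusterSpec("star", 9)],
        n_bridges=2, seed=6,
    )
    net, _ = generate_background(spec)
    outputs = []
    for run in range(2):
        result = clusterize(net, ClusteringParams(seed=6))
        d = tmp_path / f"run{run}"
        write_cluster_tables(result.network, str(d))
        outputs.append((d / "nodes.tsv").read_bytes() +
                       (d / "edges.tsv").read_bytes())
    assert outputs[0] == outputs[1]
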
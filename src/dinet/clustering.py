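"""Knowledge-network clustering pipeline.

The pipeline splits a large background network into visualisable clusters:

1. multi-level modularity optimisation (Louvain) on the undirected simple
   view, dropping communities with fewer than five nodes;
2. structural classification of each community — *densely connected*
   (approximately complete: directed arc count near n(n−1)), *star-like*
   (a single hub whose betweenness is near (n−1)(n−2)/2 and whose closeness
   is maximal, with edge count near node count), *small* (below the
   sub-division size gate) or *regular*;
3. regular clusters at or above the gate (2^10 nodes / 2^11 edges) are
   subdivided by the spinglass algorithm into as many sub-clusters as the
   cluster has hub nodes;
4. each final cluster receives a deterministic layout — grid initialisation
   refined by Fruchterman–Reingold for small clusters (≤ 2^6 nodes and
   ≤ 2^6 edges) or Kamada–Kawai otherwise.

Community detection runs through python-igraph, whose random draws come
from Python's ``random`` module, so a single seed makes the whole pipeline
reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import igraph as ig
import networkx as nx

from .model import KnowledgeNetwork, ValidationError
from .preprocess import compute_degrees, grid_positions, simplify


@dataclass
class ClusteringParams:
    """Tunable thresholds of the clustering pipeline.

    The structural rules come with tolerances because "approximately
    fully connected" and "edge count close to the number of nodes" need a
    numeric reading: a cluster is densely connected when its directed arc
    count reaches ``1 - dense_tolerance`` of n(n−1) (undirected edges count
    twice), and star-like edge/betweenness checks allow the stated relative
    slack.
    """

    min_cluster_size: int = 5
    dense_tolerance: float = 0.10
    hub_fraction: float = 0.60
    star_edge_tolerance: float = 0.10   # |m - n| <= max(2, tol * n)
    star_betweenness_tolerance: float = 0.10
    subdivide_min_nodes: int = 2 ** 10
    subdivide_min_edges: int = 2 ** 11
    gate_logic: str = "and"             # "and" (both below => excluded) or "or"
    layout_switch: int = 2 ** 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hub_fraction <= 1.0):
            raise ValueError("hub_fraction must lie in (0, 1]")
        for name in ("min_cluster_size", "subdivide_min_nodes",
                     "subdivide_min_edges", "layout_switch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gate_logic not in ("and", "or"):
            raise ValueError("gate_logic must be 'and' or 'or'")


@dataclass
class Partition:
    """Disjoint community assignment over retained nodes."""

    assignment: Dict[str, int]
    dropped: Set[str] = field(default_factory=set)

    def clusters(self) -> Dict[int, List[str]]:
        out: Dict[int, List[str]] = {}
        for nid, cid in self.assignment.items():
            out.setdefault(cid, []).append(nid)
        for members in out.values():
            members.sort()
        return out


@dataclass
class ClusterStats:
    cluster_id: int
    n_nodes: int
    n_edges: int          # retained edge records, loops excluded
    n_arcs: int           # directed count: undirected edges count twice
    max_degree: int
    hub_ids: Set[str]
    classification: str   # densely_connected | star_like | small | regular


# ---------------------------------------------------------------------------
# igraph bridge
# ---------------------------------------------------------------------------

def _to_igraph(g: nx.Graph) -> Tuple[ig.Graph, List[str]]:
    ids = sorted(g.nodes)
    index = {nid: i for i, nid in enumerate(ids)}
    edges = [(index[u], index[v]) for u, v in sorted(g.edges)]
    return ig.Graph(n=len(ids), edges=edges, directed=False), ids


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def partition_multilevel(
    net: KnowledgeNetwork,
    seed: int = 0,
    min_cluster_size: int = 5,
) -> Partition:
    """Louvain multi-level modularity partition of the undirected simple view.

    Communities smaller than ``min_cluster_size`` are moved to ``dropped``.
    Cluster ids are positive integers ordered by decreasing size (ties by
    smallest member id) so the numbering is stable under a fixed seed.
    """
    if net.n_nodes == 0:
        raise ValidationError("cannot partition an empty network")
    g = net.undirected_simple_graph()
    graph, ids = _to_igraph(g)
    random.seed(seed)
    clusters = graph.community_multilevel()
    groups = [sorted(ids[i] for i in comm) for comm in clusters]
    groups.sort(key=lambda ms: (-len(ms), ms[0]))
    assignment: Dict[str, int] = {}
    dropped: Set[str] = set()
    next_id = 1
    for members in groups:
        if len(members) < min_cluster_size:
            dropped.update(members)
            continue
        for nid in members:
            assignment[nid] = next_id
        next_id += 1
    return Partition(assignment, dropped)


def find_hubs(subgraph: nx.Graph, hub_fraction: float = 0.60) -> Set[str]:
    """Nodes with degree at or above ``hub_fraction`` of the maximal degree
    (undirected simple view).  Never empty for a non-empty graph: the
    maximum-degree node always qualifies."""
    if subgraph.number_of_nodes() == 0:
        raise ValidationError("find_hubs needs a non-empty subgraph")
    degrees = dict(subgraph.degree())
    max_deg = max(degrees.values())
    return {nid for nid, d in degrees.items() if d >= hub_fraction * max_deg}


def _arc_count(sub: KnowledgeNetwork) -> int:
    return sum(
        (1 if e.directed else 2) for e in sub.edges if not e.is_self_loop()
    )


def classify_cluster(
    sub: KnowledgeNetwork,
    params: Optional[ClusteringParams] = None,
    cluster_id: int = 0,
) -> ClusterStats:
    """Structural classification of one cluster subnetwork.

    Precedence: densely_connected, then star_like, then small (below the
    sub-division gate), then regular.  All centrality checks run on the
    undirected simple view of the cluster.
    """
    params = params or ClusteringParams()
    if sub.n_nodes == 0:
        raise ValidationError("cannot classify an empty cluster")
    g = sub.undirected_simple_graph()
    n = g.number_of_nodes()
    m_simple = g.number_of_edges()
    n_arcs = _arc_count(sub)
    n_edges = sum(1 for e in sub.edges if not e.is_self_loop())
    degrees = dict(g.degree())
    max_degree = max(degrees.values())
    hubs = find_hubs(g, params.hub_fraction)

    dense = n >= 2 and n_arcs >= (1.0 - params.dense_tolerance) * n * (n - 1)

    star = False
    if not dense and n >= 3 and len(hubs) == 1:
        hub = next(iter(hubs))
        if abs(m_simple - n) <= max(2.0, params.star_edge_tolerance * n):
            closeness = nx.closeness_centrality(g)
            if closeness[hub] >= max(closeness.values()) - 1e-12:
                target = (n - 1) * (n - 2) / 2.0
                bet = nx.betweenness_centrality(g, normalized=False)[hub]
                star = abs(bet - target) <= params.star_betweenness_tolerance * target

    if dense:
        classification = "densely_connected"
    elif star:
        classification = "star_like"
    elif (n < params.subdivide_min_nodes
          and n_edges < params.subdivide_min_edges):
        classification = "small"
    else:
        classification = "regular"

    return ClusterStats(
        cluster_id=cluster_id,
        n_nodes=n,
        n_edges=n_edges,
        n_arcs=n_arcs,
        max_degree=max_degree,
        hub_ids=hubs,
        classification=classification,
    )


def subdivision_gate(stats: ClusterStats, params: Optional[ClusteringParams] = None) -> bool:
    """True when a cluster proceeds to spinglass sub-division.

    Densely connected, star-like and small clusters are excluded.  A
    cluster is *small* when it sits below the node AND edge thresholds
    (``gate_logic="or"`` switches to either-below)."""
    params = params or ClusteringParams()
    if stats.classification != "regular":
        return False
    below_nodes = stats.n_nodes < params.subdivide_min_nodes
    below_edges = stats.n_edges < params.subdivide_min_edges
    below = (below_nodes and below_edges) if params.gate_logic == "and" \
        else (below_nodes or below_edges)
    return not below


def subdivide_spinglass(
    sub: KnowledgeNetwork,
    k: int,
    seed: int = 0,
    parent_label: str = "1",
) -> Dict[str, str]:
    """Spinglass sub-division into at most ``k`` sub-clusters.

    Returns node_id → hierarchical label (``"<parent>.<j>"``).  Spinglass
    is only defined on connected graphs; a disconnected cluster is handled
    per component, with spins allocated proportionally to each component's
    share of the cluster's hub nodes (at least one spin each).
    """
    if k < 1:
        raise ValueError("spin count k must be >= 1")
    g = sub.undirected_simple_graph()
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot subdivide an empty cluster")
    if k == 1:
        return {nid: f"{parent_label}.1" for nid in g.nodes}

    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    hubs = find_hubs(g)
    labels: Dict[str, str] = {}
    next_sub = 1
    random.seed(seed)
    for comp in components:
        comp = set(comp)
        if len(components) == 1:
            spins = k
        else:
            share = max(1, round(k * len(comp & hubs) / max(1, len(hubs))))
            spins = share
        spins = min(spins, len(comp))
        if spins <= 1 or len(comp) < 3:
            for nid in sorted(comp):
                labels[nid] = f"{parent_label}.{next_sub}"
            next_sub += 1
            continue
        cg = g.subgraph(comp)
        graph, ids = _to_igraph(cg)
        communities = graph.community_spinglass(spins=spins)
        groups = [sorted(ids[i] for i in comm) for comm in communities if comm]
        groups.sort(key=lambda ms: (-len(ms), ms[0]))
        for members in groups:
            for nid in members:
                labels[nid] = f"{parent_label}.{next_sub}"
            next_sub += 1
    return labels


def layout_cluster(
    sub: KnowledgeNetwork,
    params: Optional[ClusteringParams] = None,
    seed: int = 0,
) -> Tuple[Dict[str, Tuple[float, float]], str]:
    """Per-cluster layout: grid initialisation, then Fruchterman–Reingold
    when the cluster has at most ``layout_switch`` nodes and at most
    ``layout_switch`` edges, Kamada–Kawai otherwise.  Returns the
    coordinates and the name of the algorithm chosen."""
    params = params or ClusteringParams()
    g = sub.undirected_simple_graph()
    n, m = g.number_of_nodes(), g.number_of_edges()
    init = grid_positions(g.nodes)
    if n <= 1:
        return {nid: (0.0, 0.0) for nid in g.nodes}, "grid"
    pos0 = {nid: list(xy) for nid, xy in init.items()}
    if n <= params.layout_switch and m <= params.layout_switch:
        algorithm = "fruchterman_reingold"
        pos = nx.spring_layout(g, pos=pos0, seed=seed)
    else:
        algorithm = "kamada_kawai"
        pos = nx.kamada_kawai_layout(g, pos=pos0)
    return {nid: (float(p[0]), float(p[1])) for nid, p in pos.items()}, algorithm


@dataclass
class ClusterizeResult:
    network: KnowledgeNetwork
    partition: Partition
    stats: Dict[int, ClusterStats]
    labels: Dict[int, str]          # flat id -> hierarchical label
    layout_algorithms: Dict[int, str]
    dropped: Set[str]


def clusterize(
    net: KnowledgeNetwork,
    params: Optional[ClusteringParams] = None,
) -> ClusterizeResult:
    """Full clustering pipeline over a (simplified) background network.

    The returned network contains the retained nodes, each annotated with a
    flat integer ``cluster_id``, a hierarchical ``cluster_label``, layout
    coordinates and degree.  Edges between different clusters are kept, so
    between-cluster relations survive into the exported tables.
    """
    params = params or ClusteringParams()
    simple, _ = simplify(net)
    simple = compute_degrees(simple)
    part = partition_multilevel(
        simple, seed=params.seed, min_cluster_size=params.min_cluster_size
    )

    # classify and optionally subdivide each top-level community
    final_groups: List[Tuple[str, List[str]]] = []  # (hierarchical label, members)
    top_stats: Dict[str, ClusterStats] = {}
    for cid, members in sorted(part.clusters().items()):
        sub = simple.subnetwork(members)
        stats = classify_cluster(sub, params, cluster_id=cid)
        top_stats[str(cid)] = stats
        if subdivision_gate(stats, params):
            sub_labels = subdivide_spinglass(
                sub, k=len(stats.hub_ids), seed=params.seed, parent_label=str(cid)
            )
            groups: Dict[str, List[str]] = {}
            for nid, lab in sub_labels.items():
                groups.setdefault(lab, []).append(nid)
            for lab in sorted(groups, key=lambda s: [int(p) for p in s.split(".")]):
                final_groups.append((lab, sorted(groups[lab])))
        else:
            final_groups.append((str(cid), sorted(members)))

    out = simple.subnetwork(sorted(part.assignment))
    stats_by_flat: Dict[int, ClusterStats] = {}
    labels: Dict[int, str] = {}
    algorithms: Dict[int, str] = {}
    for flat_id, (label, members) in enumerate(final_groups, start=1):
        sub = out.subnetwork(members)
        stats_by_flat[flat_id] = classify_cluster(sub, params, cluster_id=flat_id)
        labels[flat_id] = label
        coords, algo = layout_cluster(sub, params, seed=params.seed)
        algorithms[flat_id] = algo
        for nid in members:
            rec = out.nodes[nid]
            rec.cluster_id = flat_id
            rec.cluster_label = label
            if not rec.has_coordinates():
                rec.x, rec.y = coords[nid]
    return ClusterizeResult(
        network=out,
        partition=part,
        stats=stats_by_flat,
        labels=labels,
        layout_algorithms=algorithms,
        dropped=set(part.dropped),
    )
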
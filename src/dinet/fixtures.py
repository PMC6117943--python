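"""Synthetic background networks and measurement series with ground truth.

Fixture networks are assembled from planted clusters of known topology
(cliques, stars, sparse random blocks) joined by a few bridge edges, so the
clustering pipeline's output can be scored against planted labels.  The
measurement generator models "transcriptional switches": each condition has
a responsive node set whose members carry large effects (|logFC| drawn from
a shifted folded normal, signs balanced) and small adjusted p values, while
non-responsive nodes sit near zero with uniform p values.  A persistence
parameter carries part of each responsive set to the next condition, which
produces the module turn-on/turn-off rewiring the animation machinery is
meant to display.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import (
    ConditionSeries,
    EdgeRecord,
    KnowledgeNetwork,
    Measurement,
    NodeRecord,
    ValidationError,
)

_TOPOLOGIES = ("clique", "star", "random")


@dataclass
class ClusterSpec:
    topology: str                   # clique | star | random
    size: int
    edge_prob: float = 0.2          # random topology only

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if not (0.0 <= self.edge_prob <= 1.0):
            raise ValueError("edge probability must lie in [0, 1]")


@dataclass
class FixtureSpec:
    clusters: List[ClusterSpec]
    n_bridges: int = 2
    n_conditions: int = 3
    responsive_fraction: float = 0.3
    effect_location: float = 1.0    # minimum |logFC| of a responsive node
    effect_spread: float = 0.5      # folded-normal spread on top of it
    responsive_alpha: float = 0.01  # responsive significance ~ U(0, this)
    noise_weight_sd: float = 0.1    # non-responsive weight ~ N(0, this)
    persistence: float = 0.7        # responsive carry-over between conditions
    seed: int = 0


@dataclass
class GroundTruth:
    cluster_labels: Dict[str, int] = field(default_factory=dict)
    cluster_classes: Dict[int, str] = field(default_factory=dict)
    responsive: Dict[str, Set[str]] = field(default_factory=dict)


_EDGE_TYPES = np.array(["activation", "inhibition", "binding"])


def generate_background(spec: FixtureSpec) -> Tuple[KnowledgeNetwork, GroundTruth]:
    """Build a planted-structure background network.

    Cliques carry n(n-1)/2 undirected edges, stars one hub with n-1
    directed spokes, random blocks a directed edge per sampled unordered
    pair.  Bridges join uniformly sampled node pairs from distinct
    clusters.
    """
    rng = np.random.default_rng(spec.seed)
    nodes: List[NodeRecord] = []
    edges: List[EdgeRecord] = []
    truth = GroundTruth()
    members: List[List[str]] = []
    for ci, cs in enumerate(spec.clusters, start=1):
        ids = [f"c{ci}n{j:03d}" for j in range(1, cs.size + 1)]
        members.append(ids)
        for nid in ids:
            nodes.append(NodeRecord(node_id=nid, short_name=nid,
                                    bin_code=f"{10 + ci}.1"))
            truth.cluster_labels[nid] = ci
        if cs.topology == "clique":
            truth.cluster_classes[ci] = "densely_connected"
            for a in range(cs.size):
                for b in range(a + 1, cs.size):
                    edges.append(EdgeRecord(
                        ids[a], ids[b],
                        interaction_type=str(rng.choice(_EDGE_TYPES)),
                        directed=False,
                    ))
        elif cs.topology == "star":
            truth.cluster_classes[ci] = "star_like"
            hub = ids[0]
            for leaf in ids[1:]:
                edges.append(EdgeRecord(
                    hub, leaf,
                    interaction_type=str(rng.choice(_EDGE_TYPES[:2])),
                    directed=True,
                ))
        else:
            truth.cluster_classes[ci] = "regular"
            for a in range(cs.size):
                for b in range(a + 1, cs.size):
                    if rng.random() < cs.edge_prob:
                        src, tgt = (ids[a], ids[b]) if rng.random() < 0.5 \
                            else (ids[b], ids[a])
                        edges.append(EdgeRecord(
                            src, tgt,
                            interaction_type=str(rng.choice(_EDGE_TYPES)),
                            directed=True,
                        ))
    # bridges between distinct clusters
    n_clusters = len(spec.clusters)
    if n_clusters >= 2 and spec.n_bridges > 0:
        possible = sum(
            len(members[i]) * len(members[j])
            for i in range(n_clusters) for j in range(i + 1, n_clusters)
        )
        if spec.n_bridges > possible:
            raise ValidationError(
                f"{spec.n_bridges} bridges requested but only {possible} "
                "cross-cluster pairs exist"
            )
        placed: Set[Tuple[str, str]] = set()
        while len(placed) < spec.n_bridges:
            i, j = sorted(rng.choice(n_clusters, size=2, replace=False))
            a = members[i][rng.integers(len(members[i]))]
            b = members[j][rng.integers(len(members[j]))]
            if (a, b) not in placed:
                placed.add((a, b))
                edges.append(EdgeRecord(a, b, "activation", directed=True))
    net = KnowledgeNetwork.from_records(
        nodes, edges, name=f"fixture_seed{spec.seed}",
        provenance={"generator": "dinet.fixtures.generate_background"},
    )
    return net, truth


def generate_measurements(
    net: KnowledgeNetwork,
    spec: FixtureSpec,
    truth: Optional[GroundTruth] = None,
) -> ConditionSeries:
    """Draw a multi-condition measurement series over a network.

    Responsive nodes get |weight| = effect_location + |N(0, effect_spread)|
    with balanced random signs and significance ~ U(0, responsive_alpha);
    the rest get weight ~ N(0, noise_weight_sd) and significance ~ U(0, 1).
    Between consecutive conditions each responsive node persists with the
    spec's persistence probability and the set is topped back up to the
    target fraction, modelling modules switching on and off.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ids = sorted(net.nodes)
    n = len(ids)
    target = int(round(spec.responsive_fraction * n))
    labels = [f"t{i}" for i in range(spec.n_conditions)]
    measurements: Dict[str, Dict[str, Measurement]] = {}
    current: Set[str] = set(
        rng.choice(ids, size=target, replace=False)) if target else set()
    for li, label in enumerate(labels):
        if li > 0:
            kept = {nid for nid in current if rng.random() < spec.persistence}
            pool = [nid for nid in ids if nid not in kept]
            topup = max(0, target - len(kept))
            if topup and pool:
                kept |= set(rng.choice(pool, size=min(topup, len(pool)),
                                       replace=False))
            current = kept
        if truth is not None:
            truth.responsive[label] = set(current)
        row: Dict[str, Measurement] = {}
        for nid in ids:
            if nid in current:
                mag = spec.effect_location + abs(rng.normal(0.0, spec.effect_spread))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                row[nid] = Measurement(sign * mag,
                                       float(rng.uniform(0.0, spec.responsive_alpha)))
            else:
                row[nid] = Measurement(float(rng.normal(0.0, spec.noise_weight_sd)),
                                       float(rng.uniform(0.0, 1.0)))
        measurements[label] = row
    return ConditionSeries(labels, measurements)


# ---------------------------------------------------------------------------
# worked toy
# ---------------------------------------------------------------------------

def worked_toy() -> Tuple[KnowledgeNetwork, ConditionSeries]:
    """Fixed 12-node, two-cluster network with three hand-written conditions.

    Cluster A (A1..A6) is a ring with chords mixing all three interaction
    types; cluster B (B1..B6) is a star around B1; a single bridge joins
    A1 to B1.  The conditions stage a rewiring event: cluster A responds at
    t0, the response hands over to cluster B at t1, and t2 mixes both.
    Every value is a small constant, so expected differential networks can
    be checked by hand.  Byte-stable: no randomness involved.
    """
    nodes = [
        NodeRecord(f"A{i}", short_name=f"geneA{i}", bin_code="17.5.1")
        for i in range(1, 7)
    ] + [
        NodeRecord(f"B{i}", short_name=f"geneB{i}", bin_code="20.1")
        for i in range(1, 7)
    ]
    edges = [
        EdgeRecord("A1", "A2", "activation", True),
        EdgeRecord("A2", "A3", "inhibition", True),
        EdgeRecord("A3", "A4", "binding", False),
        EdgeRecord("A4", "A5", "activation", True),
        EdgeRecord("A5", "A6", "activation", True),
        EdgeRecord("A6", "A1", "inhibition", True),
        EdgeRecord("A1", "A3", "activation", True),
        EdgeRecord("A2", "A5", "inhibition", True),
        EdgeRecord("B1", "B2", "activation", True),
        EdgeRecord("B1", "B3", "activation", True),
        EdgeRecord("B1", "B4", "activation", True),
        EdgeRecord("B1", "B5", "binding", False),
        EdgeRecord("B1", "B6", "inhibition", True),
        EdgeRecord("A1", "B1", "activation", True),
    ]
    net = KnowledgeNetwork.from_records(
        nodes, edges, name="worked_toy",
        provenance={"generator": "dinet.fixtures.worked_toy"},
    )

    def m(w: float, p: float) -> Measurement:
        return Measurement(w, p)

    series = ConditionSeries(
        labels=["t0", "t1", "t2"],
        measurements={
            "t0": {
                "A1": m(1.2, 0.01), "A2": m(-0.8, 0.02), "A3": m(0.6, 0.03),
                "A4": m(0.1, 0.50), "A5": m(-1.5, 0.001), "A6": m(0.4, 0.04),
                "B1": m(0.2, 0.30), "B2": m(0.0, 0.90), "B3": m(-0.1, 0.80),
                "B4": m(0.05, 0.70), "B5": m(0.1, 0.60), "B6": m(-0.2, 0.60),
            },
            "t1": {
                "A1": m(0.3, 0.20), "A2": m(-0.2, 0.40), "A3": m(0.2, 0.30),
                "A4": m(0.0, 0.90), "A5": m(-0.4, 0.10), "A6": m(0.1, 0.50),
                "B1": m(2.0, 0.001), "B2": m(1.0, 0.01), "B3": m(-0.9, 0.02),
                "B4": m(0.7, 0.03), "B5": m(1.1, 0.005), "B6": m(-0.6, 0.04),
            },
            "t2": {
                "A1": m(-1.0, 0.01), "A2": m(0.9, 0.02), "A3": m(0.1, 0.60),
                "A4": m(0.2, 0.40), "A5": m(-0.3, 0.20), "A6": m(0.0, 0.95),
                "B1": m(0.8, 0.02), "B2": m(0.2, 0.50), "B3": m(-1.2, 0.01),
                "B4": m(0.1, 0.60), "B5": m(0.5, 0.04), "B6": m(-0.05, 0.90),
            },
        },
    )
    return net, series
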
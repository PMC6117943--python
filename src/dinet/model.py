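"""Core data model for background knowledge networks and measurement overlays.

A :class:`KnowledgeNetwork` is a typed molecular interaction graph (nodes are
genes/proteins/metabolites, edges are activation/inhibition/binding relations)
onto which per-condition experimental measurements — a signed node weight such
as a log2 fold change and a significance such as an adjusted p value — are
projected by the :mod:`dinet.diffnet` machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import networkx as nx

#: Canonical interaction types.  Anything else is normalised to "unknown".
INTERACTION_TYPES = ("activation", "inhibition", "binding", "unknown")


@dataclass
class NodeRecord:
    """One node of the background network.

    ``bin_code`` is a dot-separated hierarchical functional-bin path
    (MapMan-style, e.g. ``"17.5.1"``); multiple bins may be given separated
    by ``|``.  ``cluster_id`` and layout coordinates are filled in by the
    clustering pipeline.
    """

    node_id: str
    short_name: str = ""
    description: Optional[str] = None
    bin_code: Optional[str] = None
    cluster_id: Optional[int] = None
    cluster_label: Optional[str] = None
    x: Optional[float] = None
    y: Optional[float] = None
    degree: Optional[int] = None

    def has_coordinates(self) -> bool:
        return (
            self.x is not None
            and self.y is not None
            and math.isfinite(self.x)
            and math.isfinite(self.y)
        )


@dataclass
class EdgeRecord:
    """A typed interaction between two nodes of the background network."""

    source_id: str
    target_id: str
    interaction_type: str = "unknown"
    directed: bool = True

    def key(self) -> Tuple:
        """Identity used for duplicate detection.

        Directed edges are keyed by the ordered pair; undirected edges by the
        unordered pair, so ``A-B`` and ``B-A`` collapse.  The interaction
        type is always part of the key: reciprocal regulation and multi-type
        relations stay distinct.
        """
        if self.directed:
            ends = (self.source_id, self.target_id)
        else:
            ends = tuple(sorted((self.source_id, self.target_id)))
        return (ends, self.interaction_type, self.directed)

    def is_self_loop(self) -> bool:
        return self.source_id == self.target_id


class ValidationError(ValueError):
    """Raised when a network or table violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an input file does not follow the documented schema."""


@dataclass
class KnowledgeNetwork:
    """Background knowledge network: nodes, typed edges, provenance."""

    nodes: Dict[str, NodeRecord] = field(default_factory=dict)
    edges: List[EdgeRecord] = field(default_factory=list)
    name: str = "network"
    provenance: Dict[str, str] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        nodes: Iterable[NodeRecord],
        edges: Iterable[EdgeRecord],
        name: str = "network",
        provenance: Optional[Mapping[str, str]] = None,
    ) -> "KnowledgeNetwork":
        node_map: Dict[str, NodeRecord] = {}
        for rec in nodes:
            if rec.node_id in node_map:
                raise ValidationError(f"duplicate node_id: {rec.node_id!r}")
            node_map[rec.node_id] = rec
        net = cls(node_map, list(edges), name, dict(provenance or {}))
        net.check_referential_integrity()
        return net

    def check_referential_integrity(self) -> None:
        missing = sorted(
            {e.source_id for e in self.edges if e.source_id not in self.nodes}
            | {e.target_id for e in self.edges if e.target_id not in self.nodes}
        )
        if missing:
            raise ValidationError(
                "edges reference nodes absent from the node set: "
                + ", ".join(missing)
            )

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "KnowledgeNetwork":
        return KnowledgeNetwork(
            {k: replace(v) for k, v in self.nodes.items()},
            [replace(e) for e in self.edges],
            self.name,
            dict(self.provenance),
        )

    def subnetwork(self, node_ids: Iterable[str]) -> "KnowledgeNetwork":
        keep = set(node_ids)
        unknown = keep - set(self.nodes)
        if unknown:
            raise ValidationError(f"unknown node ids: {sorted(unknown)}")
        return KnowledgeNetwork(
            {k: replace(v) for k, v in self.nodes.items() if k in keep},
            [
                replace(e)
                for e in self.edges
                if e.source_id in keep and e.target_id in keep
            ],
            self.name,
            dict(self.provenance),
        )

    # -- graph views ------------------------------------------------------
    def to_networkx(self, directed: bool = True) -> nx.MultiDiGraph | nx.MultiGraph:
        """Export as a networkx multigraph preserving all attributes."""
        g: nx.MultiDiGraph | nx.MultiGraph
        g = nx.MultiDiGraph() if directed else nx.MultiGraph()
        schema = {
            "description": "annotation",
            "bin_code": "bin",
            "cluster_id": "clusterID",
            "cluster_label": "clusterLabel",
            "x": "x",
            "y": "y",
            "degree": "degree",
        }
        for nid in sorted(self.nodes):
            rec = self.nodes[nid]
            attrs = {"shortName": rec.short_name}
            for attr, name in schema.items():
                val = getattr(rec, attr)
                if val is not None:
                    attrs[name] = val
            g.add_node(nid, **attrs)
        for e in self.edges:
            g.add_edge(
                e.source_id,
                e.target_id,
                type=e.interaction_type,
                directed=e.directed,
            )
        return g

    def undirected_simple_graph(self) -> nx.Graph:
        """Undirected simple view used by community detection and centrality.

        Parallel edges of any type or direction collapse to a single
        undirected edge; self-loops are excluded.
        """
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            if not e.is_self_loop():
                g.add_edge(e.source_id, e.target_id)
        return g


@dataclass
class Measurement:
    """One node's reading under one condition."""

    weight: float
    significance: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.significance <= 1.0):
            raise ValidationError(
                f"significance {self.significance} outside [0, 1]"
            )


@dataclass
class ConditionSeries:
    """Ordered per-condition measurements: the experimental overlay.

    ``measurements[label][node_id]`` holds the node's weight (e.g. logFC)
    and significance (e.g. adjusted p value) under that condition.
    """

    labels: List[str]
    measurements: Dict[str, Dict[str, Measurement]]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("a condition series needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("condition labels must be unique")
        for label in self.labels:
            self.measurements.setdefault(label, {})

    @property
    def n_conditions(self) -> int:
        return len(self.labels)

    def get(self, label: str, node_id: str) -> Optional[Measurement]:
        return self.measurements.get(label, {}).get(node_id)

    def node_ids(self) -> set:
        out: set = set()
        for label in self.labels:
            out |= set(self.measurements[label])
        return out
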
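"""Condition-specific differential subnetworks.

A node is *active* under a condition when its significance is below the
cutoff (strict, e.g. adjusted p < 0.05) and its absolute weight reaches the
weight threshold (inclusive, e.g. |logFC| >= 0.5).  An edge is active when
both endpoints are active; its display weight is the saturating sum

    w(n, m) = s / max(s, 1),   s = |n|/max(|n|, 1) + |m|/max(|m|, 1)

which lives in [0, 1], equals |n| + |m| while both are sub-unit and their
sum is below one, and saturates at 1 as soon as either endpoint's absolute
weight reaches 1.  Node size and a red–white–blue colour scale encode the
signed weight for display.

Functional-bin over-representation per cluster uses the one-sided
hypergeometric test with Benjamini–Hochberg adjustment across bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import KnowledgeNetwork, Measurement, ValidationError


@dataclass(frozen=True)
class Thresholds:
    """Cut-off parameters for building a differential network."""

    alpha: float = 0.05
    min_abs_weight: float = 0.5
    min_degree: int = 0
    weight_is_interpolated: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.min_abs_weight < 0:
            raise ValueError("min_abs_weight must be non-negative")
        if self.min_degree < 0:
            raise ValueError("min_degree must be non-negative")


@dataclass
class ActiveNode:
    weight: float
    size: float = 1.0
    colour_value: float = 0.0


@dataclass
class DifferentialNetwork:
    """Active nodes and edges of one condition over a background cluster."""

    condition_label: str
    active_nodes: Dict[str, ActiveNode] = field(default_factory=dict)
    active_edges: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def copy(self) -> "DifferentialNetwork":
        return DifferentialNetwork(
            self.condition_label,
            {k: replace(v) for k, v in self.active_nodes.items()},
            dict(self.active_edges),
        )


def node_passes(
    weight: Optional[float],
    significance: Optional[float],
    thresholds: Thresholds,
) -> bool:
    """Cut-off rule: significance strictly below alpha AND absolute weight
    at or above the weight threshold.  A missing measurement never passes."""
    if weight is None or significance is None:
        return False
    if not (0.0 <= significance <= 1.0):
        raise ValidationError(f"significance {significance} outside [0, 1]")
    return significance < thresholds.alpha and abs(weight) >= thresholds.min_abs_weight


def edge_weight(wn: float, wm: float) -> float:
    """Saturating edge weight from the two endpoint node weights."""
    if not (math.isfinite(wn) and math.isfinite(wm)):
        raise ValueError("edge_weight requires finite node weights")
    s = abs(wn) / max(abs(wn), 1.0) + abs(wm) / max(abs(wm), 1.0)
    return s / max(s, 1.0)


def active_subnetwork(
    cluster: KnowledgeNetwork,
    measurements: Mapping[str, Measurement],
    thresholds: Thresholds,
    condition_label: str = "",
) -> DifferentialNetwork:
    """Build the condition-specific subnetwork of one background cluster.

    Active nodes are the measured nodes passing the cut-offs; background
    edges with both endpoints active become active edges weighted by
    :func:`edge_weight`.  Passing nodes with no passing neighbour remain as
    isolated active nodes.
    """
    diff = DifferentialNetwork(condition_label)
    for nid in sorted(cluster.nodes):
        m = measurements.get(nid)
        if m is not None and node_passes(m.weight, m.significance, thresholds):
            diff.active_nodes[nid] = ActiveNode(weight=m.weight)
    for e in cluster.edges:
        if e.is_self_loop():
            continue
        if e.source_id in diff.active_nodes and e.target_id in diff.active_nodes:
            key = (e.source_id, e.target_id)
            diff.active_edges[key] = edge_weight(
                diff.active_nodes[e.source_id].weight,
                diff.active_nodes[e.target_id].weight,
            )
    return diff


def encode_visuals(
    diff: DifferentialNetwork,
    max_abs_weight_for_scale: float = 2.0,
    base_size: float = 10.0,
) -> DifferentialNetwork:
    """Fill node size and colour from the signed weight.

    Size grows linearly with |weight| from ``base_size``; the colour value
    is the weight clipped to ±scale, mapped onto a symmetric diverging
    red–white–blue axis (positive = red/up-regulated, negative =
    blue/down-regulated, zero = white).
    """
    if max_abs_weight_for_scale <= 0:
        raise ValueError("colour/size scale must be positive")
    out = diff.copy()
    s = max_abs_weight_for_scale
    for node in out.active_nodes.values():
        node.size = base_size * (1.0 + abs(node.weight) / s)
        node.colour_value = min(max(node.weight, -s), s)
    return out


def filter_min_degree(
    diff: DifferentialNetwork,
    cluster: KnowledgeNetwork,
    k: int,
) -> DifferentialNetwork:
    """Drop active nodes whose degree in the *background* cluster is below
    ``k``, then prune active edges left without both endpoints.  The degree
    is the static cluster-level degree, so the filter is stable across
    conditions and frames."""
    if k < 0:
        raise ValueError("minimum degree must be non-negative")
    if k == 0:
        return diff.copy()
    g = cluster.undirected_simple_graph()
    out = DifferentialNetwork(diff.condition_label)
    for nid, node in diff.active_nodes.items():
        if nid in g and g.degree(nid) >= k:
            out.active_nodes[nid] = replace(node)
    for (u, v), w in diff.active_edges.items():
        if u in out.active_nodes and v in out.active_nodes:
            out.active_edges[(u, v)] = w
    return out


def check_module_size(
    cluster: KnowledgeNetwork,
    min_edges: int = 2,
    max_edges: int = 16384,
) -> bool:
    """Visualisation module-size guard: the loop-free edge count must lie
    in [min_edges, max_edges], both ends inclusive."""
    m = sum(1 for e in cluster.edges if not e.is_self_loop())
    return min_edges <= m <= max_edges


# ---------------------------------------------------------------------------
# functional-bin enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    bin_code: str
    in_cluster_with_bin: int
    in_network_with_bin: int
    cluster_size: int
    network_size: int
    p_value: float
    adjusted_p: float


def expand_bins(bin_code: Optional[str]) -> Set[str]:
    """Expand a node's bin annotation to all ancestor bins.

    ``"17.5.1|20.1"`` → {"17", "17.5", "17.5.1", "20", "20.1"}.
    """
    out: Set[str] = set()
    if not bin_code:
        return out
    for code in bin_code.split("|"):
        parts = [p for p in code.strip().split(".") if p != ""]
        for i in range(1, len(parts) + 1):
            out.add(".".join(parts[:i]))
    return out


def bin_enrichment(
    cluster_nodes: Iterable[str],
    network_nodes: Iterable[str],
    bin_annotation: Mapping[str, str],
) -> List[EnrichmentRow]:
    """Per-bin over-representation of a cluster against the whole network.

    For each bin (hierarchical codes expanded to ancestors) the one-sided
    hypergeometric upper tail P(X >= k) is computed with population N =
    network size, K = annotated nodes in the network, n = cluster size,
    k = annotated nodes in the cluster; Benjamini–Hochberg adjusts across
    the bins tested within the cluster.
    """
    cluster = set(cluster_nodes)
    network = set(network_nodes)
    if not cluster <= network:
        raise ValidationError("cluster node set must be a subset of the network")
    node_bins = {nid: expand_bins(bin_annotation.get(nid)) for nid in network}
    bins = sorted(set().union(*node_bins.values())) if node_bins else []
    N, n = len(network), len(cluster)
    rows: List[EnrichmentRow] = []
    pvals: List[float] = []
    for b in bins:
        K = sum(1 for nid in network if b in node_bins[nid])
        k = sum(1 for nid in cluster if b in node_bins[nid])
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(0.0, p))
        rows.append(EnrichmentRow(b, k, K, n, N, p, p))
        pvals.append(p)
    if pvals:
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        for row, adj in zip(rows, adjusted):
            row.adjusted_p = float(adj)
    return rows
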
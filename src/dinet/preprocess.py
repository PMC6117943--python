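"""Network pre-processing: simplification, degrees, default layout.

Mirrors the preparation stage a background knowledge network goes through
before clustering and overlay: self-loops and duplicated edges are removed,
the node degree is computed on the simplified graph, and nodes lacking
user-supplied coordinates receive a deterministic default layout (row-major
square grid initialisation refined by Kamada–Kawai).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import networkx as nx

from .model import KnowledgeNetwork


@dataclass
class SimplificationReport:
    removed_self_loops: int = 0
    removed_duplicate_edges: int = 0


def simplify(net: KnowledgeNetwork) -> Tuple[KnowledgeNetwork, SimplificationReport]:
    """Remove self-loops and duplicated edges; first occurrence wins.

    Duplicates are detected per (source, target, interaction_type) with
    direction respected for directed edges and endpoint order ignored for
    undirected ones, so reciprocal directed regulation (A→B and B→A) is
    preserved.  Idempotent.
    """
    out = net.copy()
    report = SimplificationReport()
    kept = []
    seen = set()
    for e in out.edges:
        if e.is_self_loop():
            report.removed_self_loops += 1
            continue
        k = e.key()
        if k in seen:
            report.removed_duplicate_edges += 1
            continue
        seen.add(k)
        kept.append(e)
    out.edges = kept
    return out, report


def compute_degrees(net: KnowledgeNetwork) -> KnowledgeNetwork:
    """Set each node's ``degree`` to its incident edge count, ignoring
    direction.  Expects a simplified network; the degree sum then equals
    twice the edge count."""
    out = net.copy()
    counts: Dict[str, int] = {nid: 0 for nid in out.nodes}
    for e in out.edges:
        counts[e.source_id] += 1
        if e.target_id != e.source_id:
            counts[e.target_id] += 1
    for nid, rec in out.nodes.items():
        rec.degree = counts[nid]
    return out


def grid_positions(node_ids) -> Dict[str, Tuple[float, float]]:
    """Row-major square-grid positions over lexicographically sorted ids.

    The grid side is ceil(sqrt(n)); node i sits at (i mod side, i div side).
    A single node lands at the origin.
    """
    ids = sorted(node_ids)
    n = len(ids)
    if n == 0:
        return {}
    side = max(1, math.ceil(math.sqrt(n)))
    return {
        nid: (float(i % side), float(i // side)) for i, nid in enumerate(ids)
    }


def assign_layout(net: KnowledgeNetwork, seed: int = 0) -> KnowledgeNetwork:
    """Give every node finite coordinates.

    Nodes that already carry user coordinates are never moved.  The
    remaining nodes are initialised on a deterministic grid and the whole
    graph is refined by Kamada–Kawai (a deterministic quasi-Newton
    optimisation, so repeated runs agree exactly); afterwards the
    user-supplied coordinates are restored verbatim.  ``seed`` is accepted
    for interface symmetry with the stochastic layouts.
    """
    out = net.copy()
    if not out.nodes:
        return out
    fixed = {
        nid: (rec.x, rec.y)
        for nid, rec in out.nodes.items()
        if rec.has_coordinates()
    }
    free = [nid for nid in out.nodes if nid not in fixed]
    if not free:
        return out
    init = grid_positions(out.nodes)
    init.update(fixed)
    g = out.undirected_simple_graph()
    if g.number_of_nodes() == 1:
        pos = {next(iter(g.nodes)): (0.0, 0.0)}
    else:
        pos = nx.kamada_kawai_layout(g, pos={k: list(v) for k, v in init.items()})
    for nid, rec in out.nodes.items():
        if nid in fixed:
            rec.x, rec.y = fixed[nid]
        else:
            rec.x, rec.y = float(pos[nid][0]), float(pos[nid][1])
    return out
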
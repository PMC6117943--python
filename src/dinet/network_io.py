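"""Readers and writers for background networks and measurement tables.

Supported formats
-----------------
* Delimiter-separated node / edge / measurement tables (tab, comma or
  semicolon; auto-detected from the header when not specified).
* GraphML for whole networks (read and write), via :mod:`networkx`.
* XGMML, read-only, to merge user-defined node coordinates exported from
  Cytoscape-like tools.

Column schema (fixed, documented; extra columns are ignored)
------------------------------------------------------------
node table:        geneID, shortName, annotation, bin, clusterID, x, y, degree
edge table:        geneID1, geneID2, type, directed
measurement table: geneID, then one ``<label>_logFC`` / ``<label>_padj``
                   column pair per condition, in condition order.

GraphML node/edge attribute names follow the same schema; the mapping can be
overridden per call for foreign exports.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd
from lxml import etree

from .model import (
    ConditionSeries,
    EdgeRecord,
    FormatError,
    INTERACTION_TYPES,
    KnowledgeNetwork,
    Measurement,
    NodeRecord,
    ValidationError,
)

_DIALECTS = {"tab": "\t", "comma": ",", "semicolon": ";"}

#: Default synonym map applied to raw interaction-type strings (lower-cased,
#: stripped).  Unmapped values become "unknown".
DEFAULT_TYPE_SYNONYMS: Dict[str, str] = {
    "activation": "activation",
    "act": "activation",
    "act.": "activation",
    "activates": "activation",
    "positive": "activation",
    "+": "activation",
    "inhibition": "inhibition",
    "inh": "inhibition",
    "inh.": "inhibition",
    "inhibits": "inhibition",
    "repression": "inhibition",
    "negative": "inhibition",
    "-": "inhibition",
    "binding": "binding",
    "binds": "binding",
    "bind": "binding",
    "complex": "binding",
    "unknown": "unknown",
}

#: GraphML/XGMML attribute name -> NodeRecord field.
DEFAULT_NODE_ATTR_MAP: Dict[str, str] = {
    "shortName": "short_name",
    "annotation": "description",
    "bin": "bin_code",
    "clusterID": "cluster_id",
    "clusterLabel": "cluster_label",
    "x": "x",
    "y": "y",
    "degree": "degree",
}


def _detect_separator(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    counts = {sep: header.count(sep) for sep in ("\t", ";", ",")}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        return "\t"  # single-column table: any separator parses it
    return best


def _read_table(path: str, dialect: Optional[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect is None:
        sep = _detect_separator(path)
    else:
        try:
            sep = _DIALECTS[dialect]
        except KeyError:
            raise FormatError(
                f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
            ) from None
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       encoding="utf-8")


def _opt(row: Mapping[str, str], col: str) -> Optional[str]:
    val = row.get(col, "")
    val = val.strip() if isinstance(val, str) else val
    return val if val not in ("", None) else None


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------

def read_node_table(path: str, dialect: Optional[str] = None) -> List[NodeRecord]:
    """Read a node table; one :class:`NodeRecord` per row.

    Raises :class:`FormatError` if the geneID column is missing and
    :class:`ValidationError` on duplicate identifiers.
    """
    df = _read_table(path, dialect)
    if "geneID" not in df.columns:
        raise FormatError(f"{path}: node table lacks a geneID column")
    records: List[NodeRecord] = []
    seen: set = set()
    for _, row in df.iterrows():
        nid = str(row["geneID"]).strip()
        if nid in seen:
            raise ValidationError(f"{path}: duplicate node_id {nid!r}")
        seen.add(nid)
        cid = _opt(row, "clusterID")
        deg = _opt(row, "degree")
        records.append(
            NodeRecord(
                node_id=nid,
                short_name=_opt(row, "shortName") or nid,
                description=_opt(row, "annotation"),
                bin_code=_opt(row, "bin"),
                cluster_id=int(cid) if cid is not None else None,
                cluster_label=_opt(row, "clusterLabel"),
                x=float(_opt(row, "x")) if _opt(row, "x") is not None else None,
                y=float(_opt(row, "y")) if _opt(row, "y") is not None else None,
                degree=int(deg) if deg is not None else None,
            )
        )
    return records


def normalise_interaction_type(
    raw: str, synonyms: Optional[Mapping[str, str]] = None
) -> str:
    table = dict(DEFAULT_TYPE_SYNONYMS)
    if synonyms:
        table.update({k.strip().lower(): v for k, v in synonyms.items()})
    mapped = table.get(raw.strip().lower(), "unknown")
    if mapped not in INTERACTION_TYPES:
        raise ValidationError(f"synonym map targets unknown type {mapped!r}")
    return mapped


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def read_edge_table(
    path: str,
    dialect: Optional[str] = None,
    synonyms: Optional[Mapping[str, str]] = None,
    node_ids: Optional[Iterable[str]] = None,
) -> List[EdgeRecord]:
    """Read an edge table.  When ``node_ids`` is given, endpoints are
    checked against it and a :class:`ValidationError` lists all offenders.
    """
    df = _read_table(path, dialect)
    for col in ("geneID1", "geneID2"):
        if col not in df.columns:
            raise FormatError(f"{path}: edge table lacks a {col} column")
    edges: List[EdgeRecord] = []
    for _, row in df.iterrows():
        raw_type = _opt(row, "type") or "unknown"
        directed_raw = (_opt(row, "directed") or "true").lower()
        if directed_raw in _TRUE:
            directed = True
        elif directed_raw in _FALSE:
            directed = False
        else:
            raise FormatError(f"{path}: unparseable directed flag {directed_raw!r}")
        edges.append(
            EdgeRecord(
                source_id=str(row["geneID1"]).strip(),
                target_id=str(row["geneID2"]).strip(),
                interaction_type=normalise_interaction_type(raw_type, synonyms),
                directed=directed,
            )
        )
    if node_ids is not None:
        known = set(node_ids)
        missing = sorted(
            {e.source_id for e in edges if e.source_id not in known}
            | {e.target_id for e in edges if e.target_id not in known}
        )
        if missing:
            raise ValidationError(
                f"{path}: edges reference unknown nodes: {', '.join(missing)}"
            )
    return edges


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def read_graphml(
    path: str, attr_map: Optional[Mapping[str, str]] = None
) -> KnowledgeNetwork:
    """Read a GraphML file into a :class:`KnowledgeNetwork`.

    Node attributes are mapped to record fields through ``attr_map``
    (default :data:`DEFAULT_NODE_ATTR_MAP`); unmapped attributes are ignored.
    """
    try:
        g = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # noqa: BLE001 - surface parse failures uniformly
        raise FormatError(f"{path}: not well-formed GraphML ({exc})") from exc
    if g.number_of_nodes() == 0:
        raise ValidationError(f"{path}: GraphML contains no nodes")
    amap = dict(attr_map or DEFAULT_NODE_ATTR_MAP)
    nodes: List[NodeRecord] = []
    for nid, data in g.nodes(data=True):
        rec = NodeRecord(node_id=str(nid), short_name=str(nid))
        for attr, fieldname in amap.items():
            if attr in data:
                val = data[attr]
                if fieldname in ("x", "y"):
                    val = float(val)
                elif fieldname in ("cluster_id", "degree"):
                    val = int(val)
                else:
                    val = str(val)
                setattr(rec, fieldname, val)
        nodes.append(rec)
    edges: List[EdgeRecord] = []
    default_directed = isinstance(g, (nx.DiGraph, nx.MultiDiGraph))
    for u, v, data in g.edges(data=True):
        directed = data.get("directed", default_directed)
        if isinstance(directed, str):
            directed = directed.strip().lower() in _TRUE
        edges.append(
            EdgeRecord(
                source_id=str(u),
                target_id=str(v),
                interaction_type=normalise_interaction_type(
                    str(data.get("interaction_type", data.get("type", "unknown")))
                ),
                directed=bool(directed),
            )
        )
    return KnowledgeNetwork.from_records(
        nodes, edges,
        name=os.path.splitext(os.path.basename(path))[0],
        provenance={"source": path},
    )


def write_graphml(net: KnowledgeNetwork, path: str) -> None:
    """Write a network to GraphML, losslessly for all set record fields."""
    g = net.to_networkx(directed=True)
    nx.write_graphml(g, path, encoding="utf-8")


# ---------------------------------------------------------------------------
# XGMML coordinates
# ---------------------------------------------------------------------------

@dataclass
class CoordinateMergeReport:
    updated: List[str] = field(default_factory=list)
    unmatched_in_xgmml: List[str] = field(default_factory=list)


def merge_xgmml_coordinates(
    net: KnowledgeNetwork, path: str
) -> Tuple[KnowledgeNetwork, CoordinateMergeReport]:
    """Overwrite node coordinates from an XGMML file's graphics sections.

    Nodes are matched by XGMML ``label`` (falling back to ``id``).  Matched
    nodes get the XGMML coordinates; others are untouched and reported.
    Raises :class:`ValidationError` if nothing matches.
    """
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not well-formed XGMML ({exc})") from exc
    coords: Dict[str, Tuple[float, float]] = {}
    for node in tree.iter("{*}node"):
        key = node.get("label") or node.get("id")
        if key is None:
            continue
        for gfx in node.iter("{*}graphics"):
            x, y = gfx.get("x"), gfx.get("y")
            if x is not None and y is not None:
                coords[key] = (float(x), float(y))
    if not coords:
        raise ValidationError(f"{path}: no node graphics coordinates found")
    out = net.copy()
    report = CoordinateMergeReport()
    for key, (x, y) in sorted(coords.items()):
        if key in out.nodes:
            out.nodes[key].x = x
            out.nodes[key].y = y
            report.updated.append(key)
        else:
            report.unmatched_in_xgmml.append(key)
    if not report.updated:
        raise ValidationError(
            f"{path}: no XGMML node labels match the network identifiers"
        )
    out.provenance["coordinates"] = path
    return out, report


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str, dialect: Optional[str] = None
) -> ConditionSeries:
    """Read a wide-layout measurement table into a :class:`ConditionSeries`.

    After the geneID column, columns come in ``<label>_logFC`` /
    ``<label>_padj`` pairs, one per condition, in condition order.  An
    incomplete or mislabelled pair raises :class:`FormatError`; a
    significance outside [0, 1] raises :class:`ValidationError`.
    """
    df = _read_table(path, dialect)
    if "geneID" not in df.columns:
        raise FormatError(f"{path}: measurement table lacks a geneID column")
    cols = [c for c in df.columns if c != "geneID"]
    if len(cols) % 2 != 0 or not cols:
        raise FormatError(
            f"{path}: expected <label>_logFC/<label>_padj column pairs, "
            f"got {cols}"
        )
    labels: List[str] = []
    for wcol, pcol in zip(cols[0::2], cols[1::2]):
        if not wcol.endswith("_logFC") or not pcol.endswith("_padj"):
            raise FormatError(
                f"{path}: column pair ({wcol!r}, {pcol!r}) does not follow "
                "the <label>_logFC / <label>_padj convention"
            )
        lw, lp = wcol[: -len("_logFC")], pcol[: -len("_padj")]
        if lw != lp:
            raise FormatError(
                f"{path}: weight/significance pair labels differ: {lw!r} vs {lp!r}"
            )
        labels.append(lw)
    measurements: Dict[str, Dict[str, Measurement]] = {lab: {} for lab in labels}
    for _, row in df.iterrows():
        nid = str(row["geneID"]).strip()
        for lab in labels:
            w, p = row[f"{lab}_logFC"].strip(), row[f"{lab}_padj"].strip()
            if w == "" and p == "":
                continue  # missing measurement for this condition
            if w == "" or p == "":
                raise FormatError(
                    f"{path}: node {nid}, condition {lab}: weight/significance "
                    "pair incomplete"
                )
            measurements[lab][nid] = Measurement(float(w), float(p))
    return ConditionSeries(labels, measurements)


def write_expression_table(series: ConditionSeries, path: str) -> None:
    """Inverse of :func:`read_expression_table` (tab-separated)."""
    ids = sorted(series.node_ids())
    cols: Dict[str, List[str]] = {"geneID": ids}
    for lab in series.labels:
        wvals, pvals = [], []
        for nid in ids:
            m = series.get(lab, nid)
            wvals.append("" if m is None else repr(m.weight))
            pvals.append("" if m is None else repr(m.significance))
        cols[f"{lab}_logFC"] = wvals
        cols[f"{lab}_padj"] = pvals
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# table writers / validation
# ---------------------------------------------------------------------------

def nodes_to_frame(net: KnowledgeNetwork) -> pd.DataFrame:
    rows = []
    for nid in sorted(net.nodes):
        r = net.nodes[nid]
        rows.append(
            {
                "geneID": r.node_id,
                "shortName": r.short_name,
                "annotation": r.description or "",
                "bin": r.bin_code or "",
                "clusterID": "" if r.cluster_id is None else r.cluster_id,
                "clusterLabel": r.cluster_label or "",
                "x": "" if r.x is None else repr(float(r.x)),
                "y": "" if r.y is None else repr(float(r.y)),
                "degree": "" if r.degree is None else r.degree,
            }
        )
    return pd.DataFrame(rows)


def edges_to_frame(net: KnowledgeNetwork) -> pd.DataFrame:
    rows = []
    for e in net.edges:
        src = net.nodes.get(e.source_id)
        tgt = net.nodes.get(e.target_id)
        rows.append(
            {
                "geneID1": e.source_id,
                "geneID2": e.target_id,
                "type": e.interaction_type,
                "directed": str(e.directed).lower(),
                "clusterID1": "" if src is None or src.cluster_id is None else src.cluster_id,
                "clusterID2": "" if tgt is None or tgt.cluster_id is None else tgt.cluster_id,
            }
        )
    return pd.DataFrame(rows)


def write_cluster_tables(net: KnowledgeNetwork, directory: str) -> List[str]:
    """Emit nodes.tsv / edges.tsv for the whole network plus one GraphML per
    cluster.  Inter-cluster edges appear in edges.tsv with both cluster ids.
    Returns the written paths."""
    os.makedirs(directory, exist_ok=True)
    paths: List[str] = []
    npath = os.path.join(directory, "nodes.tsv")
    epath = os.path.join(directory, "edges.tsv")
    nodes_to_frame(net).to_csv(npath, sep="\t", index=False, encoding="utf-8")
    edges_to_frame(net).to_csv(epath, sep="\t", index=False, encoding="utf-8")
    paths += [npath, epath]
    cluster_ids = sorted(
        {r.cluster_id for r in net.nodes.values() if r.cluster_id is not None}
    )
    for cid in cluster_ids:
        members = [nid for nid, r in net.nodes.items() if r.cluster_id == cid]
        sub = net.subnetwork(members)
        gpath = os.path.join(directory, f"cluster_{cid}.graphml")
        write_graphml(sub, gpath)
        paths.append(gpath)
    return paths


@dataclass
class ValidationReport:
    """Identifier-consistency report between a network and measurements."""

    dangling_edge_endpoints: List[str] = field(default_factory=list)
    unmatched_measured_ids: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.dangling_edge_endpoints and not self.unmatched_measured_ids


def validate_network(
    net: KnowledgeNetwork, series: Optional[ConditionSeries] = None
) -> ValidationReport:
    """Check edge referential integrity and, if measurements are supplied,
    that every measured identifier exists in the network.  Unmatched
    measurement identifiers are reported (and are excluded from analysis by
    the downstream modules), not fatal."""
    report = ValidationReport()
    known = set(net.nodes)
    report.dangling_edge_endpoints = sorted(
        {e.source_id for e in net.edges if e.source_id not in known}
        | {e.target_id for e in net.edges if e.target_id not in known}
    )
    if series is not None:
        report.unmatched_measured_ids = sorted(series.node_ids() - known)
    return report
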
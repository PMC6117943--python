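"""Animation of network rewiring: homotopy frames, rendering, settings log.

Between two consecutive conditions every node weight follows a straight-line
homotopy ``(1-u)·v0 + u·v1`` for u in [0, 1]; the threshold rule is
re-evaluated at every intermediate frame on the interpolated weight, so a
node fades out of the picture the moment its interpolated |weight| drops
below the cut-off.  Edge weights are recomputed from the interpolated
endpoint weights with the same saturating formula used for the static
differential networks, so frames at integer times coincide exactly with the
per-condition networks.

Significance is not interpolated: an intermediate frame inherits the
significance pass/fail from the transition's source condition for u < 0.5
and from the destination for u >= 0.5 (rule ``"nearest"``), or can be made
to require both endpoints to pass (``"both"``).

Every run can be written to a settings log (YAML: thresholds, seeds, input
checksums, version) from which :func:`replay` re-executes the pipeline and
verifies the output checksum — a lightweight reproducibility contract in
the FAIR spirit.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import yaml
from matplotlib.patches import FancyArrowPatch

from . import __version__
from .diffnet import (
    ActiveNode,
    DifferentialNetwork,
    Thresholds,
    active_subnetwork,
    edge_weight,
    encode_visuals,
)
from .model import ConditionSeries, KnowledgeNetwork, ValidationError


def interpolate_value(v0: float, v1: float, u: float) -> float:
    """Linear homotopy between two endpoint values; u must lie in [0, 1]."""
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"homotopy parameter u={u} outside [0, 1]")
    return (1.0 - u) * v0 + u * v1


@dataclass
class FrameNode:
    weight: float
    size: float
    colour_value: float
    visible: bool


@dataclass
class Frame:
    t: float
    nodes: Dict[str, FrameNode] = field(default_factory=dict)
    edges: Dict[Tuple[str, str], Tuple[float, bool]] = field(default_factory=dict)

    def to_differential_network(self, label: str = "") -> DifferentialNetwork:
        """Visible content of the frame as a static differential network."""
        diff = DifferentialNetwork(label)
        for nid, fn in self.nodes.items():
            if fn.visible:
                diff.active_nodes[nid] = ActiveNode(fn.weight, fn.size, fn.colour_value)
        for key, (w, visible) in self.edges.items():
            if visible:
                diff.active_edges[key] = w
        return diff


@dataclass
class FrameSequence:
    frames: List[Frame]
    frames_per_transition: int
    condition_labels: List[str]


def build_frames(
    cluster: KnowledgeNetwork,
    series: ConditionSeries,
    thresholds: Thresholds,
    frames_per_transition: int = 10,
    scale: float = 2.0,
    base_size: float = 10.0,
    significance_rule: str = "nearest",
) -> FrameSequence:
    """Interpolated frame sequence over a background cluster.

    The sequence holds ``(C-1) * frames_per_transition + 1`` frames for C
    conditions.  A node measured at both endpoints interpolates between its
    measured weights; a node measured at only one endpoint ramps from/to 0;
    unmeasured nodes never appear.  Visibility at each frame requires the
    interpolated |weight| to reach the weight cut-off and the significance
    rule (see module docstring) to hold.
    """
    if series.n_conditions < 2:
        raise ValidationError(
            "need at least two conditions to animate; use a static export "
            "for a single condition"
        )
    if frames_per_transition < 1:
        raise ValueError("frames_per_transition must be >= 1")
    if significance_rule not in ("nearest", "both"):
        raise ValueError("significance_rule must be 'nearest' or 'both'")

    node_ids = sorted(cluster.nodes)
    bg_edges = sorted(
        {(e.source_id, e.target_id) for e in cluster.edges if not e.is_self_loop()}
    )

    def sig_pass(label: str, nid: str) -> bool:
        m = series.get(label, nid)
        return m is not None and m.significance < thresholds.alpha

    frames: List[Frame] = []
    C = series.n_conditions
    for c in range(C - 1):
        lab0, lab1 = series.labels[c], series.labels[c + 1]
        steps = range(frames_per_transition)
        for j in steps:
            u = j / frames_per_transition
            t = c + u
            frame = Frame(t=t)
            for nid in node_ids:
                m0, m1 = series.get(lab0, nid), series.get(lab1, nid)
                if m0 is None and m1 is None:
                    continue
                w0 = m0.weight if m0 is not None else 0.0
                w1 = m1.weight if m1 is not None else 0.0
                w = interpolate_value(w0, w1, u)
                if significance_rule == "nearest":
                    sig_ok = sig_pass(lab1, nid) if u >= 0.5 else sig_pass(lab0, nid)
                else:
                    sig_ok = sig_pass(lab0, nid) and sig_pass(lab1, nid)
                visible = sig_ok and abs(w) >= thresholds.min_abs_weight
                frame.nodes[nid] = FrameNode(
                    weight=w,
                    size=base_size * (1.0 + abs(w) / scale),
                    colour_value=min(max(w, -scale), scale),
                    visible=visible,
                )
            for (su, sv) in bg_edges:
                fu, fv = frame.nodes.get(su), frame.nodes.get(sv)
                if fu is None or fv is None:
                    continue
                visible = fu.visible and fv.visible
                frame.edges[(su, sv)] = (edge_weight(fu.weight, fv.weight), visible)
            frames.append(frame)
    # closing frame at t = C - 1 (u = 1 of the last transition)
    final = _endpoint_frame(cluster, series, thresholds, C - 1, scale, base_size)
    frames.append(final)
    return FrameSequence(frames, frames_per_transition, list(series.labels))


def _endpoint_frame(
    cluster: KnowledgeNetwork,
    series: ConditionSeries,
    thresholds: Thresholds,
    index: int,
    scale: float,
    base_size: float,
) -> Frame:
    label = series.labels[index]
    frame = Frame(t=float(index))
    for nid in sorted(cluster.nodes):
        m = series.get(label, nid)
        prev = series.get(series.labels[index - 1], nid) if index > 0 else None
        if m is None and prev is None:
            continue
        w = m.weight if m is not None else 0.0
        sig_ok = m is not None and m.significance < thresholds.alpha
        visible = sig_ok and abs(w) >= thresholds.min_abs_weight
        frame.nodes[nid] = FrameNode(
            weight=w,
            size=base_size * (1.0 + abs(w) / scale),
            colour_value=min(max(w, -scale), scale),
            visible=visible,
        )
    for e in cluster.edges:
        if e.is_self_loop():
            continue
        key = (e.source_id, e.target_id)
        fu, fv = frame.nodes.get(key[0]), frame.nodes.get(key[1])
        if fu is None or fv is None:
            continue
        frame.edges[key] = (edge_weight(fu.weight, fv.weight), fu.visible and fv.visible)
    return frame


def differential_networks(
    cluster: KnowledgeNetwork,
    series: ConditionSeries,
    thresholds: Thresholds,
    scale: float = 2.0,
    base_size: float = 10.0,
) -> List[DifferentialNetwork]:
    """Static per-condition differential networks with visual encoding."""
    return [
        encode_visuals(
            active_subnetwork(cluster, series.measurements[lab], thresholds, lab),
            max_abs_weight_for_scale=scale,
            base_size=base_size,
        )
        for lab in series.labels
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_EDGE_STYLE = {
    "activation": dict(linestyle="solid", arrowstyle="-|>"),
    "inhibition": dict(linestyle="solid", arrowstyle="|-|,widthA=0,widthB=4"),
    "binding": dict(linestyle="dashed", arrowstyle="<|-|>"),
    "unknown": dict(linestyle="solid", arrowstyle="-"),
}


def render_static(
    frame: Frame,
    cluster: KnowledgeNetwork,
    out_path: str,
    scale: float = 2.0,
) -> None:
    """Render one frame as a deterministic SVG.

    The background cluster is drawn in grey; visible nodes are coloured on
    the red–white–blue diverging scale and sized by |weight|.  Activation
    edges are full lines with one arrowhead, inhibition full lines with a
    terminal bar, binding dashed with arrowheads at both ends.  Requires
    every cluster node to carry coordinates.
    """
    missing = [nid for nid, r in cluster.nodes.items() if not r.has_coordinates()]
    if missing:
        raise ValidationError(
            f"cannot render without coordinates for: {sorted(missing)[:5]} ..."
        )
    with plt.rc_context({"svg.hashsalt": "dinet"}):
        fig, ax = plt.subplots(figsize=(6, 6))
        pos = {nid: (r.x, r.y) for nid, r in cluster.nodes.items()}
        # background
        for e in cluster.edges:
            if e.is_self_loop():
                continue
            (x0, y0), (x1, y1) = pos[e.source_id], pos[e.target_id]
            ax.plot([x0, x1], [y0, y1], color="0.85", linewidth=0.6, zorder=1)
        bg_x = [xy[0] for xy in pos.values()]
        bg_y = [xy[1] for xy in pos.values()]
        ax.scatter(bg_x, bg_y, s=8, color="0.8", zorder=2)
        # active edges, styled by interaction type
        cmap = plt.get_cmap("RdBu_r")
        for e in sorted(cluster.edges, key=lambda e: (e.source_id, e.target_id)):
            key = (e.source_id, e.target_id)
            entry = frame.edges.get(key)
            if entry is None or not entry[1] or e.is_self_loop():
                continue
            w, _ = entry
            style = _EDGE_STYLE.get(e.interaction_type, _EDGE_STYLE["unknown"])
            arrowstyle = style["arrowstyle"] if e.directed or \
                e.interaction_type == "binding" else "-"
            patch = FancyArrowPatch(
                pos[e.source_id], pos[e.target_id],
                arrowstyle=arrowstyle, mutation_scale=8,
                linestyle=style["linestyle"],
                linewidth=0.8 + 1.6 * w, color="0.2",
                shrinkA=4, shrinkB=4, zorder=3,
            )
            ax.add_patch(patch)
        # active nodes
        for nid in sorted(frame.nodes):
            fn = frame.nodes[nid]
            if not fn.visible:
                continue
            colour = cmap(0.5 * (1.0 + fn.colour_value / scale))
            x, y = pos[nid]
            ax.scatter([x], [y], s=fn.size * 4, color=[colour],
                       edgecolors="0.2", linewidths=0.5, zorder=4)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.savefig(out_path, format="svg", metadata={"Date": None})
        plt.close(fig)


# ---------------------------------------------------------------------------
# frame serialisation
# ---------------------------------------------------------------------------

def export_frames(seq: FrameSequence, out_path: str) -> None:
    """Write a frame sequence to a self-describing tab-separated file.

    One record per element per frame: frame index, time t, element kind
    (node/edge), identifier, weight, size, colour and visibility.
    """
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("# dinet frames v1\n")
        fh.write(f"# frames_per_transition\t{seq.frames_per_transition}\n")
        fh.write("# conditions\t" + "\t".join(seq.condition_labels) + "\n")
        fh.write("frame\tt\tkind\tid\tweight\tsize\tcolour\tvisible\n")
        for i, frame in enumerate(seq.frames):
            for nid in sorted(frame.nodes):
                fn = frame.nodes[nid]
                fh.write(
                    f"{i}\t{frame.t!r}\tnode\t{nid}\t{fn.weight!r}\t"
                    f"{fn.size!r}\t{fn.colour_value!r}\t{int(fn.visible)}\n"
                )
            for (u, v) in sorted(frame.edges):
                w, vis = frame.edges[(u, v)]
                fh.write(
                    f"{i}\t{frame.t!r}\tedge\t{u}|{v}\t{w!r}\t\t\t{int(vis)}\n"
                )


def read_frames(path: str) -> FrameSequence:
    """Parse a file written by :func:`export_frames`."""
    frames: Dict[int, Frame] = {}
    fpt, labels = 1, []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# frames_per_transition"):
                fpt = int(line.split("\t")[1])
                continue
            if line.startswith("# conditions"):
                labels = line.split("\t")[1:]
                continue
            if line.startswith("#") or line.startswith("frame\t") or not line:
                continue
            parts = line.split("\t")
            idx, t, kind, ident = int(parts[0]), float(parts[1]), parts[2], parts[3]
            frame = frames.setdefault(idx, Frame(t=t))
            if kind == "node":
                frame.nodes[ident] = FrameNode(
                    weight=float(parts[4]), size=float(parts[5]),
                    colour_value=float(parts[6]), visible=bool(int(parts[7])),
                )
            else:
                u, v = ident.split("|")
                frame.edges[(u, v)] = (float(parts[4]), bool(int(parts[7])))
    ordered = [frames[i] for i in sorted(frames)]
    return FrameSequence(ordered, fpt, labels)


# ---------------------------------------------------------------------------
# settings log and replay
# ---------------------------------------------------------------------------

def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Everything needed to reproduce one overlay/animation run."""

    network_path: str
    measurements_path: str
    thresholds: Thresholds = Thresholds()
    frames_per_transition: int = 10
    scale: float = 2.0
    base_size: float = 10.0
    significance_rule: str = "nearest"
    seed: int = 0
    frames_out: str = "frames.tsv"


def run_overlay(config: RunConfig) -> str:
    """Execute the overlay pipeline described by ``config``.

    Reads the background network and the measurement series, builds the
    interpolated frame sequence and writes it to ``config.frames_out``.
    Returns the sha256 checksum of the written frames file.
    """
    from .network_io import read_expression_table, read_graphml

    net = read_graphml(config.network_path)
    series = read_expression_table(config.measurements_path)
    seq = build_frames(
        net, series, config.thresholds,
        frames_per_transition=config.frames_per_transition,
        scale=config.scale, base_size=config.base_size,
        significance_rule=config.significance_rule,
    )
    export_frames(seq, config.frames_out)
    return sha256_file(config.frames_out)


def write_settings_log(config: RunConfig, out_path: str,
                       output_checksum: Optional[str] = None) -> None:
    """Serialise a run's full parameter record as human-readable YAML."""
    log = {
        "tool": "dinet",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            "network": {
                "path": config.network_path,
                "sha256": sha256_file(config.network_path),
            },
            "measurements": {
                "path": config.measurements_path,
                "sha256": sha256_file(config.measurements_path),
            },
        },
        "parameters": {
            "alpha": config.thresholds.alpha,
            "min_abs_weight": config.thresholds.min_abs_weight,
            "min_degree": config.thresholds.min_degree,
            "frames_per_transition": config.frames_per_transition,
            "scale": config.scale,
            "base_size": config.base_size,
            "significance_rule": config.significance_rule,
            "seed": config.seed,
        },
        "outputs": {
            "frames": {
                "path": config.frames_out,
                "sha256": output_checksum,
            }
        },
    }
    with open(out_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)


@dataclass
class ReplayResult:
    checksums_match: bool
    expected: Optional[str]
    recomputed: str
    frames_path: str


def replay(log_path: str, frames_out: Optional[str] = None) -> ReplayResult:
    """Re-run the pipeline recorded in a settings log and verify outputs.

    Missing input files raise a :class:`ValidationError` listing them; a
    changed input or parameter shows up as a checksum mismatch in the
    result rather than an exception, so tampering is detectable.
    """
    with open(log_path, "r", encoding="utf-8") as fh:
        log = yaml.safe_load(fh)
    inputs = log["inputs"]
    missing = [
        entry["path"]
        for entry in (inputs["network"], inputs["measurements"])
        if not os.path.exists(entry["path"])
    ]
    if missing:
        raise ValidationError(f"settings log references missing inputs: {missing}")
    params = log["parameters"]
    frames_out = frames_out or log["outputs"]["frames"]["path"] + ".replay"
    config = RunConfig(
        network_path=inputs["network"]["path"],
        measurements_path=inputs["measurements"]["path"],
        thresholds=Thresholds(
            alpha=float(params["alpha"]),
            min_abs_weight=float(params["min_abs_weight"]),
            min_degree=int(params["min_degree"]),
        ),
        frames_per_transition=int(params["frames_per_transition"]),
        scale=float(params["scale"]),
        base_size=float(params["base_size"]),
        significance_rule=params["significance_rule"],
        seed=int(params["seed"]),
        frames_out=frames_out,
    )
    checksum = run_overlay(config)
    expected = log["outputs"]["frames"]["sha256"]
    return ReplayResult(
        checksums_match=(expected == checksum),
        expected=expected,
        recomputed=checksum,
        frames_path=frames_out,
    )
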
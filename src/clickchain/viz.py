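"""Data exports behind the navigation visualizations.

Produces the artifacts a browser-based renderer consumes rather than the
renderer itself: a probability-thresholded edge list, node-link graph
JSON (d3-style) and GraphViz DOT for the navigation graph, and a
trail-heatmap table of clustered sessions.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .clustering import ClusterModel
from .markov import TransitionModel, page_view_summary
from .sessionizer import Session, filter_sessions

__all__ = [
    "Edge",
    "EdgeList",
    "threshold_edges",
    "export_graph_json",
    "read_graph_json",
    "export_dot",
    "export_cluster_heatmap",
]


@dataclasses.dataclass(frozen=True)
class Edge:
    source: str
    target: str
    probability: float
    exception: bool = False  # retained as a max-incoming edge despite p < cutoff


@dataclasses.dataclass
class EdgeList:
    edges: list[Edge]
    cutoff: float

    def __iter__(self):
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}


def threshold_edges(
    model: TransitionModel, cutoff: float = 0.13, keep_max_incoming: bool = True
) -> EdgeList:
    """Filter the chain's edges for display.

    Keeps every edge with probability ≥ ``cutoff``.  With
    ``keep_max_incoming`` on, any non-exit page whose incoming edges all
    fall below the cutoff (so it would be visually isolated) additionally
    retains its single highest-probability incoming edge, flagged as an
    exception; ties on the maximum break by source-state order.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    states = model.states
    labels = states.labels
    P = model.P
    edges = [
        Edge(labels[i], labels[j], float(P[i, j]))
        for i in range(states.n_pages)
        for j in range(states.n_states)
        if P[i, j] >= cutoff and P[i, j] > 0.0
    ]
    if keep_max_incoming:
        retained_targets = {e.target for e in edges}
        for j, target in enumerate(labels[: states.n_pages]):
            if target in retained_targets:
                continue
            incoming = P[: states.n_pages, j]
            if (incoming <= 0.0).all():
                continue  # genuinely unreachable; nothing to rescue
            i = int(np.argmax(incoming))  # first max wins → source-order tie-break
            edges.append(Edge(labels[i], target, float(incoming[i]), exception=True))
    return EdgeList(edges=edges, cutoff=cutoff)


def export_graph_json(
    model: TransitionModel,
    edges: EdgeList,
    dest: str | Path | IO[str],
    sessions: Sequence[Session] | None = None,
) -> dict:
    """Write a d3-style node-link document for the navigation graph.

    Nodes carry the initial-distribution mass and, when sessions are
    supplied, each page's share of total page views; the exit node is
    flagged so renderers may hide it.  Probabilities are serialized at
    full precision so the paired :func:`read_graph_json` round-trips the
    edge set bit-exactly.  Returns the document.
    """
    states = model.states
    shares: dict[str, float] = {}
    if sessions:
        summary = page_view_summary(sessions)
        shares = summary["share"].to_dict()
    doc = {
        "nodes": [
            {
                "id": label,
                "label": label,
                "pi": float(model.pi[i]),
                "view_share": shares.get(label),
                "is_exit": label == states.exit_label,
            }
            for i, label in enumerate(states.labels)
        ],
        "links": [
            {
                "source": e.source,
                "target": e.target,
                "probability": e.probability,
                "exception": e.exception,
            }
            for e in edges
        ],
        "cutoff": edges.cutoff,
    }
    text = json.dumps(doc, indent=1)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
    return doc


def read_graph_json(source: str | Path | IO[str]) -> EdgeList:
    """Read back the edge list from a node-link document."""
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    doc = json.loads(text)
    return EdgeList(
        edges=[
            Edge(l["source"], l["target"], l["probability"], l["exception"])
            for l in doc["links"]
        ],
        cutoff=doc["cutoff"],
    )


def export_dot(
    model: TransitionModel, edges: EdgeList, dest: str | Path | IO[str]
) -> str:
    """Write the thresholded graph as GraphViz DOT with probability labels."""
    lines = ["digraph navigation {"]
    for label in model.states.labels:
        shape = "doublecircle" if label == model.states.exit_label else "ellipse"
        lines.append(f'  "{label}" [shape={shape}];')
    for e in edges:
        style = ", style=dashed" if e.exception else ""
        lines.append(
            f'  "{e.source}" -> "{e.target}" [label="{e.probability:.2f}"{style}];'
        )
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
    return text


def export_cluster_heatmap(
    model: ClusterModel,
    sessions: Sequence[Session] | Sequence[Sequence[str]],
    dest: str | Path | IO[str],
    min_len: int = 2,
    max_len: int = 20,
) -> list[list[str]]:
    """Write the clustered-trails table behind the session heatmap.

    One row per session with trail length in ``[min_len, max_len]``:
    first column the cluster id, then the trail's page labels in order.
    Rows are grouped by cluster and sorted by trail length within each
    cluster.  Written as CSV (ragged rows padded with empty cells);
    returns the unpadded rows.
    """
    trails = [list(s.trail) if isinstance(s, Session) else list(s) for s in sessions]
    keep = [
        (int(k), t)
        for k, t in zip(model.assignments, trails)
        if min_len <= len(t) <= max_len
    ]
    keep.sort(key=lambda kt: (kt[0], len(kt[1])))
    rows = [[str(k)] + t for k, t in keep]
    width = max((len(r) for r in rows), default=1)
    out = dest if hasattr(dest, "write") else open(dest, "w", newline="")
    try:
        writer = csv.writer(out)
        writer.writerow(["cluster"] + [f"action_{i}" for i in range(1, width)])
        for r in rows:
            writer.writerow(r + [""] * (width - len(r)))
    finally:
        if out is not dest:
            out.close()
    return rows
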
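"""Assembly-graph topology triage.

Connected components of the segment adjacency (orientation ignored) are
classified into the three contig classes used to route assemblies downstream:

* ``circular`` — a single segment closed onto itself by a self-link with
  matching orientation signs; a complete replicon.
* ``tangled`` — a component whose undirected link structure contains a cycle;
  typically several co-assembled strains of one species sharing segments.
  These are exported per component for independent reassembly.
* ``linear`` — an acyclic component (including isolated segments); an
  incomplete assembly destined for binning.

A lone segment whose only self-link has mismatched signs ((+,-)) closes the
sequence onto its reverse complement, not into a circle, and is called
linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import AssemblyGraph, SequenceRecord, write_fasta

CLASSES = ("circular", "tangled", "linear")


@dataclass(frozen=True)
class ComponentCall:
    component_id: str
    segment_ids: tuple[str, ...]
    topology: str
    total_length: int
    mean_depth: float

    @property
    def n_segments(self) -> int:
        return len(self.segment_ids)


def _component_graph(graph: AssemblyGraph) -> nx.MultiGraph:
    g = nx.MultiGraph()
    g.add_nodes_from(graph.segments)
    # reverse-complement restatements of the same join collapse to one edge
    for key in {ln.canonical() for ln in graph.links}:
        from_id, from_orient, to_id, to_orient = key
        g.add_edge(from_id, to_id, orients=(from_orient, to_orient))
    return g


def classify_components(graph: AssemblyGraph) -> list[ComponentCall]:
    """Classify every connected component into circular / tangled / linear."""
    graph.validate()
    g = _component_graph(graph)
    calls: list[ComponentCall] = []
    for nodes in nx.connected_components(g):
        members = sorted(nodes)
        sub = g.subgraph(members)
        n_edges = sub.number_of_edges()
        if len(members) == 1:
            sid = members[0]
            self_matching = any(
                d["orients"][0] == d["orients"][1] for _u, _v, d in sub.edges(data=True)
            )
            topology = "circular" if self_matching else "linear"
        else:
            # a connected multigraph has a cycle iff edges exceed a tree's
            has_cycle = n_edges > len(members) - 1
            topology = "tangled" if has_cycle else "linear"
        total_length = sum(graph.segments[s].length for s in members)
        weighted = sum(graph.segments[s].length * graph.segments[s].depth for s in members)
        mean_depth = weighted / total_length if total_length else 0.0
        calls.append(
            ComponentCall(
                component_id=members[0],
                segment_ids=tuple(members),
                topology=topology,
                total_length=total_length,
                mean_depth=mean_depth,
            )
        )
    calls.sort(key=lambda c: c.component_id)
    return calls


def depth_table(graph: AssemblyGraph) -> pd.DataFrame:
    """Per-segment (id, length, depth), longest first."""
    rows = [
        {"segment_id": s.id, "length": s.length, "depth": s.depth}
        for s in graph.segments.values()
    ]
    df = pd.DataFrame(rows, columns=["segment_id", "length", "depth"])
    if len(df) and (df["depth"] == 0).all():
        logging.getLogger("magcurate").warning(
            "depth_table: no depth tags present; depth column is all zero"
        )
    return df.sort_values(
        ["length", "segment_id"], ascending=[False, True], ignore_index=True
    )


def components_table(calls: list[ComponentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component_id": c.component_id,
                "class": c.topology,
                "n_segments": c.n_segments,
                "total_length": c.total_length,
                "mean_depth": c.mean_depth,
            }
            for c in calls
        ],
        columns=["component_id", "class", "n_segments", "total_length", "mean_depth"],
    )


def export_by_class(
    graph: AssemblyGraph, calls: list[ComponentCall], out_dir: str | Path
) -> dict[str, Path]:
    """Write per-class FASTA files; tangled components additionally get one
    FASTA each as reassembly input."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def record(sid: str) -> SequenceRecord:
        seg = graph.segments[sid]
        if seg.sequence is None:
            raise ValueError(f"segment {sid!r} has no sequence to export")
        return SequenceRecord(sid, seg.sequence)

    paths: dict[str, Path] = {}
    for topology in CLASSES:
        members = [c for c in calls if c.topology == topology]
        records = [record(s) for c in members for s in c.segment_ids]
        if records:
            path = out_dir / f"{topology}.fasta"
            write_fasta(records, path)
            paths[topology] = path
    for call in calls:
        if call.topology == "tangled":
            path = out_dir / f"tangled.{call.component_id}.fasta"
            write_fasta([record(s) for s in call.segment_ids], path)
            paths[f"tangled.{call.component_id}"] = path
    return paths
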
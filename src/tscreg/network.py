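"""TF -> target regulatory network and its core regulatory motifs.

The network has one directed edge per (factor, assigned target gene) pair,
deduplicated.  Three motifs characteristic of core regulatory circuitry
are counted over the assayed-TF subset:

* autoregulation — a TF binding its own gene (self-edge);
* interconnectivity — an unordered TF pair with edges both ways;
* feed-forward loops — ordered triples (A, B, C) with A, B assayed TFs,
  C any node, A != B != C != A, and edges A->B, A->C, B->C.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .annotation import TargetAssignment

__all__ = ["RegNetwork", "MotifCounts", "build_network", "count_motifs", "write_network"]


@dataclass
class RegNetwork:
    graph: nx.DiGraph
    tf_set: frozenset[str]

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


@dataclass(frozen=True)
class MotifCounts:
    autoregulation: int
    feedforward: int
    interconnected_pairs: int


def build_network(
    assignments_per_tf: Mapping[str, Iterable[TargetAssignment]],
    tf_symbols: Mapping[str, str] | None = None,
    motif_tfs: Iterable[str] | None = None,
) -> RegNetwork:
    """Build the TF->target digraph from per-factor target assignments.

    ``tf_symbols`` maps a factor label to the gene symbol of its own gene
    (identity by default); a self-edge arises when a factor targets its own
    symbol.  Duplicate (TF, gene) pairs collapse to one edge.  By default
    every assayed factor belongs to the motif-counting TF set; pass
    ``motif_tfs`` to restrict it (e.g. to keep a cofactor such as EP300 in
    the graph but out of the regulatory-motif definitions).
    """
    if tf_symbols is None:
        tf_symbols = {f: f for f in assignments_per_tf}
    missing = set(assignments_per_tf) - set(tf_symbols)
    if missing:
        raise ValueError(f"no gene symbol mapping for factor(s): {sorted(missing)}")
    g = nx.DiGraph()
    if motif_tfs is None:
        tf_set = frozenset(tf_symbols[f] for f in assignments_per_tf)
    else:
        tf_set = frozenset(motif_tfs)
    g.add_nodes_from(tf_set)
    for factor, assignments in assignments_per_tf.items():
        src = tf_symbols[factor]
        for a in assignments:
            g.add_edge(src, a.gene)
    return RegNetwork(graph=g, tf_set=tf_set)


def count_motifs(net: RegNetwork) -> MotifCounts:
    """Count autoregulation, feed-forward loops and interconnected TF pairs."""
    g = net.graph
    tfs = sorted(net.tf_set & set(g.nodes))
    auto = sum(1 for t in tfs if g.has_edge(t, t))
    inter = sum(
        1
        for i, a in enumerate(tfs)
        for b in tfs[i + 1 :]
        if g.has_edge(a, b) and g.has_edge(b, a)
    )
    ffl = 0
    for a, b in permutations(tfs, 2):
        if not g.has_edge(a, b):
            continue
        # C ranges over common successors of A and B, excluding A and B
        succ_a = set(g.successors(a))
        succ_b = set(g.successors(b))
        ffl += len((succ_a & succ_b) - {a, b})
    return MotifCounts(autoregulation=auto, feedforward=ffl, interconnected_pairs=inter)


def write_network(net: RegNetwork, edges_path: str | Path, sif_path: str | Path | None = None) -> None:
    """Export the edge list as TSV and optionally as Cytoscape SIF."""
    edges = sorted(net.graph.edges)
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in edges:
            fh.write(f"{s}\t{t}\n")
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for s, t in edges:
                fh.write(f"{s}\tregulates\t{t}\n")


def write_motifs(counts: MotifCounts, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(counts), indent=2) + "\n")
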
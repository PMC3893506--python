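"""Core-node selection on merged pathway graphs.

Significant pathways' directed edge lists are merged into one graph and
each node is scored by relative betweenness centrality: the fraction of
all-pairs shortest paths passing through it (endpoints excluded,
fractional credit over equal-length paths), normalized by (n-1)(n-2) for
a directed graph on n nodes.  Nodes above a cutoff, optionally
intersected with the called microRNA targets, are the core genes.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = [
    "graph_from_edges",
    "merge_graphs",
    "relative_betweenness",
    "select_core_nodes",
]

logger = logging.getLogger(__name__)


def graph_from_edges(edges: pd.DataFrame, pathway_id: str | None = None) -> nx.DiGraph:
    """Build a directed graph from an edge-list table.

    Expects columns source, target, edge_type (and optionally pathway_id,
    used to filter when ``pathway_id`` is given).  Self-loops are dropped
    and duplicate edges collapsed (first edge_type wins).
    """
    if pathway_id is not None and "pathway_id" in edges.columns:
        edges = edges[edges["pathway_id"] == pathway_id]
    g = nx.DiGraph()
    if pathway_id is not None:
        g.graph["pathway_id"] = pathway_id
    for row in edges.itertuples(index=False):
        s, t = str(row.source), str(row.target)
        if s == t:
            continue
        if not g.has_edge(s, t):
            g.add_edge(s, t, edge_type=getattr(row, "edge_type", ""))
    return g


def merge_graphs(graphs: Iterable[nx.DiGraph]) -> nx.DiGraph:
    """Node and edge union with deduplication.

    On an edge_type conflict for the same (source, target) edge the first
    occurrence wins; conflicts are logged.
    """
    merged = nx.DiGraph()
    for g in graphs:
        merged.add_nodes_from(g.nodes)
        for s, t, data in g.edges(data=True):
            if s == t:
                continue
            if merged.has_edge(s, t):
                old = merged.edges[s, t].get("edge_type")
                new = data.get("edge_type")
                if old != new:
                    logger.info(
                        "edge (%s, %s): keeping edge_type %r over %r", s, t, old, new
                    )
            else:
                merged.add_edge(s, t, **data)
    return merged


def relative_betweenness(graph: nx.DiGraph) -> pd.Series:
    """Relative betweenness centrality per node, in [0, 1].

    Endpoints are excluded and shortest-path ties share credit; directed
    normalization divides by (n-1)(n-2).  Graphs with fewer than 3 nodes
    score all zeros (no node can be interior to a path).
    """
    nodes = list(graph.nodes)
    if len(nodes) < 3:
        values = {v: 0.0 for v in nodes}
    else:
        values = nx.betweenness_centrality(graph, normalized=True)
    s = pd.Series(values, dtype=float, name="centrality")
    s.index.name = "node"
    return s.sort_index()


def select_core_nodes(
    table: pd.Series,
    cut: float = 0.01,
    targets: Iterable[str] | None = None,
) -> set[str]:
    """Nodes with centrality strictly above ``cut``.

    When ``targets`` is given (the called microRNA targets), the result is
    intersected with it, yielding the core microRNA targets.
    """
    core = {str(node) for node, value in table.items() if value > cut}
    if targets is not None:
        core &= {str(t) for t in targets}
    return core
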
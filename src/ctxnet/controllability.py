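"""Structural controllability of a directed network.

A directed network is structurally controllable from a minimum set of driver
nodes of size N_D = max(N - |M|, 1), where M is a maximum matching in the
bipartite representation of the graph (every node split into an out-copy and
an in-copy; each arc a->b becomes the bipartite edge out(a)-in(b)).  A node
matched on its in-copy is driven internally by its matched predecessor;
unmatched in-copies need external control inputs.

Nodes and edges are classified by the effect of their removal on N_D:
indispensable if N_D increases, dispensable if it decreases, neutral
otherwise.  Deleting a single edge can never enlarge the matching, so the
dispensable edge class is structurally empty; it is computed regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

__all__ = [
    "ControllabilityReport",
    "minimum_driver_count",
    "driver_nodes",
    "classify_nodes",
    "classify_edges",
    "brute_force_driver_count",
    "analyze",
]

CLASSES = ("indispensable", "dispensable", "neutral")


@dataclass
class ControllabilityReport:
    n_driver: int
    node_class: dict[str, str]
    edge_class: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for c in self.node_class.values():
            counts[c] += 1
        return counts

    @property
    def class_percentages(self) -> dict[str, float]:
        n = len(self.node_class)
        return {c: 100.0 * k / n for c, k in self.class_counts.items()} if n else {}


def _matching_size(edges: list[tuple[int, int]], n: int) -> int:
    """Maximum matching cardinality in the bipartite out/in representation."""
    if not edges:
        return 0
    rows = np.fromiter((e[0] for e in edges), dtype=np.int32, count=len(edges))
    cols = np.fromiter((e[1] for e in edges), dtype=np.int32, count=len(edges))
    data = np.ones(len(edges), dtype=np.int8)
    bi = csr_matrix((data, (rows, cols)), shape=(n, n))
    match = maximum_bipartite_matching(bi, perm_type="column")
    return int((match >= 0).sum())


def _indexed(g: nx.DiGraph) -> tuple[list[str], dict[str, int], list[tuple[int, int]]]:
    nodes = sorted(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    return nodes, index, edges


def minimum_driver_count(g: nx.DiGraph) -> int:
    """Minimum number of driver nodes, N_D = max(N - |M|, 1)."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("controllability is undefined on an empty graph")
    _, _, edges = _indexed(g)
    return max(n - _matching_size(edges, n), 1)


def driver_nodes(g: nx.DiGraph) -> set[str]:
    """One valid minimum driver set: nodes whose in-copy is unmatched.

    When the matching is perfect any single node suffices; the
    lexicographically smallest is returned for determinism.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("controllability is undefined on an empty graph")
    nodes, _, edges = _indexed(g)
    if not edges:
        return set(nodes)
    rows = np.array([e[0] for e in edges], dtype=np.int32)
    cols = np.array([e[1] for e in edges], dtype=np.int32)
    bi = csr_matrix((np.ones(len(edges), dtype=np.int8), (rows, cols)), shape=(n, n))
    match = maximum_bipartite_matching(bi, perm_type="row")  # per in-copy
    unmatched = {nodes[i] for i in range(n) if match[i] < 0}
    return unmatched if unmatched else {nodes[0]}


def _classify(n_d_removed: int, n_d: int) -> str:
    if n_d_removed > n_d:
        return "indispensable"
    if n_d_removed < n_d:
        return "dispensable"
    return "neutral"


def classify_nodes(g: nx.DiGraph) -> dict[str, str]:
    """Per-node class from recomputing N_D on the graph without the node."""
    if g.number_of_nodes() < 2:
        raise ValueError("node classification needs at least 2 nodes")
    nodes, index, edges = _indexed(g)
    n = len(nodes)
    n_d = max(n - _matching_size(edges, n), 1)
    out: dict[str, str] = {}
    for v in nodes:
        vi = index[v]
        kept = [e for e in edges if vi not in e]
        n_d_removed = max((n - 1) - _matching_size(kept, n), 1)
        out[v] = _classify(n_d_removed, n_d)
    return out


def classify_edges(g: nx.DiGraph) -> dict[tuple[str, str], str]:
    """Per-edge class from recomputing N_D on the graph without the arc."""
    if g.number_of_edges() < 1:
        raise ValueError("edge classification needs at least 1 edge")
    nodes, index, edges = _indexed(g)
    n = len(nodes)
    n_d = max(n - _matching_size(edges, n), 1)
    out: dict[tuple[str, str], str] = {}
    for u, v in g.edges():
        e = (index[u], index[v])
        kept = [x for x in edges if x != e]
        n_d_removed = max(n - _matching_size(kept, n), 1)
        out[(u, v)] = _classify(n_d_removed, n_d)
    return out


def brute_force_driver_count(g: nx.DiGraph) -> int:
    """N_D by exhaustive search over matchings; test oracle for small graphs.

    Enumerates every subset of bipartite edges of each cardinality from
    largest to smallest and accepts the first that forms a matching
    (distinct tails, distinct heads).
    """
    if g.number_of_edges() > 20:
        raise ValueError("brute force limited to graphs with <= 20 edges")
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("controllability is undefined on an empty graph")
    edges = list(g.edges())
    best = 0
    for k in range(min(len(edges), n), 0, -1):
        for subset in combinations(edges, k):
            tails = {e[0] for e in subset}
            heads = {e[1] for e in subset}
            if len(tails) == k and len(heads) == k:
                best = k
                break
        if best:
            break
    return max(n - best, 1)


def analyze(g: nx.DiGraph, with_edges: bool = True) -> ControllabilityReport:
    """Full report: N_D, node classes, and (optionally) edge classes."""
    report = ControllabilityReport(
        n_driver=minimum_driver_count(g),
        node_class=classify_nodes(g),
    )
    if with_edges and g.number_of_edges():
        report.edge_class = classify_edges(g)
    return report
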
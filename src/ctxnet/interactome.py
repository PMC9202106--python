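"""The directed protein-protein interactome as a knowledge template.

Loading, de-duplication, per-node statistics (degree, scaled betweenness,
housekeeping membership) and the undirected edge view used when comparing
against inherently undirected co-expression networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "NodeStats",
    "read_interactome",
    "write_interactome",
    "undirected_edges",
    "node_statistics",
    "housekeeping_overlap",
]


@dataclass(frozen=True)
class NodeStats:
    node: str
    degree: int
    betweenness_scaled: float
    housekeeping: bool
    controllability_class: str = ""


def read_interactome(path: str | Path) -> nx.DiGraph:
    """Directed simple graph from a (source, target[, relation]) TSV.

    Duplicate directed edges and self-loops are dropped with a warning; a
    malformed row raises with its line number.
    """
    g = nx.DiGraph()
    n_dup = n_loop = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must have at least 2 columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            u, v = fields[0], fields[1]
            if u == v:
                n_loop += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate directed edges")
    if n_loop:
        warnings.warn(f"{path}: dropped {n_loop} self-loops")
    return g


def write_interactome(g: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\t{v}\n")


def undirected_edges(g: nx.DiGraph) -> set[tuple[str, str]]:
    """Unordered node pairs connected in either direction, each once."""
    return {(u, v) if u < v else (v, u) for u, v in g.edges()}


def node_statistics(g: nx.DiGraph, housekeeping: list[str] | set[str]) -> list[NodeStats]:
    """Degree (in+out), min-max scaled directed betweenness, housekeeping flag.

    Betweenness uses the standard shortest-path (Brandes) definition on the
    directed graph; scores are min-max scaled to [0, 1] for comparability.
    """
    hk = set(housekeeping)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    values = list(betweenness.values())
    lo, hi = (min(values), max(values)) if values else (0.0, 0.0)
    span = hi - lo
    stats = []
    for node in sorted(g.nodes()):
        scaled = (betweenness[node] - lo) / span if span > 0 else 0.0
        stats.append(
            NodeStats(
                node=node,
                degree=g.in_degree(node) + g.out_degree(node),
                betweenness_scaled=scaled,
                housekeeping=node in hk,
            )
        )
    return stats


def housekeeping_overlap(
    g: nx.DiGraph, housekeeping: list[str] | set[str]
) -> tuple[int, float]:
    """How many housekeeping genes are interactome nodes, and what fraction
    of the interactome they make up."""
    nodes = set(g.nodes())
    count = len(nodes & set(housekeeping))
    fraction = count / len(nodes) if nodes else 0.0
    return count, fraction


def node_table(stats: list[NodeStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": [s.node for s in stats],
            "degree": [s.degree for s in stats],
            "betweenness_scaled": [s.betweenness_scaled for s in stats],
            "housekeeping": [s.housekeeping for s in stats],
            "class": [s.controllability_class for s in stats],
        }
    )
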
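"""Pathway-network similarity and pathway-profile clustering of networks.

For a pathway P with m member genes, C_n is the set of all m(m-1)/2
unordered member pairs.  The pathway-network similarity of P and a
co-expression network N = (n', E_N) is

    similarity(P, N) = |{(u, v) in C_n : u, v in n' and {u, v} in E_N}| / |C_n|,

the fraction of possible member pairs realized as network edges.  The
denominator counts ALL member pairs, so pathways whose genes are absent
from a network score low rather than being dropped.  Networks are compared
to each other by hierarchical clustering of their rows in the
networks x pathways similarity matrix (Euclidean distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree

from .coexpr import CoexpressionNetwork

__all__ = [
    "PathwayGeneSet",
    "read_gmt",
    "write_gmt",
    "pathway_network_similarity",
    "similarity_matrix",
    "cluster_networks",
]


@dataclass
class PathwayGeneSet:
    pathway_id: str
    name: str
    members: set[str]


def read_gmt(path: str | Path) -> list[PathwayGeneSet]:
    """Parse a GMT file (name TAB description TAB member...).

    Duplicate members within a line are deduplicated with a warning; a line
    with fewer than three fields is an error reported with its line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, *members = fields
            unique = set(members)
            if len(unique) < len(members):
                warnings.warn(f"{path}: line {lineno}: duplicate members deduplicated")
            out.append(PathwayGeneSet(pathway_id=name, name=desc, members=unique))
    return out


def write_gmt(pathways: list[PathwayGeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.members)]) + "\n")


def pathway_network_similarity(p: PathwayGeneSet, net: CoexpressionNetwork) -> float:
    """Fraction of all unordered pathway-member pairs that are network edges."""
    members = sorted(p.members)
    m = len(members)
    if m < 2:
        raise ValueError(f"pathway {p.pathway_id!r} has fewer than 2 members")
    nodes = net.nodes
    edges = net.edge_set()
    overlap = 0
    present = [g for g in members if g in nodes]
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            if ((a, b) if a < b else (b, a)) in edges:
                overlap += 1
    return overlap / (m * (m - 1) // 2)


def similarity_matrix(
    nets: list[CoexpressionNetwork], pathways: list[PathwayGeneSet]
) -> pd.DataFrame:
    """Networks x pathways matrix of similarity scores in [0, 1].

    Pathways with fewer than two members are skipped with a warning.
    """
    if not nets:
        raise ValueError("need at least one network")
    scoreable = []
    for p in pathways:
        if len(p.members) < 2:
            warnings.warn(f"skipping pathway {p.pathway_id!r} with <2 members")
        else:
            scoreable.append(p)
    if not scoreable:
        raise ValueError("no scoreable pathways")
    data = np.zeros((len(nets), len(scoreable)))
    for i, net in enumerate(nets):
        for j, p in enumerate(scoreable):
            data[i, j] = pathway_network_similarity(p, net)
    return pd.DataFrame(
        data,
        index=[n.subcontext for n in nets],
        columns=[p.pathway_id for p in scoreable],
    )


def cluster_networks(
    m: pd.DataFrame, method: str = "average"
) -> tuple[list[str], np.ndarray, str]:
    """Agglomerative clustering of networks by their pathway profiles.

    Rows are pre-sorted by label so ties resolve deterministically.  Returns
    the leaf order, the SciPy linkage matrix (merge heights in its third
    column), and a Newick rendering of the dendrogram.
    """
    if len(m) < 2:
        raise ValueError("clustering needs at least 2 networks")
    ordered = m.sort_index()
    z = linkage(ordered.to_numpy(), method=method, metric="euclidean")
    labels = list(ordered.index)
    order = [labels[i] for i in leaves_list(z)]
    newick = _to_newick(to_tree(z), labels)
    return order, z, newick


def _to_newick(node, labels: list[str]) -> str:
    def render(n, parent_height: float) -> str:
        length = parent_height - n.dist
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        left = render(n.left, n.dist)
        right = render(n.right, n.dist)
        return f"({left},{right}):{length:.6g}"

    if node.is_leaf():
        return f"{labels[node.id]};"
    left = render(node.left, node.dist)
    right = render(node.right, node.dist)
    return f"({left},{right});"
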
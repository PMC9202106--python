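"""Signed weighted co-expression networks via topological overlap.

One network per subcontext: Pearson correlation across samples, signed
soft-threshold adjacency a_ij = ((1 + cor_ij)/2)^beta, topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

and retention of exactly the top fraction (default 1%) of unordered gene
pairs by TOM.  Fixing the retained-edge count rather than a weight cutoff
makes networks of the same gene universe directly comparable by edge counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import GeneExpressionMatrix

__all__ = [
    "CoexpressionNetwork",
    "correlation_matrix",
    "signed_adjacency",
    "topological_overlap",
    "top_edge_count",
    "select_top_edges",
    "build_network",
    "network_from_matrix",
    "write_network",
    "read_network",
]

DEFAULT_SOFT_POWER = 12.0
DEFAULT_TOP_FRACTION = 0.01


@dataclass
class CoexpressionNetwork:
    """Undirected weighted network over the retained top-TOM gene pairs.

    ``edges`` maps lexicographically ordered gene pairs to TOM weight; the
    node set is exactly the genes incident to at least one retained edge.
    """

    subcontext: str
    edges: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            if a > b:
                raise ValueError(f"edge ({a!r}, {b!r}) not lexicographically ordered")

    @property
    def nodes(self) -> set[str]:
        return {g for pair in self.edges for g in pair}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return (a, b) in self.edges if a < b else (b, a) in self.edges

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)


def correlation_matrix(m: GeneExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Gene-gene Pearson correlation across samples.

    Zero-variance genes are dropped with a warning (their correlation is
    undefined).  Returns the matrix and the retained gene ids; the diagonal
    is exactly 1.
    """
    if m.values.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    variances = m.values.var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance genes: {dropped[:5]}")
    values = m.values[keep]
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    cor = np.atleast_2d(np.corrcoef(values))
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return cor, genes


def signed_adjacency(cor: np.ndarray, beta: float = DEFAULT_SOFT_POWER) -> np.ndarray:
    """a_ij = ((1 + cor_ij) / 2)^beta off-diagonal, 1 on the diagonal.

    The signed transform maps correlation -1 to adjacency 0 and +1 to 1, so
    strong negative correlations do not masquerade as connections.
    """
    if beta <= 0:
        raise ValueError(f"soft power must be positive, got {beta!r}")
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a [0,1] symmetric adjacency.

    Shared-neighbour weight l_ij excludes both endpoints and connectivity
    k_i excludes the diagonal; the diagonal of the result is set to 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    l = off @ off  # l[i, j] = sum_u a_iu a_uj over u != i, j (diagonal zeroed)
    k = off.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + off) / (kmin + 1.0 - off)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def top_edge_count(n_genes: int, fraction: float = DEFAULT_TOP_FRACTION) -> int:
    """Number of retained pairs: round-to-nearest of fraction * n(n-1)/2.

    Half-way cases round up, so the count is platform-determined and
    identical for every subcontext on the same gene universe.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction!r}")
    n_pairs = n_genes * (n_genes - 1) // 2
    return int(np.floor(fraction * n_pairs + 0.5))


def select_top_edges(
    tom: np.ndarray,
    genes: list[str],
    fraction: float = DEFAULT_TOP_FRACTION,
) -> list[tuple[str, str, float]]:
    """The top-fraction unordered pairs by TOM, sorted by weight descending.

    Ties at the cutoff break by lexicographic gene-pair order, so the
    selection is bit-reproducible.
    """
    n = len(genes)
    n_keep = top_edge_count(n, fraction)
    iu, ju = np.triu_indices(n, k=1)
    weights = tom[iu, ju]
    # order: weight descending, then lexicographic pair ascending
    pair_names = [(genes[i], genes[j]) if genes[i] < genes[j] else (genes[j], genes[i])
                  for i, j in zip(iu, ju)]
    order = sorted(range(len(weights)), key=lambda t: (-weights[t], pair_names[t]))
    return [(pair_names[t][0], pair_names[t][1], float(weights[t])) for t in order[:n_keep]]


def build_network(
    edges: list[tuple[str, str, float]], subcontext: str
) -> CoexpressionNetwork:
    """Assemble a network from weighted pairs; nodes are the edge endpoints."""
    if not edges:
        raise ValueError("cannot build a network from an empty edge list")
    edge_map: dict[tuple[str, str], float] = {}
    for a, b, w in edges:
        key = (a, b) if a < b else (b, a)
        edge_map[key] = float(w)
    return CoexpressionNetwork(subcontext=subcontext, edges=edge_map)


def network_from_matrix(
    m: GeneExpressionMatrix,
    beta: float = DEFAULT_SOFT_POWER,
    fraction: float = DEFAULT_TOP_FRACTION,
) -> CoexpressionNetwork:
    """Full construction: correlation -> signed adjacency -> TOM -> top edges."""
    cor, genes = correlation_matrix(m)
    adj = signed_adjacency(cor, beta)
    tom = topological_overlap(adj)
    edges = select_top_edges(tom, genes, fraction)
    return build_network(edges, m.subcontext)


def write_network(net: CoexpressionNetwork, path: str | Path, **sidecar) -> None:
    """Edge-list TSV (gene_a < gene_b) plus a JSON sidecar of summary stats."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for (a, b), w in sorted(net.edges.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
    meta = {
        "subcontext": net.subcontext,
        "n_nodes": len(net.nodes),
        "n_edges": net.n_edges,
        **sidecar,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_network(path: str | Path, subcontext: str = "") -> CoexpressionNetwork:
    edges: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError(f"unexpected header in {path}: {header!r}")
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")
            key = (a, b) if a < b else (b, a)
            edges[key] = float(w)
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    if not subcontext and sidecar.exists():
        with open(sidecar) as fh:
            subcontext = json.load(fh).get("subcontext", "")
    return CoexpressionNetwork(subcontext=subcontext, edges=edges)
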
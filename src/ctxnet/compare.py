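"""Network-level comparisons and degree-preserving permutation nulls.

Edge overlap between co-expression networks is directly comparable because
every network of a run retains the same number of edges; overlap with the
interactome ignores edge direction.  Significance of the interactome
overlap is assessed against XSwap permutations of the co-expression
network: repeated two-edge endpoint exchanges that preserve every node's
degree exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .coexpr import CoexpressionNetwork
from .interactome import undirected_edges

__all__ = [
    "EdgeFrequencyTable",
    "PermutationResult",
    "pairwise_edge_overlap",
    "edge_frequency",
    "node_commonality",
    "interactome_edge_overlap",
    "xswap",
    "permutation_overlap_test",
    "common_protein_degree_overlap",
]

TIERS = (0.25, 0.50, 0.75)


@dataclass
class EdgeFrequencyTable:
    """How often each unordered gene pair occurs across a context's networks."""

    counts: dict[tuple[str, str], int]
    context_size: int
    tier_counts: dict[float, int] = field(default_factory=dict)
    tier_fractions: dict[float, float] = field(default_factory=dict)
    n_unique: int = 0
    unique_fraction: float = 0.0


@dataclass
class PermutationResult:
    observed: int
    permuted: list[int]
    fold_ratio: float
    empirical_p: float
    seed: int
    degenerate: bool = False


def pairwise_edge_overlap(a: CoexpressionNetwork, b: CoexpressionNetwork) -> int:
    """Number of unordered gene pairs present as edges in both networks."""
    return len(a.edge_set() & b.edge_set())


def edge_frequency(nets: list[CoexpressionNetwork]) -> EdgeFrequencyTable:
    """Edge occurrence counts and commonality tiers over a context.

    Tier thresholds are >= ceil(tier * context size) networks; fractions are
    over the union of all edges observed in the context.
    """
    if len(nets) < 2:
        raise ValueError("edge frequency needs at least 2 networks")
    counts: dict[tuple[str, str], int] = {}
    for net in nets:
        for pair in net.edges:
            counts[pair] = counts.get(pair, 0) + 1
    size = len(nets)
    total = len(counts)
    table = EdgeFrequencyTable(counts=counts, context_size=size)
    table.n_unique = sum(1 for c in counts.values() if c <= 1)
    table.unique_fraction = table.n_unique / total if total else 0.0
    for tier in TIERS:
        threshold = math.ceil(tier * size)
        k = sum(1 for c in counts.values() if c >= threshold)
        table.tier_counts[tier] = k
        table.tier_fractions[tier] = k / total if total else 0.0
    return table


def node_commonality(nets: list[CoexpressionNetwork]) -> tuple[set[str], set[str]]:
    """Genes present in every network, and genes present in exactly one."""
    if len(nets) < 2:
        raise ValueError("node commonality needs at least 2 networks")
    membership: dict[str, int] = {}
    for net in nets:
        for g in net.nodes:
            membership[g] = membership.get(g, 0) + 1
    in_all = {g for g, c in membership.items() if c == len(nets)}
    in_one = {g for g, c in membership.items() if c == 1}
    return in_all, in_one


def node_membership_counts(nets: list[CoexpressionNetwork]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for net in nets:
        for g in net.nodes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def interactome_edge_overlap(net: CoexpressionNetwork, g: nx.DiGraph) -> int:
    """Shared unordered pairs between the network and the interactome."""
    return len(net.edge_set() & undirected_edges(g))


def xswap(
    net: CoexpressionNetwork, n_swap_multiplier: int = 10, seed: int | None = None
) -> CoexpressionNetwork:
    """Degree-preserving permutation by repeated two-edge endpoint exchange.

    Each attempt picks two distinct edges {a,b}, {c,d} (endpoint order
    randomized) and proposes {a,d}, {c,b}; proposals creating self-loops or
    duplicate edges are rejected.  The attempt budget is
    ``n_swap_multiplier * |edges|``.  Every node's degree and the edge count
    are preserved exactly.  A swap-locked network (e.g. a triangle) comes
    back unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    edges = [list(pair) for pair in net.edges]
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("xswap needs at least 2 edges")
    present = {tuple(sorted(e)) for e in edges}
    attempts = n_swap_multiplier * n_edges
    n_swapped = 0
    idx = rng.integers(0, n_edges, size=2 * attempts)
    flips = rng.random(size=2 * attempts) < 0.5
    for t in range(attempts):
        i, j = idx[2 * t], idx[2 * t + 1]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flips[2 * t]:
            a, b = b, a
        if flips[2 * t + 1]:
            c, d = d, c
        # propose {a, d}, {c, b}
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        old1 = tuple(sorted(edges[i]))
        old2 = tuple(sorted(edges[j]))
        if new1 in present or new2 in present or new1 == new2:
            continue
        present.discard(old1)
        present.discard(old2)
        present.add(new1)
        present.add(new2)
        edges[i] = [a, d]
        edges[j] = [c, b]
        n_swapped += 1
    if n_swapped == 0:
        warnings.warn("xswap could not perform any swap; returning the input network")
    new_edges = {tuple(sorted(e)): 1.0 for e in edges}
    out = CoexpressionNetwork(subcontext=net.subcontext, edges=new_edges)
    assert out.n_edges == net.n_edges
    assert out.degree() == net.degree()
    return out


def permutation_overlap_test(
    net: CoexpressionNetwork,
    g: nx.DiGraph,
    n_perm: int = 1000,
    seed: int | None = None,
    n_swap_multiplier: int = 10,
) -> PermutationResult:
    """Observed interactome overlap against XSwap-permuted networks.

    fold_ratio = observed / mean(permuted overlaps); the empirical p-value
    uses the permutation-inclusive add-one estimator
    (1 + #{permuted >= observed}) / (n_perm + 1).  A degenerate null (mean
    permuted overlap zero) reports fold_ratio 0 with a flag.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = interactome_edge_overlap(net, g)
    permuted = []
    for _ in range(n_perm):
        permuted_net = xswap(net, n_swap_multiplier=n_swap_multiplier,
                             seed=int(rng.integers(0, 2**31)))
        permuted.append(interactome_edge_overlap(permuted_net, g))
    mean_perm = float(np.mean(permuted))
    degenerate = mean_perm == 0.0
    fold = 0.0 if degenerate else observed / mean_perm
    p = (1 + sum(1 for x in permuted if x >= observed)) / (n_perm + 1)
    return PermutationResult(
        observed=observed,
        permuted=permuted,
        fold_ratio=fold,
        empirical_p=p,
        seed=seed if seed is not None else -1,
        degenerate=degenerate,
    )


def common_protein_degree_overlap(
    nets: list[CoexpressionNetwork],
    g: nx.DiGraph,
    housekeeping: set[str] | list[str] = (),
    node_classes: dict[str, str] | None = None,
    k: int = 400,
    end: str = "most",
) -> dict[str, dict]:
    """Overlap of the k most/least common network proteins with the k
    highest/lowest-degree interactome nodes.

    Genes are ranked by the number of networks they occur in (ties by gene
    id); interactome nodes by total degree (ties by node id).  Members of
    the overlap are annotated with housekeeping membership and, when
    provided, controllability class.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if end not in ("most", "least"):
        raise ValueError("end must be 'most' or 'least'")
    counts = node_membership_counts(nets)
    if k > len(counts):
        warnings.warn(f"k={k} exceeds {len(counts)} available genes; truncating")
        k_genes = len(counts)
    else:
        k_genes = k
    reverse = end == "most"
    ranked_genes = sorted(counts, key=lambda g_: (-counts[g_] if reverse else counts[g_], g_))
    top_genes = set(ranked_genes[:k_genes])

    degree = {v: g.in_degree(v) + g.out_degree(v) for v in g.nodes()}
    k_nodes = min(k, len(degree))
    ranked_nodes = sorted(degree, key=lambda v: (-degree[v] if reverse else degree[v], v))
    top_nodes = set(ranked_nodes[:k_nodes])

    hk = set(housekeeping)
    overlap = sorted(top_genes & top_nodes)
    return {
        gene: {
            "housekeeping": gene in hk,
            "class": (node_classes or {}).get(gene, ""),
            "network_count": counts[gene],
            "interactome_degree": degree[gene],
        }
        for gene in overlap
    }
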
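import networkx as nx
import numpy as np
import pytest

from ctxnet.coexpr import CoexpressionNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_digraph(rng, n_nodes=5, p=0.4) -> nx.DiGraph:
    """Random simple digraph on letter-labelled nodes."""
    nodes = [chr(ord("a") + i) for i in range(n_nodes)]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p:
                g.add_edge(u, v)
    return g


def random_network(rng, n_genes=30, n_edges=60, subcontext="sc") -> CoexpressionNetwork:
    """Random undirected network over a toy gene universe."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    pairs = [(genes[i], genes[j]) for i in range(n_genes) for j in range(i + 1, n_genes)]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    edges = {pairs[i]: float(rng.random()) for i in idx}
    return CoexpressionNetwork(subcontext=subcontext, edges=edges)
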
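"""End-to-end orchestration: simulate/load -> preprocess -> networks ->
comparisons -> controllability -> pathways -> summary report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import compare, controllability, coexpr, interactome as itm, pathways as pw
from .preprocess import (
    SampleMetadata,
    filter_samples,
    preprocess_subcontext,
    read_expression_tsv,
    read_metadata_tsv,
    read_probe_map,
)
from .simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_housekeeping,
    simulate_interactome,
    simulate_pathways,
    write_simulation,
)

logger = logging.getLogger("ctxnet")

__all__ = ["PipelineConfig", "run_pipeline", "report"]

_STAGE_OFFSETS = {"simulate": 1, "interactome": 2, "pathways": 3, "permutation": 4}


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed from the single global seed (documented derivation)."""
    return (seed * 1_000_003 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str = "ctxnet_out"
    data_dir: str | None = None           # None -> simulate
    interactome_path: str | None = None
    pathways_path: str | None = None
    housekeeping_path: str | None = None
    beta: float = coexpr.DEFAULT_SOFT_POWER
    top_fraction: float = coexpr.DEFAULT_TOP_FRACTION
    n_perm: int = 1000
    k_common: int = 400
    linkage: str = "average"
    seed: int = 0
    classify_edges: bool = True
    simulation: SimulationConfig | None = None
    sim_interactome_nodes: int = 800
    sim_interactome_edges: int = 4000
    sim_n_pathways: int = 30
    sim_pathway_sizes: tuple[int, int] = (8, 12)
    sim_planted_fraction: float = 0.4
    render: bool = False


def _load_or_simulate(config: PipelineConfig, out: Path):
    """Returns (datasets keyed by id, metadata rows, probe map, interactome,
    pathway sets, housekeeping list, planted truth or None)."""
    if config.data_dir is None:
        sim = config.simulation or SimulationConfig(seed=derive_seed(config.seed, "simulate"))
        logger.info("simulate: seed=%d config=%s", sim.seed, sim)
        datasets, planted = simulate_expression(sim)
        graph = simulate_interactome(
            config.sim_interactome_nodes,
            config.sim_interactome_edges,
            derive_seed(config.seed, "interactome"),
        )
        # the simulated interactome lives (partly) on the gene universe so
        # overlap analyses are non-trivial; the gene-to-protein assignment is
        # random so interactome topology stays independent of planted modules
        relabel_rng = np.random.default_rng(derive_seed(config.seed, "interactome"))
        protein_ids = relabel_rng.permutation(sorted(graph.nodes()))
        gene_ids = relabel_rng.permutation(planted.gene_ids)
        relabel = dict(zip(protein_ids, gene_ids))
        graph = nx.relabel_nodes(graph, relabel)
        pathway_sets = simulate_pathways(
            planted,
            config.sim_n_pathways,
            config.sim_pathway_sizes,
            config.sim_planted_fraction,
            derive_seed(config.seed, "pathways"),
        )
        housekeeping = simulate_housekeeping(planted)
        data_dir = out / "data"
        write_simulation(data_dir, datasets, planted, graph, pathway_sets)
        metadata = [row for _, rows in datasets for row in rows]
        matrices = {rows[0].dataset_id: m for m, rows in datasets}
        probe_map = read_probe_map(data_dir / "probe_map.tsv")
        return matrices, metadata, probe_map, graph, pathway_sets, housekeeping, planted

    data_dir = Path(config.data_dir)
    metadata = read_metadata_tsv(data_dir / "metadata.tsv")
    matrices = {}
    for ds in sorted({m.dataset_id for m in metadata}):
        matrices[ds] = read_expression_tsv(data_dir / f"{ds}.expression.tsv")
    probe_map = read_probe_map(data_dir / "probe_map.tsv")
    graph = itm.read_interactome(config.interactome_path or data_dir / "interactome.tsv")
    pathway_sets = pw.read_gmt(config.pathways_path or data_dir / "pathways.gmt")
    hk_path = Path(config.housekeeping_path or data_dir / "housekeeping.txt")
    housekeeping = [l.strip() for l in open(hk_path) if l.strip()]
    return matrices, metadata, probe_map, graph, pathway_sets, housekeeping, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts; returns the summary bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (matrices, metadata, probe_map, graph, pathway_sets,
     housekeeping, planted) = _load_or_simulate(config, out)

    usable = filter_samples(metadata)
    by_subcontext: dict[str, list[str]] = {}
    samples_of_dataset: dict[str, list[str]] = {}
    for row in usable:
        samples_of_dataset.setdefault(row.dataset_id, []).append(row.sample_id)
        if row.dataset_id not in by_subcontext.setdefault(row.subcontext, []):
            by_subcontext[row.subcontext].append(row.dataset_id)

    networks = []
    summary_networks = {}
    for subcontext in sorted(by_subcontext):
        parts = []
        for ds in by_subcontext[subcontext]:
            m = matrices[ds]
            keep = [s for s in m.sample_ids if s in set(samples_of_dataset[ds])]
            cols = [m.sample_ids.index(s) for s in keep]
            trimmed = type(m)(m.values[:, cols], list(m.probe_ids), keep)
            parts.append((trimmed, ds))
        logger.info("preprocess: subcontext=%s datasets=%d", subcontext, len(parts))
        merged = preprocess_subcontext(parts, probe_map, subcontext)
        net = coexpr.network_from_matrix(merged, beta=config.beta, fraction=config.top_fraction)
        coexpr.write_network(
            net, out / f"network_{subcontext}.tsv",
            beta=config.beta, fraction=config.top_fraction,
        )
        networks.append(net)
        summary_networks[subcontext] = {
            "n_nodes": len(net.nodes),
            "n_edges": net.n_edges,
            "n_samples": len(merged.sample_ids),
            "n_datasets": len(parts),
        }

    # network size vs sample count (bias check)
    sizes = np.array([v["n_nodes"] for v in summary_networks.values()], dtype=float)
    counts = np.array([v["n_samples"] for v in summary_networks.values()], dtype=float)
    if len(sizes) >= 2 and sizes.std() > 0 and counts.std() > 0:
        size_sample_r = float(np.corrcoef(counts, sizes)[0, 1])
    else:
        size_sample_r = None  # undefined when either quantity is constant

    # pairwise overlaps
    labels = [n.subcontext for n in networks]
    overlap = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for a in networks:
        for b in networks:
            overlap.loc[a.subcontext, b.subcontext] = compare.pairwise_edge_overlap(a, b)
    overlap.to_csv(out / "pairwise_edge_overlap.tsv", sep="\t")

    freq = compare.edge_frequency(networks) if len(networks) >= 2 else None
    commonality = compare.node_commonality(networks) if len(networks) >= 2 else (set(), set())

    perm_rng = np.random.default_rng(derive_seed(config.seed, "permutation"))
    permutation = {}
    for net in networks:
        res = compare.permutation_overlap_test(
            net, graph, n_perm=config.n_perm, seed=int(perm_rng.integers(0, 2**31))
        )
        permutation[net.subcontext] = {
            "observed": res.observed,
            "mean_permuted": float(np.mean(res.permuted)),
            "fold_ratio": res.fold_ratio,
            "empirical_p": res.empirical_p,
            "degenerate": res.degenerate,
        }
    with open(out / "permutation_overlap.json", "w") as fh:
        json.dump(permutation, fh, indent=1)

    logger.info("controllability: nodes=%d edges=%d",
                graph.number_of_nodes(), graph.number_of_edges())
    ctrl = controllability.analyze(graph, with_edges=config.classify_edges)
    stats = itm.node_statistics(graph, housekeeping)
    table = itm.node_table(stats)
    table["class"] = table["node"].map(ctrl.node_class)
    table.to_csv(out / "interactome_nodes.tsv", sep="\t", index=False)
    hk_count, hk_fraction = itm.housekeeping_overlap(graph, housekeeping)

    common = compare.common_protein_degree_overlap(
        networks, graph, housekeeping, ctrl.node_class,
        k=min(config.k_common, len({g for n in networks for g in n.nodes})),
        end="most",
    ) if networks else {}

    sim_matrix = pw.similarity_matrix(networks, pathway_sets)
    sim_matrix.to_csv(out / "pathway_similarity.tsv", sep="\t")
    if len(sim_matrix) >= 2:
        order, _, newick = pw.cluster_networks(sim_matrix, method=config.linkage)
        (out / "network_dendrogram.nwk").write_text(newick + "\n")
    else:
        order = list(sim_matrix.index)

    edge_classes = {}
    if ctrl.edge_class:
        counter: dict[str, int] = {c: 0 for c in controllability.CLASSES}
        for c in ctrl.edge_class.values():
            counter[c] += 1
        edge_classes = counter

    bundle = {
        "seed": config.seed,
        "parameters": {
            "beta": config.beta,
            "top_fraction": config.top_fraction,
            "n_perm": config.n_perm,
            "k_common": config.k_common,
            "linkage": config.linkage,
        },
        "networks": summary_networks,
        "size_sample_correlation": size_sample_r,
        "pairwise_edge_overlap": overlap.to_dict(),
        "edge_frequency": {
            "n_unique": freq.n_unique,
            "unique_fraction": freq.unique_fraction,
            "tier_counts": {str(t): c for t, c in freq.tier_counts.items()},
            "tier_fractions": {str(t): f for t, f in freq.tier_fractions.items()},
        } if freq else {},
        "node_commonality": {
            "in_all": len(commonality[0]),
            "in_exactly_one": len(commonality[1]),
        },
        "permutation": permutation,
        "controllability": {
            "n_driver": ctrl.n_driver,
            "node_class_counts": ctrl.class_counts,
            "node_class_percentages": ctrl.class_percentages,
            "edge_class_counts": edge_classes,
        },
        "interactome": {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "housekeeping_in_interactome": hk_count,
            "housekeeping_fraction": hk_fraction,
        },
        "common_protein_overlap_size": len(common),
        "pathway_similarity_shape": list(sim_matrix.shape),
        "network_cluster_order": order,
    }
    if planted is not None:
        recovery = {}
        for net in networks:
            truth = planted.within_module_pairs(net.subcontext)
            if truth:
                recovery[net.subcontext] = len(truth & net.edge_set()) / len(truth)
        bundle["planted_pair_recovery"] = recovery

    with open(out / "summary.json", "w") as fh:
        json.dump(bundle, fh, indent=1)
    (out / "report.md").write_text(report(bundle))
    return bundle


def report(bundle: dict) -> str:
    """Human-readable markdown rendering of a pipeline summary bundle."""
    lines = ["# ctxnet pipeline report", ""]
    if not bundle:
        return "\n".join(lines + ["WARNING: empty bundle, nothing to report", ""])

    nets = bundle.get("networks")
    if nets:
        lines += ["## Co-expression networks", "",
                  "| subcontext | nodes | edges | samples | datasets |",
                  "|---|---|---|---|---|"]
        for name, v in sorted(nets.items()):
            lines.append(f"| {name} | {v['n_nodes']} | {v['n_edges']} "
                         f"| {v['n_samples']} | {v['n_datasets']} |")
        r = bundle.get("size_sample_correlation")
        if isinstance(r, (int, float)):
            lines += ["", f"Pearson r (samples vs network nodes): {r:.3f}"]
        lines.append("")
    else:
        lines.append("WARNING: no network summaries\n")

    ctrl = bundle.get("controllability")
    if ctrl:
        lines += ["## Interactome controllability", "",
                  f"Driver nodes: {ctrl['n_driver']}", "",
                  "| class | nodes | % |", "|---|---|---|"]
        for cls in controllability.CLASSES:
            n = ctrl["node_class_counts"].get(cls, 0)
            p = ctrl["node_class_percentages"].get(cls, 0.0)
            lines.append(f"| {cls} | {n} | {p:.2f} |")
        lines.append("")
    else:
        lines.append("WARNING: controllability results missing\n")

    freq = bundle.get("edge_frequency")
    if freq:
        lines += ["## Edge commonality", "",
                  f"Unique edges: {freq['n_unique']} ({100 * freq['unique_fraction']:.1f}%)"]
        for tier, frac in sorted(freq.get("tier_fractions", {}).items()):
            lines.append(f"Edges in >= {float(tier):.0%} of networks: {100 * frac:.1f}%")
        lines.append("")

    perm = bundle.get("permutation")
    if perm:
        lines += ["## Interactome overlap vs permuted networks", "",
                  "| subcontext | observed | mean permuted | fold | p |",
                  "|---|---|---|---|---|"]
        for name, v in sorted(perm.items()):
            lines.append(f"| {name} | {v['observed']} | {v['mean_permuted']:.1f} "
                         f"| {v['fold_ratio']:.2f} | {v['empirical_p']:.4f} |")
        lines.append("")
    else:
        lines.append("WARNING: permutation results missing\n")

    return "\n".join(lines)
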
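"""Synthetic multi-dataset expression corpora with planted co-expression structure.

The generator emulates the statistical structure the downstream pipeline
assumes: several microarray-style datasets per biological subcontext (tissue,
cell type, cell line), gene modules that are co-expressed within the
subcontexts where they are "active" (some modules shared across every
subcontext, some subcontext-specific), per-dataset batch effects of the
additive-shift / multiplicative-scale form, and probe-level measurement with
several probes per gene.  Alongside the data it returns the planted ground
truth so parameter-recovery tests can score the pipeline.

Module signal follows an equicorrelated one-factor model: for a gene g in an
active module with latent factor f and target correlation r,

    z_g = sqrt(r) * f + sqrt(1 - r) * eps_g,

so any two same-module genes have latent correlation exactly r (closed form,
hence testable).  Background genes are independent unit-variance noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import ProbeExpressionMatrix, SampleMetadata
from .pathways import PathwayGeneSet

__all__ = [
    "SimulationConfig",
    "PlantedStructure",
    "simulate_expression",
    "simulate_interactome",
    "simulate_pathways",
    "simulate_housekeeping",
    "write_simulation",
]

#: Signal attenuation of secondary probes relative to probe 1.  Probe 1
#: carries the full latent signal with a small fraction of the measurement
#: noise, so it is deterministically the most variable probe of its gene and
#: the variance-based collapse rule recovers it.
_SECONDARY_PROBE_ATTENUATION = 0.5
_PRIMARY_PROBE_NOISE_FRACTION = 0.2


class ConfigurationError(ValueError):
    """A simulation configuration violates one of its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic corpus.

    Defaults define the package's desk-scale study conditions: three
    subcontexts observed by three datasets of 20 samples each, 300 genes of
    which six modules of 12 genes carry planted co-expression (two modules
    shared across all subcontexts), moderate batch effects, and up to three
    probes per gene.
    """

    n_genes: int = 300
    n_subcontexts: int = 3
    datasets_per_subcontext: int = 3
    samples_per_dataset: int = 20
    n_modules: int = 6
    module_size: int = 12
    shared_module_fraction: float = 1.0 / 3.0
    within_module_correlation: float = 0.7
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.1
    probes_per_gene_max: int = 3
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_subcontexts": self.n_subcontexts,
            "datasets_per_subcontext": self.datasets_per_subcontext,
            "samples_per_dataset": self.samples_per_dataset,
            "module_size": self.module_size,
            "probes_per_gene_max": self.probes_per_gene_max,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a count >= 1, got {value!r}")
        if self.n_modules < 0:
            raise ConfigurationError(f"n_modules must be >= 0, got {self.n_modules!r}")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError(
                "n_modules * module_size exceeds n_genes "
                f"({self.n_modules} * {self.module_size} > {self.n_genes})"
            )
        if not 0.0 <= self.shared_module_fraction <= 1.0:
            raise ConfigurationError(
                f"shared_module_fraction must be in [0, 1], got {self.shared_module_fraction!r}"
            )
        if not 0.0 <= self.within_module_correlation < 1.0:
            raise ConfigurationError(
                "within_module_correlation must be in [0, 1), "
                f"got {self.within_module_correlation!r}"
            )
        for name in ("batch_shift_sd", "batch_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class PlantedStructure:
    """Ground truth of a simulated corpus.

    module_assignments maps gene id -> module id for module genes only
    (background genes absent); subcontext_modules maps subcontext label ->
    set of active module ids; batch_params maps (dataset id, gene id) ->
    (additive shift, multiplicative scale); housekeeping_truth is the set of
    genes belonging to modules active in every subcontext.
    """

    module_assignments: dict[str, int]
    subcontext_modules: dict[str, set[int]]
    batch_params: dict[tuple[str, str], tuple[float, float]]
    housekeeping_truth: set[str] = field(default_factory=set)
    gene_ids: list[str] = field(default_factory=list)

    def module_members(self, module: int) -> set[str]:
        return {g for g, m in self.module_assignments.items() if m == module}

    def within_module_pairs(self, subcontext: str) -> set[tuple[str, str]]:
        """All unordered same-module gene pairs of modules active in a subcontext."""
        pairs: set[tuple[str, str]] = set()
        for module in self.subcontext_modules[subcontext]:
            members = sorted(self.module_members(module))
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add((a, b))
        return pairs


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _plan_structure(config: SimulationConfig, rng: np.random.Generator) -> PlantedStructure:
    genes = _gene_ids(config.n_genes)
    assignments: dict[str, int] = {}
    for m in range(config.n_modules):
        for g in genes[m * config.module_size:(m + 1) * config.module_size]:
            assignments[g] = m

    n_shared = int(round(config.shared_module_fraction * config.n_modules))
    shared = set(range(n_shared))
    subcontexts = [f"subcontext_{c + 1}" for c in range(config.n_subcontexts)]
    active: dict[str, set[int]] = {s: set(shared) for s in subcontexts}
    # context-specific modules distributed round-robin
    for i, m in enumerate(range(n_shared, config.n_modules)):
        active[subcontexts[i % len(subcontexts)]].add(m)

    housekeeping = {g for g, m in assignments.items() if m in shared}
    return PlantedStructure(
        module_assignments=assignments,
        subcontext_modules=active,
        batch_params={},
        housekeeping_truth=housekeeping,
        gene_ids=genes,
    )


def simulate_expression(
    config: SimulationConfig,
) -> tuple[list[tuple[ProbeExpressionMatrix, list[SampleMetadata]]], PlantedStructure]:
    """Simulate probe-level datasets for every subcontext.

    Returns one ``(ProbeExpressionMatrix, metadata rows)`` pair per dataset
    (``n_subcontexts * datasets_per_subcontext`` in total) plus the planted
    ground truth.  Dataset id doubles as batch id.  All randomness flows from
    ``config.seed`` through a splittable SeedSequence, so identical configs
    reproduce byte-identical output.
    """
    root = np.random.SeedSequence(config.seed)
    ss_plan, ss_base, ss_batch, ss_data = root.spawn(4)
    plan_rng = np.random.default_rng(ss_plan)
    planted = _plan_structure(config, plan_rng)
    genes = planted.gene_ids

    # baseline log-intensity per gene, shared by all datasets (like a
    # microarray log2 scale)
    base = np.random.default_rng(ss_base).normal(7.0, 1.0, size=config.n_genes)

    batch_rng = np.random.default_rng(ss_batch)
    data_rng = np.random.default_rng(ss_data)

    # number of probes per gene is a global property of the platform
    n_probes = plan_rng.integers(1, config.probes_per_gene_max + 1, size=config.n_genes)

    datasets: list[tuple[ProbeExpressionMatrix, list[SampleMetadata]]] = []
    module_of = np.full(config.n_genes, -1)
    for i, g in enumerate(genes):
        module_of[i] = planted.module_assignments.get(g, -1)

    for c, (subcontext, active) in enumerate(sorted(planted.subcontext_modules.items())):
        for d in range(config.datasets_per_subcontext):
            dataset_id = f"ds_{subcontext}_{d + 1}"
            n = config.samples_per_dataset
            r = config.within_module_correlation

            # latent gene signal, unit variance for every gene
            z = data_rng.standard_normal((config.n_genes, n))
            factors = data_rng.standard_normal((max(config.n_modules, 1), n))
            for m in active:
                rows = module_of == m
                z[rows] = np.sqrt(r) * factors[m] + np.sqrt(1.0 - r) * z[rows]

            shift = batch_rng.normal(0.0, config.batch_shift_sd, size=config.n_genes)
            scale = np.exp(batch_rng.normal(0.0, config.batch_scale_sd, size=config.n_genes))
            for i, g in enumerate(genes):
                planted.batch_params[(dataset_id, g)] = (float(shift[i]), float(scale[i]))

            latent = base[:, None] + shift[:, None] + scale[:, None] * z

            probe_rows = []
            probe_ids = []
            for i, g in enumerate(genes):
                for k in range(1, n_probes[i] + 1):
                    probe_ids.append(f"{g}_p{k}")
                    if k == 1:
                        eps = data_rng.normal(
                            0.0, _PRIMARY_PROBE_NOISE_FRACTION * config.noise_sd, size=n
                        )
                        probe_rows.append(latent[i] + eps)
                    else:
                        eps = data_rng.normal(0.0, config.noise_sd, size=n)
                        att = _SECONDARY_PROBE_ATTENUATION
                        centred = latent[i] - base[i]
                        probe_rows.append(base[i] + att * centred + eps)

            sample_ids = [f"{dataset_id}_s{j + 1}" for j in range(n)]
            matrix = ProbeExpressionMatrix(
                values=np.asarray(probe_rows),
                probe_ids=probe_ids,
                sample_ids=sample_ids,
            )
            metadata = [
                SampleMetadata(
                    sample_id=s,
                    dataset_id=dataset_id,
                    subcontext=subcontext,
                    usable=True,
                    is_control=True,
                )
                for s in sample_ids
            ]
            datasets.append((matrix, metadata))
    return datasets, planted


def simulate_interactome(n_nodes: int, n_edges: int, seed: int) -> nx.DiGraph:
    """Scale-free-style directed interactome with an exact edge count.

    Grows the graph by preferential attachment on total degree (each new node
    attaches in a random direction to degree-biased targets), then tops up
    with degree-biased extra arcs until exactly ``n_edges`` distinct directed
    edges exist.  No self-loops, no duplicate arcs.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError(
            f"n_edges={n_edges} infeasible for a simple digraph on {n_nodes} nodes"
        )
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_nodes)))
    nodes = [f"p{i:0{width}d}" for i in range(1, n_nodes + 1)]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    if n_edges == 0:
        return g

    m0 = max(1, n_edges // max(n_nodes - 1, 1))
    degree = np.zeros(n_nodes)
    # seed arc
    g.add_edge(nodes[0], nodes[1]) if n_nodes > 1 else None
    if n_nodes > 1:
        degree[0] += 1
        degree[1] += 1
    for i in range(2, n_nodes):
        if g.number_of_edges() >= n_edges:
            break
        weights = degree[:i] + 1.0
        weights /= weights.sum()
        k = min(m0, i, n_edges - g.number_of_edges())
        targets = rng.choice(i, size=k, replace=False, p=weights)
        for t in targets:
            if rng.random() < 0.5:
                g.add_edge(nodes[i], nodes[t])
            else:
                g.add_edge(nodes[t], nodes[i])
            degree[i] += 1
            degree[t] += 1

    # top-up with degree-biased arcs until the exact count is reached
    guard = 0
    while g.number_of_edges() < n_edges:
        weights = degree + 1.0
        weights /= weights.sum()
        a, b = rng.choice(n_nodes, size=2, replace=False, p=weights)
        if not g.has_edge(nodes[a], nodes[b]):
            g.add_edge(nodes[a], nodes[b])
            degree[a] += 1
            degree[b] += 1
            guard = 0
        else:
            guard += 1
            if guard > 1000:
                # dense corner: fall back to uniform missing-arc sampling
                missing = [
                    (u, v)
                    for u in nodes
                    for v in nodes
                    if u != v and not g.has_edge(u, v)
                ]
                idx = rng.choice(len(missing), size=n_edges - g.number_of_edges(), replace=False)
                for j in idx:
                    g.add_edge(*missing[j])
                break
    return g


def simulate_pathways(
    planted: PlantedStructure,
    n_pathways: int,
    pathway_size_range: tuple[int, int],
    planted_fraction: float,
    seed: int,
) -> list[PathwayGeneSet]:
    """Pathway gene sets, a fraction drawn from single planted modules.

    ``planted_fraction`` of the pathways sample their members from one
    planted module each (cycling through modules), the rest are uniform
    random subsets of the gene universe.  Module-derived pathways are
    expected to score high under the pathway-network similarity on networks
    where their module is active; random ones near zero at 1% edge density.
    """
    lo, hi = pathway_size_range
    if lo < 2 or hi < lo:
        raise ValueError("pathway sizes must satisfy 2 <= lo <= hi")
    if hi > len(planted.gene_ids):
        raise ValueError("pathway size exceeds the gene universe")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    modules = sorted(set(planted.module_assignments.values()))
    n_planted = int(round(planted_fraction * n_pathways))
    if n_planted and not modules:
        raise ValueError("planted_fraction > 0 but the structure has no modules")

    pathways: list[PathwayGeneSet] = []
    universe = list(planted.gene_ids)
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if i < n_planted:
            module = modules[i % len(modules)]
            members = sorted(planted.module_members(module))
            size = min(size, len(members))
            chosen = sorted(rng.choice(members, size=size, replace=False))
            name = f"pw{i + 1:03d}_module{module}"
            desc = f"planted module {module}"
        else:
            chosen = sorted(rng.choice(universe, size=size, replace=False))
            name = f"pw{i + 1:03d}_random"
            desc = "random gene set"
        pathways.append(PathwayGeneSet(pathway_id=name, name=desc, members=set(chosen)))
    return pathways


def simulate_housekeeping(planted: PlantedStructure) -> list[str]:
    """Genes of modules active in every subcontext, sorted."""
    return sorted(planted.housekeeping_truth)


def write_simulation(
    out_dir: str | Path,
    datasets: list[tuple[ProbeExpressionMatrix, list[SampleMetadata]]],
    planted: PlantedStructure,
    interactome: nx.DiGraph | None = None,
    pathways: list[PathwayGeneSet] | None = None,
) -> None:
    """Write the synthetic corpus in the pipeline's plain-text interchange formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for matrix, metadata in datasets:
        dataset_id = metadata[0].dataset_id
        df = pd.DataFrame(matrix.values, index=matrix.probe_ids, columns=matrix.sample_ids)
        df.index.name = "probe_id"
        df.to_csv(out / f"{dataset_id}.expression.tsv", sep="\t")
        for row in metadata:
            meta_rows.append(
                {
                    "sample_id": row.sample_id,
                    "dataset_id": row.dataset_id,
                    "subcontext": row.subcontext,
                    "usable": row.usable,
                    "is_control": row.is_control,
                }
            )
    pd.DataFrame(meta_rows).to_csv(out / "metadata.tsv", sep="\t", index=False)

    probe_map = []
    seen = set()
    for matrix, _ in datasets:
        for probe in matrix.probe_ids:
            if probe not in seen:
                seen.add(probe)
                probe_map.append({"probe_id": probe, "gene_id": probe.rsplit("_p", 1)[0]})
    pd.DataFrame(probe_map).to_csv(out / "probe_map.tsv", sep="\t", index=False)

    if interactome is not None:
        with open(out / "interactome.tsv", "w") as fh:
            fh.write("source\ttarget\n")
            for u, v in sorted(interactome.edges()):
                fh.write(f"{u}\t{v}\n")

    if pathways is not None:
        with open(out / "pathways.gmt", "w") as fh:
            for p in pathways:
                fh.write("\t".join([p.pathway_id, p.name, *sorted(p.members)]) + "\n")

    with open(out / "housekeeping.txt", "w") as fh:
        for g in simulate_housekeeping(planted):
            fh.write(g + "\n")

    truth = {
        "module_assignments": planted.module_assignments,
        "subcontext_modules": {k: sorted(v) for k, v in planted.subcontext_modules.items()},
        "housekeeping_truth": sorted(planted.housekeeping_truth),
        "gene_ids": planted.gene_ids,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
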
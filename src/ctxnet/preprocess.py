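"""From probe-level datasets to one batch-corrected gene matrix per subcontext.

Pipeline order: per-dataset quantile normalization, probe-to-gene collapse
(most variable probe wins), column-wise merge of all datasets of a
subcontext over the shared gene universe, then parametric empirical-Bayes
batch adjustment with the dataset of origin as the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbeExpressionMatrix",
    "GeneExpressionMatrix",
    "SampleMetadata",
    "filter_samples",
    "quantile_normalize",
    "collapse_probes",
    "merge_by_subcontext",
    "combat_adjust",
    "read_expression_tsv",
    "read_metadata_tsv",
    "read_probe_map",
]


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    dataset_id: str
    subcontext: str
    usable: bool = True
    is_control: bool = True


@dataclass
class ProbeExpressionMatrix:
    """Probes x samples matrix of normalized expression values."""

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")


@dataclass
class GeneExpressionMatrix:
    """Genes x samples matrix with per-sample batch labels and a subcontext tag."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    batch_labels: dict[str, str] = field(default_factory=dict)
    subcontext: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.sample_ids if self.batch_labels and s not in self.batch_labels]
        if missing:
            raise ValueError(f"batch label missing for samples: {missing[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def filter_samples(metadata: list[SampleMetadata]) -> list[SampleMetadata]:
    """Keep usable control/reference samples, preserving order."""
    return [m for m in metadata if m.usable and m.is_control]


def quantile_normalize(m: ProbeExpressionMatrix) -> ProbeExpressionMatrix:
    """Force every sample onto the common (row-mean of sorted columns) distribution.

    Ties within a column receive the mean of the reference quantile values
    their positions span, so the operation is permutation-equivariant and
    idempotent.
    """
    x = m.values
    if x.shape[1] < 1:
        raise ValueError("need at least one sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in expression matrix")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        assigned = np.empty_like(sorted_col)
        i = 0
        n = len(sorted_col)
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            assigned[i:k + 1] = reference[i:k + 1].mean()
            i = k + 1
        out[order, j] = assigned
    return ProbeExpressionMatrix(out, list(m.probe_ids), list(m.sample_ids))


def collapse_probes(
    m: ProbeExpressionMatrix, probe_map: dict[str, str] | pd.DataFrame
) -> GeneExpressionMatrix:
    """One row per gene: the mapped probe with the largest sample variance.

    Unmapped probes are dropped.  Variance ties break toward the
    lexicographically smallest probe id.  A probe mapped to more than one
    gene is an error.
    """
    if isinstance(probe_map, pd.DataFrame):
        dup = probe_map.loc[probe_map["probe_id"].duplicated(keep=False)]
        conflict = dup.groupby("probe_id")["gene_id"].nunique()
        bad = conflict[conflict > 1]
        if len(bad):
            raise ValueError(f"probe mapped to multiple genes: {bad.index[0]}")
        mapping = dict(zip(probe_map["probe_id"], probe_map["gene_id"]))
    else:
        mapping = dict(probe_map)

    variances = m.values.var(axis=1, ddof=1) if m.values.shape[1] > 1 else np.zeros(len(m.probe_ids))
    best: dict[str, tuple[float, str, int]] = {}
    for i, probe in enumerate(m.probe_ids):
        gene = mapping.get(probe)
        if gene is None:
            continue
        candidate = (-variances[i], probe, i)
        if gene not in best or candidate < best[gene]:
            best[gene] = candidate
    genes = sorted(best)
    rows = np.array([best[g][2] for g in genes], dtype=int)
    return GeneExpressionMatrix(
        values=m.values[rows],
        gene_ids=genes,
        sample_ids=list(m.sample_ids),
    )


def merge_by_subcontext(
    datasets: list[tuple[GeneExpressionMatrix, str]], subcontext: str
) -> GeneExpressionMatrix:
    """Concatenate samples of all datasets of a subcontext over shared genes.

    ``datasets`` pairs each matrix with its dataset id, which becomes the
    batch label.  Sample-id collisions across datasets are resolved by
    prefixing the dataset id.  Genes are intersected; an empty intersection
    is an error.
    """
    if not datasets:
        raise ValueError(f"no datasets for subcontext {subcontext!r}")
    shared: set[str] | None = None
    for matrix, _ in datasets:
        shared = set(matrix.gene_ids) if shared is None else shared & set(matrix.gene_ids)
    if not shared:
        raise ValueError(f"empty gene intersection for subcontext {subcontext!r}")
    genes = sorted(shared)

    seen: set[str] = set()
    columns = []
    sample_ids: list[str] = []
    batch_labels: dict[str, str] = {}
    for matrix, dataset_id in datasets:
        index = {g: i for i, g in enumerate(matrix.gene_ids)}
        rows = [index[g] for g in genes]
        columns.append(matrix.values[rows])
        for s in matrix.sample_ids:
            name = s if s not in seen else f"{dataset_id}:{s}"
            seen.add(name)
            sample_ids.append(name)
            batch_labels[name] = dataset_id
    return GeneExpressionMatrix(
        values=np.concatenate(columns, axis=1),
        gene_ids=genes,
        sample_ids=sample_ids,
        batch_labels=batch_labels,
        subcontext=subcontext,
    )


def combat_adjust(m: GeneExpressionMatrix, max_iter: int = 100, tol: float = 1e-4) -> GeneExpressionMatrix:
    """Parametric empirical-Bayes batch adjustment (no covariates).

    Gene-wise standardization against the pooled batch-design fit, then
    method-of-moments priors — normal on the per-batch location effects and
    inverse-gamma on the per-batch scale effects — shrink the batch
    parameters gene-wise before the data are adjusted back to the pooled
    location and scale.  A single-batch matrix is returned unchanged.
    """
    batches: dict[str, list[int]] = {}
    for j, s in enumerate(m.sample_ids):
        batches.setdefault(m.batch_labels.get(s, "batch0"), []).append(j)
    if len(batches) < 2:
        return replace(m, values=m.values.copy())
    small = [b for b, idx in batches.items() if len(idx) < 2]
    if small:
        raise ValueError(f"batch with fewer than 2 samples: {small[0]}")

    x = m.values
    n_genes, n_samples = x.shape
    batch_names = sorted(batches)
    sizes = np.array([len(batches[b]) for b in batch_names], dtype=float)

    batch_means = np.stack([x[:, batches[b]].mean(axis=1) for b in batch_names])
    grand_mean = (sizes[:, None] * batch_means).sum(axis=0) / n_samples
    fitted = np.empty_like(x)
    for bi, b in enumerate(batch_names):
        fitted[:, batches[b]] = batch_means[bi][:, None]
    var_pooled = ((x - fitted) ** 2).sum(axis=1) / n_samples
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd_pooled = np.sqrt(var_pooled)

    z = (x - grand_mean[:, None]) / sd_pooled[:, None]

    adjusted = np.empty_like(z)
    for bi, b in enumerate(batch_names):
        idx = batches[b]
        n_b = len(idx)
        zb = z[:, idx]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)

        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        # inverse-gamma moment estimators
        a_prior = (2 * d_var + d_mean**2) / d_var if d_var > 0 else 2.0
        b_prior = (d_mean * d_var + d_mean**3) / d_var if d_var > 0 else d_mean

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            gamma_new = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (
                n_b * tau2 + delta_star
            )
            ss = ((zb - gamma_new[:, None]) ** 2).sum(axis=1)
            delta_new = (b_prior + 0.5 * ss) / (n_b / 2.0 + a_prior - 1.0)
            change = max(
                np.abs(gamma_new - gamma_star).max(),
                np.abs(delta_new - delta_star).max(),
            )
            gamma_star, delta_star = gamma_new, delta_new
            if change < tol:
                break
        adjusted[:, idx] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adjusted * sd_pooled[:, None] + grand_mean[:, None]
    return replace(m, values=out)


def read_expression_tsv(path: str | Path) -> ProbeExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ProbeExpressionMatrix(
        values=df.to_numpy(dtype=float),
        probe_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
    )


def read_metadata_tsv(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMetadata(
            sample_id=str(r.sample_id),
            dataset_id=str(r.dataset_id),
            subcontext=str(r.subcontext),
            usable=bool(r.usable),
            is_control=bool(r.is_control),
        )
        for r in df.itertuples()
    ]


def read_probe_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError("probe map needs columns probe_id and gene_id")
    return df


def preprocess_subcontext(
    datasets: list[tuple[ProbeExpressionMatrix, str]],
    probe_map: dict[str, str] | pd.DataFrame,
    subcontext: str,
) -> GeneExpressionMatrix:
    """Quantile-normalize, collapse, merge and batch-adjust one subcontext."""
    collapsed = []
    for matrix, dataset_id in datasets:
        normed = quantile_normalize(matrix)
        collapsed.append((collapse_probes(normed, probe_map), dataset_id))
    merged = merge_by_subcontext(collapsed, subcontext)
    if len(set(merged.batch_labels.values())) < 2:
        return merged
    return combat_adjust(merged)
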
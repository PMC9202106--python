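"""Preprocessing: sample filtering, quantile normalization, probe collapse,
merging, and empirical-Bayes batch adjustment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ctxnet.preprocess import (
    GeneExpressionMatrix,
    ProbeExpressionMatrix,
    SampleMetadata,
    collapse_probes,
    combat_adjust,
    filter_samples,
    merge_by_subcontext,
    quantile_normalize,
)


def make_probe_matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ProbeExpressionMatrix(values, probes, samples)


class TestFilterSamples:
    def test_keeps_usable_controls_only(self):
        rows = [
            SampleMetadata("s1", "d", "sc", usable=True, is_control=True),
            SampleMetadata("s2", "d", "sc", usable=False, is_control=True),
            SampleMetadata("s3", "d", "sc", usable=True, is_control=False),
            SampleMetadata("s4", "d", "sc", usable=False, is_control=False),
            SampleMetadata("s5", "d", "sc", usable=True, is_control=True),
        ]
        kept = filter_samples(rows)
        assert [m.sample_id for m in kept] == ["s1", "s5"]

    def test_identity_and_empty(self):
        rows = [SampleMetadata("s1", "d", "sc"), SampleMetadata("s2", "d", "sc")]
        assert filter_samples(rows) == rows
        assert filter_samples([]) == []


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        m = make_probe_matrix([[1, 4], [2, 5], [3, 6]])
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values, expected)

    def test_identical_columns_unchanged(self):
        m = make_probe_matrix([[1, 1], [5, 5], [3, 3]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_single_column_unchanged(self):
        m = make_probe_matrix([[3], [1], [2]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_ties_get_mean_of_spanned_quantiles(self):
        # column 1 has a tie at its two smallest positions
        m = make_probe_matrix([[1, 10], [1, 20], [5, 30]])
        out = quantile_normalize(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert out.values[0, 0] == out.values[1, 0] == pytest.approx(ref[:2].mean())
        assert out.values[2, 0] == pytest.approx(ref[2])

    def test_idempotent(self, rng):
        m = make_probe_matrix(rng.normal(size=(40, 6)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_all_columns_share_sorted_values(self, rng):
        m = make_probe_matrix(rng.normal(size=(25, 4)))
        out = quantile_normalize(m)
        sorted_cols = np.sort(out.values, axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_non_finite_rejected(self):
        m = make_probe_matrix([[1.0, 2.0], [3.0, 4.0]])
        m.values[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            quantile_normalize(m)


class TestCollapseProbes:
    def test_most_variable_probe_wins(self):
        m = make_probe_matrix([[1, 1, 1, 1], [0, 2, 0, 2]], probes=["pA", "pB"])
        out = collapse_probes(m, {"pA": "G1", "pB": "G1"})
        assert out.gene_ids == ["G1"]
        np.testing.assert_allclose(out.values[0], [0, 2, 0, 2])

    def test_variance_tie_breaks_lexicographically(self):
        m = make_probe_matrix([[0, 2], [2, 0]], probes=["pB", "pA"])
        out = collapse_probes(m, {"pA": "G1", "pB": "G1"})
        np.testing.assert_allclose(out.values[0], [2, 0])  # pA's row

    def test_unmapped_probes_dropped_and_count_contract(self, rng):
        values = rng.normal(size=(6, 5))
        probes = [f"p{i}" for i in range(6)]
        mapping = {"p0": "G1", "p1": "G1", "p2": "G2", "p3": "G3"}
        out = collapse_probes(make_probe_matrix(values, probes=probes), mapping)
        assert out.gene_ids == ["G1", "G2", "G3"]

    def test_probe_mapped_to_two_genes_is_an_error(self):
        m = make_probe_matrix([[1, 2]], probes=["pX"])
        probe_map = pd.DataFrame(
            {"probe_id": ["pX", "pX"], "gene_id": ["G1", "G2"]}
        )
        with pytest.raises(ValueError, match="pX"):
            collapse_probes(m, probe_map)


class TestMerge:
    def make_gene_matrix(self, genes, samples, values=None, rng=None):
        if values is None:
            values = rng.normal(size=(len(genes), len(samples)))
        return GeneExpressionMatrix(np.asarray(values, float), genes, samples)

    def test_counts_and_batches(self, rng):
        a = self.make_gene_matrix(["A", "B"], [f"a{i}" for i in range(10)], rng=rng)
        b = self.make_gene_matrix(["A", "B"], [f"b{i}" for i in range(15)], rng=rng)
        merged = merge_by_subcontext([(a, "d1"), (b, "d2")], "liver")
        assert len(merged.sample_ids) == 25
        assert set(merged.batch_labels.values()) == {"d1", "d2"}
        assert merged.subcontext == "liver"

    def test_gene_intersection(self, rng):
        a = self.make_gene_matrix(["A", "B", "C"], ["s1", "s2"], rng=rng)
        b = self.make_gene_matrix(["B", "C", "D"], ["t1", "t2"], rng=rng)
        merged = merge_by_subcontext([(a, "d1"), (b, "d2")], "sc")
        assert merged.gene_ids == ["B", "C"]

    def test_empty_intersection_errors(self, rng):
        a = self.make_gene_matrix(["A"], ["s1"], rng=rng)
        b = self.make_gene_matrix(["B"], ["t1"], rng=rng)
        with pytest.raises(ValueError, match="intersection"):
            merge_by_subcontext([(a, "d1"), (b, "d2")], "sc")

    def test_sample_collision_prefixed(self, rng):
        a = self.make_gene_matrix(["A"], ["s1"], rng=rng)
        b = self.make_gene_matrix(["A"], ["s1"], rng=rng)
        merged = merge_by_subcontext([(a, "d1"), (b, "d2")], "sc")
        assert merged.sample_ids == ["s1", "d2:s1"]


def two_batch_matrix(rng, n_genes=50, n_per_batch=100, shift=3.0):
    base = rng.normal(7, 1, size=(n_genes, 1))
    b1 = base + rng.normal(0, 1, size=(n_genes, n_per_batch))
    b2 = base + shift + rng.normal(0, 1, size=(n_genes, n_per_batch))
    samples = [f"a{i}" for i in range(n_per_batch)] + [f"b{i}" for i in range(n_per_batch)]
    batches = {s: ("batch1" if s.startswith("a") else "batch2") for s in samples}
    genes = [f"G{i}" for i in range(n_genes)]
    return GeneExpressionMatrix(np.hstack([b1, b2]), genes, samples, batches, "sc")


class TestCombat:
    def test_single_batch_unchanged(self, rng):
        m = GeneExpressionMatrix(
            rng.normal(size=(5, 4)), list("ABCDE"), ["s1", "s2", "s3", "s4"],
            {f"s{i}": "b1" for i in range(1, 5)}, "sc",
        )
        out = combat_adjust(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_shift_removed(self, rng):
        m = two_batch_matrix(rng, shift=3.0)
        out = combat_adjust(m)
        idx1 = [j for j, s in enumerate(m.sample_ids) if s.startswith("a")]
        idx2 = [j for j, s in enumerate(m.sample_ids) if s.startswith("b")]
        diff = out.values[:, idx2].mean(axis=1) - out.values[:, idx1].mean(axis=1)
        # residual is EB-shrinkage sampling noise (identical in sva::ComBat);
        # the +3 shift must be reduced ~40-fold on average
        assert np.abs(diff).mean() < 0.1

    def test_shape_and_samples_preserved(self, rng):
        m = two_batch_matrix(rng, n_genes=10, n_per_batch=10)
        out = combat_adjust(m)
        assert out.values.shape == m.values.shape
        assert out.sample_ids == m.sample_ids

    def test_pooled_mean_preserved_for_balanced_batches(self, rng):
        m = two_batch_matrix(rng, n_genes=20, n_per_batch=30)
        out = combat_adjust(m)
        # exact invariance is broken by EB shrinkage; the residue is
        # O(sampling noise / sqrt(n)) and sva::ComBat behaves the same
        np.testing.assert_allclose(
            out.values.mean(axis=1), m.values.mean(axis=1), atol=1e-3
        )

    def test_small_batch_rejected(self, rng):
        m = GeneExpressionMatrix(
            rng.normal(size=(5, 3)), list("ABCDE"), ["s1", "s2", "s3"],
            {"s1": "b1", "s2": "b1", "s3": "b2"}, "sc",
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            combat_adjust(m)

    def test_agrees_with_sva_combat(self, rng, tmp_path):
        """Independent cross-check against the reference EB implementation in R."""
        m = two_batch_matrix(rng, n_genes=30, n_per_batch=15, shift=2.0)
        ours = combat_adjust(m)
        df = m.to_frame()
        df.to_csv(tmp_path / "expr.tsv", sep="\t")
        batch = ",".join(
            "1" if m.batch_labels[s] == "batch1" else "2" for s in m.sample_ids
        )
        script = textwrap.dedent(f"""
            suppressMessages(library(sva))
            x <- as.matrix(read.table("{tmp_path}/expr.tsv", sep="\\t",
                                      header=TRUE, row.names=1, check.names=FALSE))
            batch <- c({batch})
            out <- ComBat(dat=x, batch=batch, par.prior=TRUE, mean.only=FALSE)
            write.table(out, "{tmp_path}/combat.tsv", sep="\\t", quote=FALSE)
        """)
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        theirs = pd.read_csv(tmp_path / "combat.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(ours.values, theirs.to_numpy(), atol=1e-4)
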
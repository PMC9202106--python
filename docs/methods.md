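# Methods

This note documents the models, parameter choices, and numerical
conventions behind `ctxnet`, and what the synthetic-data experiments do and
do not demonstrate.

## Preprocessing

The pipeline consumes normalized probe-level matrices (probes × samples)
per dataset, with sample metadata carrying dataset id, subcontext label,
a usable flag, and a control/reference flag. Raw array processing (.CEL
parsing, RMA background subtraction) is out of scope; `quantile_normalize`
is provided as a standalone utility for raw-ish input.

Order of operations per subcontext: quantile normalization per dataset →
probe-to-gene collapse per dataset → column-wise merge over the gene
intersection → empirical-Bayes batch adjustment with dataset of origin as
the batch. Collapsing before merging keeps the operation order-stable and
deterministic regardless of which datasets participate; probe variance is
therefore computed within a dataset. Gene sets are intersected (not
unioned) at merge time because all datasets of a corpus come from one
platform, making universes near-identical and avoiding missing values.

*Quantile normalization.* Every column is forced onto the common reference
distribution (row-wise mean of per-column sorted values). Ties within a
column receive the mean of the reference quantiles their positions span,
which makes the operation idempotent and independent of sort stability.

*Probe collapse.* One row per gene: the mapped probe with the largest
sample variance, ties broken toward the lexicographically smallest probe
id so output is bit-reproducible.

*Batch adjustment.* Parametric empirical-Bayes adjustment of per-batch,
per-gene location and scale (the ComBat model), without covariates:
gene-wise standardization against the pooled batch-design fit,
method-of-moments priors (normal on batch locations, inverse-gamma on
batch scales), fixed-point iteration of the shrinkage equations
(tolerance 1e-4, max 100 iterations), then back-transformation. Output
matches Bioconductor's `sva::ComBat` to ~1e-4 (cross-checked in the test
suite). Two consequences worth knowing: shrinkage leaves a residual batch
difference of order (sampling noise)/2 per gene — removal is never exact —
and the per-gene pooled mean is preserved only up to that same residual
(~1e-3–1e-4 at realistic sizes), not exactly. Single-batch input is
returned unchanged; a batch with fewer than two samples is an error.

## Network construction

Pearson correlation across samples (zero-variance genes dropped with a
warning, ≥3 samples required), signed soft-threshold adjacency
a_ij = ((1+cor_ij)/2)^β, and the standard topological overlap
TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with l excluding both
endpoints and k excluding the diagonal (unsigned TOM on signed adjacency —
the conventional signed-network default).

Parameters:

- **β (soft power), default 12** — the conventional default for signed
  networks; configurable. Higher β sharpens the separation between strong
  and weak correlations before the TOM is computed.
- **top fraction, default 0.01** — the network keeps exactly
  round(fraction · n(n−1)/2) gene pairs with the largest TOM (half-way
  cases round up). Fixing the count rather than a weight threshold makes
  same-universe networks comparable by raw shared-edge counts. Ties at the
  cutoff break by lexicographic gene-pair order, so networks are
  bit-reproducible.

No module detection, eigengenes, or scale-free fit diagnostics: the
retained-edge network itself is the object of study.

## Structural controllability

The bipartite representation splits every node into an out-copy and an
in-copy; arc a→b becomes the bipartite edge out(a)–in(b). The minimum
driver-node count is N_D = max(N − |M|, 1) for a maximum matching M
(computed by SciPy's Hopcroft–Karp-class matcher; only the cardinality
matters, which is unique even though the matching is not). Unmatched
in-copies identify one valid driver set; on a perfectly matched graph any
single node may serve, and the lexicographically smallest is returned.

Node classification removes the node from the universe (N−1 nodes remain)
and recomputes N_D from scratch; likewise per edge. Removing a single edge
can only shrink or preserve the matching, so the *dispensable* edge class
is structurally empty — it is still computed and reported for fidelity,
and the suite asserts it is zero. An exhaustive subset-search oracle
(≤20 edges) validates counts and classes on hundreds of random digraphs.

## Comparisons and permutation nulls

Edge overlap between same-universe networks is a plain set intersection of
unordered pairs. Edge-frequency tiers use thresholds ceil(tier ·
context-size) for tiers 25/50/75%, with fractions over the union of edges
observed in the context. Interactome overlap ignores arc direction.

XSwap permutation: each attempt draws two distinct edges, randomizes
endpoint orientation, and exchanges endpoints ({a,b},{c,d} → {a,d},{c,b}),
rejecting self-loops and duplicates; the attempt budget is 10 × |edges|
(configurable). Degree multiset and edge count are asserted after every
call. A swap-locked graph (e.g. a triangle) returns unchanged with a
warning. The permutation test reports fold ratio observed/mean(permuted)
and the add-one empirical p-value (1 + #{permuted ≥ observed})/(n_perm+1);
a null with mean overlap zero is flagged degenerate with fold 0.

A single fold ratio is one stochastic draw over the null; at small overlap
counts its Monte-Carlo spread is large (≈1/√overlap relative). The
calibration check (a self-permuted network must score ≈1) therefore
averages folds over five independent self-permutations at a problem size
(60 genes, 500 edges, n_perm = 200) where the averaged estimate's error is
well inside ±10%.

## Pathway–network similarity

similarity(P, N) = |{member pairs of P that are edges of N}| / (m(m−1)/2).
The denominator counts *all* member pairs, including genes absent from the
network — absence dilutes the score rather than being ignored, which reads
the score as "how completely is this pathway wired in this context".
Pathways with fewer than two members are skipped with a warning. Network
clustering uses Euclidean distances between score-matrix rows with average
linkage by default (configurable); rows are pre-sorted by label for
deterministic tie handling, and the dendrogram is exported as Newick.

## Synthetic corpus

The generator emulates the statistical structure the analysis assumes —
not the biology of any real compendium:

- **Module signal**: equicorrelated one-factor blocks,
  z_g = √r·f + √(1−r)·ε, giving a closed-form latent correlation of
  exactly r between same-module genes (chosen for testability). Background
  genes are independent unit-variance noise. Shared modules are active in
  every subcontext (their genes form the housekeeping ground truth);
  specific modules are distributed round-robin.
- **Batch effects**: per-(dataset, gene) additive shift ~N(0, shift_sd)
  and log-normal multiplicative scale on the centred signal — exactly the
  location/scale family the EB batch adjustment assumes, so parameter
  recovery is well-posed.
- **Probes**: each gene yields 1..3 probe rows. Probe 1 carries the full
  latent signal plus a small noise term (0.2 × noise_sd); secondary probes
  are attenuated copies (signal coefficient 0.5) with full measurement
  noise. Probe 1 is thereby deterministically the most variable probe of
  its gene for every gene class, so variance-based collapse has a known
  right answer. (A purely additive probe-noise model cannot make the
  best probe the most variable one — added noise only inflates variance —
  hence the attenuation design.)
- **Interactome**: preferential-attachment growth with degree-biased
  top-up arcs to an exact edge count; heavy-tailed in/out degrees, no
  self-loops or duplicate arcs. In the pipeline, interactome nodes are
  randomly assigned gene identities (seeded), keeping interactome topology
  independent of planted modules — so the pipeline's own fold ratios
  center on 1 by construction, and enrichment behaviour is exercised by
  constructed fixtures in the test suite instead.
- **Pathways**: a configurable fraction sampled from single planted
  modules (high expected similarity on home networks), the rest uniform
  random (near-zero similarity at 1% density).

Default study conditions: 300 genes, 3 subcontexts × 3 datasets × 20
samples, 6 modules of 12 genes (2 shared), within-module correlation 0.7,
batch shift sd 1.0, scale sd 0.1, noise sd 0.3. These sizes keep a full
pipeline run in seconds while leaving ~450 retained edges per network
against ~260 planted active-module pairs — recovery is achievable but not
trivially saturated. All randomness flows from one seed through a
splittable generator; identical configs are byte-identical.

What passing on this corpus does **not** show: robustness to non-Gaussian
expression, platform-specific probe biases, outlier samples, unbalanced or
confounded batch designs, or interactomes with literature ascertainment
bias. It shows the pipeline's operations implement their definitions and
recover structure under the model they assume.

## Problem sizes for the reproduction script

`scripts/acceptance.py` runs the default corpus above; the synthetic
interactome uses 800 nodes / 4000 edges (full node and edge
classification — ~4800 matchings — stays in seconds), and permutation
tests use n_perm = 200, which the calibration analysis above shows is
enough for fold ratios at these overlap scales.

## Known limitations

- Probe collapse happens per dataset before merging; variance is not
  recomputed on the merged matrix. With heterogeneous datasets different
  probes may win in different datasets; the collapse is deterministic but
  platform-wide probe choice is not harmonized.
- ComBat is parametric-prior only, no covariates, no reference batch.
- Edge selection materializes all n(n−1)/2 TOM entries; fine to a few
  thousand genes, not engineered for the full 20k-gene platform on one
  machine.
- The fold ratio for small expected overlaps (< ~20 edges) is noisy; use
  larger n_perm and read the empirical p-value alongside it.
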
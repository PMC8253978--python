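# Methods

This note documents the models and procedures implemented in `reostrat`,
the parameters that matter, the assumptions behind the synthetic-data
generator, and the numerical choices made where the design was open.

## Consensus NMF subtyping

### Factorization

The clustering substrate is the non-negative abundance matrix V (genes ×
samples) restricted to the selected gene set. V is factorized as V ≈ WH
(W: genes × r, H: r × samples, both non-negative) by the classical
multiplicative updates that monotonically decrease the generalized
Kullback–Leibler divergence

    D(V ‖ WH) = Σᵢⱼ [ Vᵢⱼ log(Vᵢⱼ / (WH)ᵢⱼ) − Vᵢⱼ + (WH)ᵢⱼ ].

No log transform is applied by default: log-TPM can be negative, and the
KL objective is the natural fit for non-negative abundance data.

Numerical choices:

- W and H are initialized i.i.d. uniform(0, 1]; every consensus run gets
  its own seed derived from the master seed by a counter, so a 200-run
  consensus is reproducible from one integer.
- An epsilon guard of 1e-12 is added inside every division of the
  multiplicative updates; a NaN or infinity appearing despite the guard
  raises immediately rather than propagating.
- Stopping follows the connectivity-stability rule: every `check_every`
  (default 10) iterations the sample partition implied by H (argmax over
  metagenes, ties to the lowest index) is recomputed, and the run stops
  once the partition has been unchanged for `patience` (default 40)
  consecutive checks, or at `max_iter` (default 2000). The library
  defaults are conservative; the test and acceptance suites pass
  `max_iter=200, patience=5`, which this package's experiments show is
  ample for the strongly structured inputs they use, and which keeps the
  full recovery suites fast on a single CPU.

### Consensus and rank selection

For each candidate rank r (grid 2–8 by default; the recovery suites use
2–4), `n_runs` random-start factorizations are pooled into a consensus
matrix C where Cᵢⱼ is the fraction of runs in which samples i and j share a
dominant metagene. Stability is the cophenetic correlation coefficient:
Pearson correlation between the off-diagonal entries of D = 1 − C and the
cophenetic distances of the average-linkage (UPGMA) tree built on D, via
`scipy.cluster.hierarchy`. A perfectly ultrametric consensus (samples
co-cluster always or never) scores 1. The selected rank maximizes the mean
coefficient across cohorts; exact ties resolve to the smaller rank
(fewer clusters is the conservative reading).

Final labels cut the average-linkage tree of the selected consensus into r
clusters, renumbered 1..r by descending cluster size for determinism. Two
conventions here are genuinely open — extracting run labels from H rather
than W, and deriving final labels from the consensus tree rather than a
single best factorization — and this package fixes them as stated; both
are the common practice in consensus-NMF implementations.

Cross-cohort subtype matching maximizes the summed Pearson correlation of
per-cluster mean log1p expression profiles over shared genes, solved
exactly over all r! permutations (r ≤ 8, so exhaustive search is cheap).

## Feature selection

- Genes with mean abundance strictly greater than 1 (unit-scale threshold,
  configurable) are retained.
- "MAD" is implemented as the **mean** absolute deviation from the gene's
  mean, on the natural (not log) scale; this follows the protocol's spelled
  out definition. The conventional median-based MAD is available via
  `mad_scores(statistic="median")` since the acronym usually means that
  elsewhere. Ties in the ranking break lexicographically by gene id.
- Per-cohort top-N lists (N = 1500 by default) are intersected before
  clustering. The recovery suites on 2000-gene synthetic data use N = 300,
  the package's desk-scale choice: it retains essentially all planted
  marker genes while keeping the factorization small.

## DEG concordance

For two directed DEG lists with L₁ and L₂ entries over a common background
of L measured genes, overlapping in k genes of which s share direction, the
score is s/k and the significance is the cumulative hypergeometric
complement P = 1 − Σᵢ₌₀^{s−1} C(L₂,i)C(L−L₂,L₁−i)/C(L,L₁), evaluated by
scipy's log-space survival function. Note that the formula indexes the
overlap distribution (parameterized by L, L₁, L₂) by the consistency count
s rather than the overlap count k; it is implemented exactly as published.
A sign-test alternative (s successes in k trials at p₀ = ½) is available
behind the `binomial_alternative` flag for sensitivity analysis, never as
the default. A zero overlap leaves the score undefined and raises.

## REO biomarkers

### Stable and subtype-specific pairs

For a candidate pair and a sample group, n counts samples with a strict
ordering and k the majority orientation; the raw p-value is the upper
binomial tail P(X ≥ k | n, p₀ = 0.5), BH-adjusted across all tested pairs,
thresholded at FDR < 1e-7. Exact expression ties are uninformative and are
excluded from n by default (`tie_policy="failure"` counts them in n but
never in k); whether the original protocol excluded ties is unknowable
from its description, and exclusion is the conservative choice. Groups
smaller than 24 trigger a warning: even a unanimous pair cannot reach a
raw p below 1e-7 with fewer samples (2⁻²⁴ ≈ 6e-8).

A subtype-specific pair must pass the FDR cutoff with one orientation
inside the subtype and the reversed orientation in the pooled remaining
samples; each side gets its own BH adjustment over the full candidate set.

The candidate pair universe is a free parameter: all unordered pairs over
~15k genes is ~10⁸ tests, so `REOSubtypeClassifier` takes a
`candidate_genes` list (top-MAD genes are the natural default) and guards
against universes above 10⁷ pairs.

### Forward selection and voting

Classification calls a sample subtype-positive when strictly more than
half of a biomarker's pairs show gene_hi > gene_lo. The protocol's metric
definitions are deliberately nonstandard and are the default here:
precision = TP/(TP+FN), the fraction of subtype samples caught
(sensitivity); recall = TN/(TN+FP), the fraction of non-subtype samples
rejected (specificity); F = 2PR/(P+R). `standard_metrics=True` gives the
conventional definitions.

Forward selection seeds with the single pair of highest F, then repeatedly
tentatively adds every remaining candidate and keeps the best strict
improvement, stopping when none improves. The scan order is deterministic:
descending single-pair F, ties by smaller stability p-value, then
lexicographic pair id. The result never scores below the best single
candidate.

The trained ensemble applies biomarkers sequentially in a fixed order
(ascending subtype label); the first strict-majority vote wins and samples
firing no biomarker are labeled `unassigned`. An exact half vote on an
even-sized biomarker does not fire — "more than half" is read literally.

The published three-subtype ensemble ships as a fixture: the single
subtype-1 pair (MT-ND5, RPS27) and the 1/21/19 pair counts are stated
unambiguously in the source's running text, while the exact pairing of
the subtype-2 and subtype-3 table columns is reconstructed from the
typeset row-major layout; `PAIR_PROVENANCE` records which parts are
text-anchored and which are layout-inferred.

## Synthetic data generator

The generator emulates the statistical shape of a two-cohort bulk RNA-seq
subtype study on log2 scale:

    log2 x_gs = b_g + m_gs + c_g(cohort) + l_s + e_gs

| parameter | meaning | default |
|---|---|---|
| `baseline_log_mean`, `baseline_log_sd` | gene baselines b_g ~ N(3, 1) log2 TPM | 3.0, 1.0 |
| `effect_size` | marker half-separation (log2) | 2.0 |
| `batch_shift_sd` | per-cohort gene-wise shift sd (log2) | 0.5 |
| `libsize_sd` | per-sample library factor sd (log2) | 0.3 |
| `noise_sd` | within-group noise sd (log2) | 1.0 |
| cohort sizes | per-subtype samples, two unequal cohorts | 52/78/46 and 21/42/37 |

Exponentiating normal log-values gives strictly positive, right-skewed
(heavy-tailed) TPM-like data. Each subtype's marker program splits into an
up half and a down half: up-markers sit +effect above baseline in their own
subtype and −effect outside, down-markers mirror them, and pairing up- and
down-markers with a shared baseline plants ground-truth reversed pairs that
`SyntheticSpec.planted_pairs` exposes. Batch shifts are gene-wise per
cohort and deliberately not confounded with subtype, so REO robustness is
tested against batch structure without batch acting as a subtype surrogate.
The default cohort sizes mirror a large and a small study arm (the larger
arm scaled down from a TCGA-sized cohort); the recovery suites override
them with three balanced groups of 50 per cohort.

What the generator does **not** model: read-level sampling noise, gene-gene
correlation beyond the subtype programs, zero inflation, transcript-length
effects, or outlier samples. Passing the recovery suites therefore shows
that the pipeline's machinery is correct under its own assumptions — not
that real tumor cohorts will yield the same effect sizes or F-scores.

`monotone_distort` produces per-sample strictly increasing perturbations
(random power maps, random positive scalings, global log1p) under which
every REO-based result must be bit-identical; this is the package's
executable statement of the central robustness claim.

## Degenerate inputs and errors

Readers validate non-negativity, finiteness, and id uniqueness and report
the offending cell. The cophenetic coefficient is undefined (and raises)
when all pairwise consensus distances are equal. Concordance with zero
overlap raises rather than returning 0/0. Metrics with an empty subtype or
complement group warn and report 0. Splitting requires at least two
samples per class. All stochastic steps take explicit seeds.

## Problem sizes in the shipped suites

The recovery suites simulate 2000 genes and 3 × 50 samples per cohort per
condition, cluster with 50 NMF runs over ranks 2–4, and train biomarkers on
a 70/30 split of the 300 merged samples with a 300-gene candidate
universe. These sizes are the package's own desk-scale choices: they
preserve the qualitative regime of a real two-cohort study (hundreds of
samples, strong subtype programs, far more candidate pairs than true
pairs) while keeping the full suite runnable in minutes on one CPU.
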
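# reostrat

Rank-based molecular subtyping of bulk expression cohorts: consensus
non-negative matrix factorization (NMF) discovers tumor subtypes, and
within-sample **relative expression orderings** (REOs) of gene pairs turn
them into normalization-free classifiers that transfer across cohorts and
platforms.

The package is aimed at computational biologists who have gene-by-sample
abundance matrices (TPM-like values) from two or more cohorts and want to

1. stratify samples into molecular subtypes reproducibly,
2. check that differential-expression signatures agree across cohorts, and
3. distill each subtype into a small, portable gene-pair biomarker.

## The methods in brief

**Consensus NMF subtyping.** Genes are filtered to mean abundance > 1,
ranked per cohort by the mean absolute deviation (MAD) of their expression,
and the per-cohort top lists are intersected. The non-negative matrix
V (genes × samples) is factorized as V ≈ WH by multiplicative updates
minimizing the generalized Kullback–Leibler divergence D(V‖WH); each
random-start run assigns samples to their dominant metagene. Pooling many
runs yields a consensus matrix of co-clustering frequencies whose stability
is scored by the **cophenetic correlation coefficient** — the correlation
between consensus distances 1 − C and the cophenetic distances of their
average-linkage tree. The rank with the highest mean cophenetic coefficient
across cohorts wins.

**DEG concordance.** Two differential-expression lists of sizes L₁ and L₂
drawn from L background genes, overlapping in k genes of which s agree in
up/down direction, get concordance score s/k and the cumulative
hypergeometric tail probability

&nbsp;&nbsp;&nbsp;&nbsp;P = 1 − Σᵢ₌₀^{s−1} C(L₂, i) · C(L−L₂, L₁−i) / C(L, L₁).

**REO gene-pair biomarkers.** The REO of a gene pair (i, j) in a sample is
simply whether Gᵢ > Gⱼ; it is invariant to any strictly increasing
per-sample transform, hence robust to library-size scaling, monotone
normalization, and batch shifts. A pair is *stable* in a group when one
orientation holds in k of n samples with upper binomial tail
P(X ≥ k | n, p₀ = 0.5) passing BH FDR < 10⁻⁷; a *subtype-specific* pair is
stable one way inside the subtype and stably reversed in all remaining
samples. Greedy forward selection then grows a minimal pair set maximizing
the F-score — the harmonic mean of the protocol's precision (fraction of
subtype samples called) and recall (fraction of non-subtype samples
rejected) — and a sample is classified into the first subtype (in a fixed
application order) whose biomarker wins a strict majority vote.

## Worked example

Everything below runs on synthetic data from the built-in generator, which
emulates a two-cohort, three-subtype study (heavy-tailed TPM-like values,
subtype-specific up/down gene programs, per-cohort batch shifts,
per-sample library factors).

```python
import reostrat as rs

spec = rs.SyntheticSpec(seed=7)          # 2 cohorts, 3 subtypes, 2000 genes
cohorts = rs.generate_cohorts(spec)

# feature selection: mean-abundance filter, top-MAD per cohort, intersection
mats = [rs.filter_expressed(c.matrix, 1.0) for c in cohorts]
shared = rs.intersect_features(*[rs.select_top_mad(m, 300) for m in mats])

profiles = {}
for name, m in zip("AB", mats):
    sub = rs.ConsensusNMFSubtyper(rank_range=(2, 4), n_runs=30, max_iter=200,
                                  patience=5, random_state=7)
    sub.fit(m.subset_genes(shared).values.T.to_numpy())
    profiles[name] = sub.cophenetic_
    print(f"cohort {name} cophenetic:",
          {r: round(c, 4) for r, c in sub.cophenetic_.items()})
print("selected rank:", rs.select_rank(profiles))
```

prints

```
cohort A cophenetic: {2: 1.0, 3: 1.0, 4: 0.9989}
cohort B cophenetic: {2: 0.9984, 3: 1.0, 4: 0.9991}
selected rank: 3
```

Cluster stability is perfect at three clusters in both cohorts and degrades
away from it, so three subtypes are selected — matching the generator's
ground truth. Training pair biomarkers on a 70/30 stratified split of the
merged cohorts:

```python
merged = rs.merge_cohorts([c.matrix for c in cohorts])
labels = {**cohorts[0].true_labels, **cohorts[1].true_labels}
train, test = rs.split_train_test(labels, 0.7, seed=7)
clf = rs.REOSubtypeClassifier(
    candidate_genes=rs.select_top_mad(merged.subset_samples(train), 300))
clf.fit(merged.subset_samples(train), [labels[s] for s in train])
for st in clf.classes_:
    m = clf.metrics_[st]
    print(f"subtype {st}: {len(clf.ensemble_.biomarkers[st].pairs)} pair(s), "
          f"train F={m.f_score:.4f}")
print("held-out accuracy:",
      round(clf.score(merged.subset_samples(test),
                      [labels[s] for s in test]), 4))
```

prints

```
subtype 1: 1 pair(s), train F=1.0000
subtype 2: 1 pair(s), train F=1.0000
subtype 3: 1 pair(s), train F=1.0000
held-out accuracy: 0.988
```

On this clean synthetic signal a single reversed pair per subtype already
separates the classes perfectly in training, and 98.8% of held-out samples
are assigned their true subtype by the sequential majority-vote ensemble.

The same pipeline is available from the shell:

```bash
reostrat simulate --out-prefix sim --seed 7
reostrat cluster --matrix sim.cohortA.expression.tsv \
                 --matrix sim.cohortB.expression.tsv \
                 --ranks 2..4 --runs 30 --out-prefix clus
reostrat train-biomarker --matrix sim.cohortA.expression.tsv \
                         --labels sim.cohortA.labels.tsv --out bm.json
reostrat classify --matrix sim.cohortB.expression.tsv \
                  --biomarker bm.json --out calls.tsv
reostrat concordance --deg1 a.tsv --deg2 b.tsv --background 15000
```

A published three-subtype kidney-cancer ensemble (1, 21, and 19 pairs;
subtype 1 is called by the single pair MT-ND5 > RPS27) ships as
`rs.load_fixture_table1()` and can be applied to any matrix containing its
60 genes.

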
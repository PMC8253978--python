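"""Expression filtering, variability-based gene selection, cohort merging,
and stratified train/test splitting.

Feature selection follows the protocol of ranking genes by the mean absolute
deviation of their expression across samples and intersecting the per-cohort
top lists before clustering. Note the deliberate reading of the "MAD"
acronym: here it is the MEAN absolute deviation from the gene's mean (the
protocol spells the acronym out that way), not the median-based robust MAD;
``mad_scores(statistic="median")`` provides the conventional alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "filter_expressed",
    "mad_scores",
    "select_top_mad",
    "intersect_features",
    "merge_cohorts",
    "split_train_test",
]

_LOG_FLOOR = 1e-12  # guards log of exact zeros in batch centering


def filter_expressed(matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose mean abundance is strictly above ``threshold``.

    The sample set is unchanged. Raises if no gene survives, which almost
    always means the threshold is on the wrong scale for the input unit.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = matrix.values.mean(axis=1) > threshold
    if not keep.any():
        raise ValueError(
            f"no gene has mean abundance > {threshold}; "
            "lower the threshold or check the input unit"
        )
    return matrix.subset_genes(matrix.values.index[keep])


def mad_scores(matrix: ExpressionMatrix, statistic: str = "mean") -> pd.Series:
    """Per-gene absolute-deviation variability score across samples.

    statistic="mean" (default): mean |x - mean(x)|, the protocol's reading.
    statistic="median": median |x - median(x)|, the conventional robust MAD.
    """
    if matrix.shape[1] < 2:
        raise ValueError("variability scores need at least 2 samples")
    vals = matrix.values
    if statistic == "mean":
        return (vals.sub(vals.mean(axis=1), axis=0)).abs().mean(axis=1)
    if statistic == "median":
        return (vals.sub(vals.median(axis=1), axis=0)).abs().median(axis=1)
    raise ValueError(f"unknown statistic {statistic!r}")


def select_top_mad(matrix: ExpressionMatrix, top_n: int,
                   statistic: str = "mean") -> list[str]:
    """Gene ids of the ``top_n`` most variable genes, descending score.

    Ties are broken lexicographically by gene id so the list is a pure
    function of the data.
    """
    if top_n > matrix.shape[0]:
        raise ValueError(f"top_n={top_n} exceeds {matrix.shape[0]} genes")
    scores = mad_scores(matrix, statistic=statistic)
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return order[:top_n]


def intersect_features(*lists: list[str]) -> list[str]:
    """Set intersection of >= 2 gene lists, ordered by the first list."""
    if len(lists) < 2:
        raise ValueError("need at least two gene lists")
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    return [g for g in lists[0] if g in common]


def merge_cohorts(cohorts: list[ExpressionMatrix], batch_center: bool = False) -> ExpressionMatrix:
    """Column-concatenate cohorts on their shared gene universe.

    With ``batch_center`` the per-gene per-batch means are equalized in log
    space and re-exponentiated — a deliberately simple stand-in for a
    linear-model batch correction, adequate because downstream rank-based
    features are unaffected by per-sample monotone changes anyway.
    """
    if not cohorts:
        raise ValueError("no cohorts to merge")
    shared = cohorts[0].gene_ids
    for c in cohorts[1:]:
        shared = intersect_features(shared, c.gene_ids)
    if not shared:
        raise ValueError("cohorts share no genes")
    values = pd.concat([c.values.loc[shared] for c in cohorts], axis=1)
    batch: dict[str, str] = {}
    for i, c in enumerate(cohorts):
        for s in c.sample_ids:
            batch[s] = c.batch.get(s, f"cohort{i}")
    merged = ExpressionMatrix(values, cohorts[0].unit, batch)
    if not batch_center:
        return merged
    logv = np.log(np.maximum(merged.values.to_numpy(float), _LOG_FLOOR))
    logdf = pd.DataFrame(logv, index=merged.values.index, columns=merged.values.columns)
    groups = pd.Series(merged.batch)
    grand = logdf.mean(axis=1)
    centered = logdf.copy()
    for b in groups.unique():
        cols = groups.index[groups == b]
        centered[cols] = logdf[cols].sub(logdf[cols].mean(axis=1), axis=0).add(grand, axis=0)
    return ExpressionMatrix(np.exp(centered), merged.unit, dict(merged.batch))


def split_train_test(labels: dict[str, str], fraction: float = 0.7,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified random split of labeled samples into train/test ids.

    Per label class, ``round(fraction * n)`` samples go to train (at least
    one to each side), so per-class proportions are preserved up to integer
    rounding. Deterministic under ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[str]] = {}
    for s, lab in labels.items():
        by_label.setdefault(lab, []).append(s)
    train: list[str] = []
    test: list[str] = []
    for lab in sorted(by_label):
        members = sorted(by_label[lab])
        if len(members) < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 samples; cannot split")
        n_train = int(round(fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        perm = rng.permutation(len(members))
        train += [members[i] for i in perm[:n_train]]
        test += [members[i] for i in perm[n_train:]]
    return sorted(train), sorted(test)
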
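"""Within-sample relative expression orderings (REOs) and stable-pair testing.

The REO of a gene pair (i, j) in one sample is simply which of the two is
more highly expressed. Because it only compares values within a sample, a
REO is invariant to any strictly increasing per-sample transform — library
size scaling, monotone normalization, batch-wide shifts — which is what
makes rank-based pair biomarkers portable across platforms and cohorts.

A pair is *stable* in a group of samples when one orientation dominates far
beyond chance: with n informative samples and k showing the majority
orientation, the upper binomial tail P(X >= k | n, p0 = 1/2) is computed
per pair, BH-adjusted across all tested pairs, and thresholded at a
stringent FDR (1e-7 in the published protocol). A *subtype-specific* pair
is stable in one orientation within the subtype and stable in the reversed
orientation in all remaining samples pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "DirectedGenePair",
    "StablePairResult",
    "reo",
    "stable_pair_pvalue",
    "bh_adjust",
    "find_stable_pairs",
    "find_subtype_specific_pairs",
    "reo_sign_matrix",
]


@dataclass(frozen=True, order=True)
class DirectedGenePair:
    """Ordered pair: ``gene_hi`` expected above ``gene_lo``."""

    gene_hi: str
    gene_lo: str

    def __post_init__(self) -> None:
        if self.gene_hi == self.gene_lo:
            raise ValueError(f"gene pair must name two distinct genes, got {self.gene_hi!r} twice")

    def reversed(self) -> "DirectedGenePair":
        return DirectedGenePair(self.gene_lo, self.gene_hi)


@dataclass
class StablePairResult:
    pair: DirectedGenePair
    group: str
    n: int        # informative samples (ties excluded by default)
    k: int        # samples showing the majority orientation
    p_value: float
    fdr: float


def reo(sample: pd.Series, pair: DirectedGenePair) -> int:
    """+1 if gene_hi > gene_lo in this sample, -1 if below, 0 on an exact tie."""
    for g in (pair.gene_hi, pair.gene_lo):
        if g not in sample.index:
            raise KeyError(f"gene {g!r} missing from sample")
    d = sample[pair.gene_hi] - sample[pair.gene_lo]
    return int(np.sign(d))


def stable_pair_pvalue(n: int, k: int, p0: float = 0.5) -> float:
    """Upper binomial tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def reo_sign_matrix(matrix: ExpressionMatrix, pairs: list[DirectedGenePair],
                    sample_ids: list[str] | None = None) -> np.ndarray:
    """Signs of gene_hi - gene_lo for each pair (rows) x sample (cols)."""
    cols = sample_ids if sample_ids is not None else matrix.sample_ids
    vals = matrix.values[list(cols)]
    missing = {g for p in pairs for g in (p.gene_hi, p.gene_lo)} - set(matrix.gene_ids)
    if missing:
        raise KeyError(f"genes missing from matrix: {sorted(missing)[:10]}")
    hi = vals.loc[[p.gene_hi for p in pairs]].to_numpy(float)
    lo = vals.loc[[p.gene_lo for p in pairs]].to_numpy(float)
    return np.sign(hi - lo).astype(np.int8)


def _as_pairs(candidate_pairs) -> list[DirectedGenePair]:
    out = []
    for p in candidate_pairs:
        out.append(p if isinstance(p, DirectedGenePair) else DirectedGenePair(*p))
    return out


def find_stable_pairs(matrix: ExpressionMatrix, sample_ids: list[str],
                      candidate_pairs, fdr_threshold: float = 1e-7,
                      group: str = "group", tie_policy: str = "exclude",
                      keep_all: bool = False) -> list[StablePairResult]:
    """Test every candidate pair for a stable majority orientation.

    For each candidate, n counts the group samples with a strict ordering
    (exact ties are uninformative and excluded under the default policy;
    ``tie_policy="failure"`` counts them in n but never in k), k is the
    count of the majority orientation, and the returned pair is oriented
    that way. BH adjustment runs across all tested candidates; pairs with
    fdr < ``fdr_threshold`` are returned (all of them if ``keep_all``).
    """
    pairs = _as_pairs(candidate_pairs)
    if not pairs:
        raise ValueError("empty candidate pair universe")
    if tie_policy not in ("exclude", "failure"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    if len(sample_ids) < 24:
        warnings.warn(
            f"group {group!r} has {len(sample_ids)} samples; no unanimous pair can "
            "reach a raw p below 1e-7 with fewer than 24 samples",
            stacklevel=2,
        )
    signs = reo_sign_matrix(matrix, pairs, sample_ids)
    pos = (signs > 0).sum(axis=1)
    neg = (signs < 0).sum(axis=1)
    if tie_policy == "exclude":
        n_eff = pos + neg
    else:
        n_eff = np.full(len(pairs), len(sample_ids))
    k = np.maximum(pos, neg)
    with np.errstate(invalid="ignore"):
        raw = np.where(k > 0, stats.binom.sf(k - 1, np.maximum(n_eff, 1), 0.5), 1.0)
    raw = np.where(n_eff == 0, 1.0, raw)
    fdr = bh_adjust(raw)
    results = []
    for i, pair in enumerate(pairs):
        if not keep_all and not fdr[i] < fdr_threshold:
            continue
        oriented = pair if pos[i] >= neg[i] else pair.reversed()
        results.append(StablePairResult(pair=oriented, group=group, n=int(n_eff[i]),
                                        k=int(k[i]), p_value=float(raw[i]),
                                        fdr=float(fdr[i])))
    return results


def find_subtype_specific_pairs(matrix: ExpressionMatrix, labels: dict[str, str],
                                subtype: str, candidate_pairs,
                                fdr_threshold: float = 1e-7,
                                tie_policy: str = "exclude") -> list[StablePairResult]:
    """Pairs stably ordered one way inside ``subtype`` and reversed outside.

    Stability is assessed independently (with its own BH adjustment) in the
    subtype group and in the pooled remaining samples; a candidate qualifies
    only when both calls pass the FDR cutoff with opposite orientations.
    Results are oriented as (higher-in-subtype, lower-in-subtype) and carry
    the within-subtype test statistics.
    """
    in_group = [s for s, l in labels.items() if l == subtype and s in set(matrix.sample_ids)]
    out_group = [s for s, l in labels.items() if l != subtype and s in set(matrix.sample_ids)]
    if not in_group or not out_group:
        raise ValueError(f"subtype {subtype!r} or its complement is empty")
    inside = find_stable_pairs(matrix, in_group, candidate_pairs, fdr_threshold,
                               group=str(subtype), tie_policy=tie_policy)
    outside = find_stable_pairs(matrix, out_group, candidate_pairs, fdr_threshold,
                                group=f"not-{subtype}", tie_policy=tie_policy)
    reversed_out = {r.pair for r in outside}
    return [r for r in inside if r.pair.reversed() in reversed_out]
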
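"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exact rational arithmetic,
exhaustive enumeration, quadratic clustering — and shares no code with the
implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def binom_upper_tail_exact(n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, 1/2) as an exact rational."""
    return Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2**n)


def hypergeom_upper_tail_exact(L: int, L1: int, L2: int, s: int) -> Fraction:
    """P(X >= s) for X ~ Hypergeom(L, L2, L1) as an exact rational."""
    total = comb(L, L1)
    num = 0
    for i in range(s, min(L1, L2) + 1):
        if L1 - i <= L - L2:
            num += comb(L2, i) * comb(L - L2, L1 - i)
    return Fraction(num, total)


def hypergeom_upper_tail_by_draws(L: int, L1: int, L2: int, s: int) -> Fraction:
    """Same tail by literally enumerating all C(L, L1) draws (tiny L only)."""
    special = set(range(L2))
    hits = sum(1 for draw in combinations(range(L), L1)
               if len(special.intersection(draw)) >= s)
    return Fraction(hits, comb(L, L1))


def average_linkage_cophenetic(D: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix of average-linkage clustering on D.

    Inter-cluster distance is the mean of all original pairwise distances
    between the two clusters (UPGMA). Quadratic, dictionary-based, no scipy.
    """
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        best, best_d = None, np.inf
        for a, b in combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if d < best_d:
                best, best_d = (a, b), d
        a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = best_d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return coph


def cophenetic_coefficient_oracle(consensus: np.ndarray) -> float:
    """Pearson correlation between 1-consensus distances and the cophenetic
    distances of the naive average-linkage tree."""
    D = 1.0 - np.asarray(consensus, float)
    np.fill_diagonal(D, 0.0)
    coph = average_linkage_cophenetic(D)
    iu = np.triu_indices_from(D, k=1)
    x, y = D[iu], coph[iu]
    return float(np.corrcoef(x, y)[0, 1])


def bh_adjust_oracle(pvals) -> np.ndarray:
    """Textbook BH step-up: p_(i) * m / i with right-to-left monotonization."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return adj


def greedy_forward_replay(vote_rows: np.ndarray, is_subtype: np.ndarray):
    """Stepwise replay of greedy F-score forward selection on raw vote rows.

    vote_rows[c, s] is True when candidate pair c votes +1 in sample s.
    Returns the list of selected row indices (in original indexing).
    """
    def f(sel):
        called = vote_rows[sel].sum(axis=0) * 2 > len(sel)
        tp = np.sum(called & is_subtype)
        tn = np.sum(~called & ~is_subtype)
        prec = tp / is_subtype.sum()
        rec = tn / (~is_subtype).sum()
        return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)

    singles = [f([c]) for c in range(len(vote_rows))]
    order = sorted(range(len(vote_rows)), key=lambda c: -singles[c])
    selected = [order[0]]
    remaining = order[1:]
    best = f(selected)
    while remaining:
        scores = [f(selected + [c]) for c in remaining]
        j = int(np.argmax(scores))
        if scores[j] > best + 1e-12:
            best = scores[j]
            selected.append(remaining.pop(j))
        else:
            break
    return selected, best
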
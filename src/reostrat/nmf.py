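"""Brunet-style NMF, consensus clustering, and cophenetic rank selection.

A non-negative expression matrix V (genes x samples) is factorized as
V ~ W H by multiplicative updates that minimize the generalized
Kullback-Leibler divergence

    D(V || WH) = sum_ij V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij .

Each run assigns every sample to its dominant metagene (argmax over the
columns of H). Repeating the factorization from many random starts yields a
consensus matrix of co-clustering frequencies; the cophenetic correlation
between consensus-derived distances and the average-linkage tree built from
them measures cluster stability, and the rank with the highest mean
cophenetic coefficient across cohorts is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "NMFFactors",
    "ConsensusResult",
    "nmf_factorize",
    "run_labels",
    "run_consensus",
    "cophenetic_coefficient",
    "select_rank",
    "assign_final",
    "match_subtypes_across_cohorts",
    "ConsensusNMFSubtyper",
]

_EPS = 1e-12  # guards divisions inside multiplicative updates


@dataclass
class NMFFactors:
    """One converged factorization V ~ W H with its objective trace."""

    W: np.ndarray  # genes x rank, non-negative
    H: np.ndarray  # rank x samples, non-negative
    divergence: float  # final KL objective
    n_iter: int
    seed: int
    trace: list[float] = field(default_factory=list)  # objective at each check


@dataclass
class ConsensusResult:
    """Co-clustering frequencies over repeated runs at one rank."""

    rank: int
    consensus: np.ndarray  # samples x samples, symmetric, unit diagonal
    n_runs: int
    cophenetic: float
    sample_ids: list[str] | None = None


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = float(np.sum(WH - V))
    div += float(np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))))
    return div


def nmf_factorize(V: np.ndarray, rank: int, seed: int = 0, max_iter: int = 2000,
                  check_every: int = 10, patience: int = 40) -> NMFFactors:
    """Multiplicative-update KL NMF with connectivity-stability stopping.

    Every ``check_every`` iterations the sample partition implied by H is
    recomputed; the run stops once it has been unchanged for ``patience``
    consecutive checks, or at ``max_iter``. ``patience`` and ``check_every``
    trade runtime for certainty that the partition has settled.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-d matrix")
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    if rank >= min(V.shape):
        raise ValueError(f"rank {rank} must be < min matrix dimension {min(V.shape)}")
    if (V.sum(axis=1) == 0).any() or (V.sum(axis=0) == 0).any():
        raise ValueError("V has an all-zero row or column; filter before factorizing")

    rng = np.random.default_rng(seed)
    n, m = V.shape
    # uniform(0,1] initialization: 1 - uniform[0,1)
    W = 1.0 - rng.random((n, rank))
    H = 1.0 - rng.random((rank, m))

    trace: list[float] = []
    prev_assign = None
    stable = 0
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H
        H *= (W.T @ (V / np.maximum(WH, _EPS))) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H
        W *= ((V / np.maximum(WH, _EPS)) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if not (np.isfinite(W).all() and np.isfinite(H).all()):
            raise FloatingPointError("NaN/inf in multiplicative update despite epsilon guard")
        if it % check_every == 0 or it == max_iter:
            trace.append(_kl_divergence(V, W @ H))
            assign = np.argmax(H, axis=0)
            if prev_assign is not None and np.array_equal(assign, prev_assign):
                stable += 1
            else:
                stable = 0
            prev_assign = assign
            if stable >= patience:
                break
    return NMFFactors(W=W, H=H, divergence=_kl_divergence(V, W @ H),
                      n_iter=it, seed=seed, trace=trace)


def run_labels(factors: NMFFactors) -> np.ndarray:
    """Per-sample cluster index: argmax over metagene coefficients.

    Ties go to the lowest index (numpy argmax convention).
    """
    return np.argmax(factors.H, axis=0)


def _connectivity(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Stability of a consensus matrix.

    Pearson correlation between the off-diagonal entries of
    D = 1 - consensus and the cophenetic distances of the average-linkage
    dendrogram built on D. 1.0 means the consensus is perfectly ultrametric
    (samples co-cluster either always or never).
    """
    C = np.asarray(consensus, dtype=float)
    if C.shape[0] != C.shape[1] or C.shape[0] < 3:
        raise ValueError("consensus must be square with >= 3 samples")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("consensus must be symmetric")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    dvec = squareform(D, checks=False)
    if np.ptp(dvec) == 0:
        raise ValueError("all pairwise consensus distances equal; cophenetic undefined")
    Z = hierarchy.linkage(dvec, method="average")
    coph = hierarchy.cophenet(Z)
    if np.ptp(coph) == 0:
        raise ValueError("cophenetic distances constant; correlation undefined")
    return float(np.corrcoef(dvec, coph)[0, 1])


def run_consensus(V: np.ndarray, rank: int, n_runs: int = 200, seed: int = 0,
                  max_iter: int = 2000, check_every: int = 10, patience: int = 40,
                  sample_ids: list[str] | None = None) -> ConsensusResult:
    """Average connectivity over ``n_runs`` random-start factorizations.

    Run seeds are derived from ``seed`` by a counter, so the full consensus
    is reproducible from one integer.
    """
    if n_runs < 2:
        raise ValueError("consensus needs n_runs >= 2")
    V = np.asarray(V, dtype=float)
    m = V.shape[1]
    acc = np.zeros((m, m))
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    for r in range(n_runs):
        fac = nmf_factorize(V, rank, seed=int((base + r) % (2**31)),
                            max_iter=max_iter, check_every=check_every,
                            patience=patience)
        acc += _connectivity(run_labels(fac))
    consensus = acc / n_runs
    np.fill_diagonal(consensus, 1.0)
    coph = cophenetic_coefficient(consensus)
    return ConsensusResult(rank=rank, consensus=consensus, n_runs=n_runs,
                           cophenetic=coph, sample_ids=sample_ids)


def select_rank(profiles: dict[str, dict[int, float]]) -> int:
    """Rank with the highest across-cohort mean cophenetic coefficient.

    All cohorts must share the same rank grid; exact ties resolve to the
    smallest rank.
    """
    if not profiles:
        raise ValueError("empty cophenetic profiles")
    grids = [tuple(sorted(p)) for p in profiles.values()]
    if len(set(grids)) != 1:
        raise ValueError("cohorts evaluated on different rank grids")
    ranks = sorted(grids[0])
    means = {r: float(np.mean([p[r] for p in profiles.values()])) for r in ranks}
    return min(ranks, key=lambda r: (-means[r], r))


def assign_final(result: ConsensusResult) -> dict[str, int]:
    """Final subtype labels from the consensus matrix.

    The average-linkage tree of 1 - consensus is cut into ``rank`` clusters;
    cluster indices are renumbered 1..rank by descending cluster size (ties
    by first occurrence) so labels are deterministic.
    """
    C = result.consensus
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=result.rank, criterion="maxclust")
    sizes = {c: np.sum(raw == c) for c in np.unique(raw)}
    order = sorted(sizes, key=lambda c: (-sizes[c], np.argmax(raw == c)))
    remap = {c: i + 1 for i, c in enumerate(order)}
    ids = result.sample_ids or [str(i) for i in range(len(raw))]
    return {ids[i]: remap[raw[i]] for i in range(len(raw))}


def match_subtypes_across_cohorts(
    cohort_a: tuple[np.ndarray, dict[str, int], list[str], list[str]],
    cohort_b: tuple[np.ndarray, dict[str, int], list[str], list[str]],
    shared_genes: list[str] | None = None,
) -> dict[int, int]:
    """Match cluster numbering of cohort B to cohort A by centroid similarity.

    Each cohort is (values genes x samples, labels, gene_ids, sample_ids).
    Centroids are per-cluster mean log1p expression over the shared genes;
    the permutation of B's labels maximizing the summed Pearson correlation
    with A's centroids is found by exhaustive search over all rank!
    permutations. Returns {old B label: new (A-aligned) label}.
    """
    Va, la, ga, sa = cohort_a
    Vb, lb, gb, sb = cohort_b
    ka, kb = sorted(set(la.values())), sorted(set(lb.values()))
    if len(ka) != len(kb):
        raise ValueError(f"rank mismatch: {len(ka)} vs {len(kb)} clusters")
    if shared_genes is None:
        shared_genes = [g for g in ga if g in set(gb)]
    ia = [ga.index(g) for g in shared_genes]
    ib = [gb.index(g) for g in shared_genes]

    def centroids(V, idx, labels, sample_ids, clusters):
        L = np.log1p(np.asarray(V, float)[idx])
        out = {}
        for c in clusters:
            cols = [j for j, s in enumerate(sample_ids) if labels[s] == c]
            out[c] = L[:, cols].mean(axis=1)
        return out

    ca = centroids(Va, ia, la, sa, ka)
    cb = centroids(Vb, ib, lb, sb, kb)
    corr = {
        (x, y): float(np.corrcoef(ca[x], cb[y])[0, 1]) for x in ka for y in kb
    }
    best, best_score = None, -np.inf
    for perm in permutations(kb):
        score = sum(corr[(ka[i], perm[i])] for i in range(len(ka)))
        if score > best_score:
            best, best_score = perm, score
    return {best[i]: ka[i] for i in range(len(ka))}


class ConsensusNMFSubtyper(ClusterMixin, BaseEstimator):
    """Consensus NMF clustering with cophenetic rank selection.

    scikit-learn style estimator: ``fit(X)`` expects a samples x features
    non-negative matrix. For each rank in ``rank_range`` it pools
    ``n_runs`` random-start KL-NMF factorizations into a consensus matrix,
    scores its stability by the cophenetic correlation coefficient, selects
    the most stable rank, and assigns final labels by cutting the
    average-linkage tree of the selected consensus.

    Parameters
    ----------
    rank_range : tuple (lo, hi), inclusive grid of candidate cluster counts.
    n_runs : random restarts per rank.
    rank : fix the rank instead of selecting it (rank_range then ignored).
    max_iter, check_every, patience : stopping rule of each NMF run.
    random_state : master seed.

    Attributes
    ----------
    consensus_results_ : dict rank -> ConsensusResult
    cophenetic_ : dict rank -> float
    rank_ : selected number of clusters
    labels_ : final integer labels (1-based), one per sample
    """

    def __init__(self, rank_range: tuple[int, int] = (2, 8), n_runs: int = 200,
                 rank: int | None = None, max_iter: int = 2000,
                 check_every: int = 10, patience: int = 40,
                 random_state: int = 0):
        self.rank_range = rank_range
        self.n_runs = n_runs
        self.rank = rank
        self.max_iter = max_iter
        self.check_every = check_every
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        if (X < 0).any():
            raise ValueError("expression values must be non-negative")
        V = X.T  # genes x samples
        ranks = ([self.rank] if self.rank is not None
                 else list(range(self.rank_range[0], self.rank_range[1] + 1)))
        self.consensus_results_ = {}
        self.cophenetic_ = {}
        for r in ranks:
            res = run_consensus(V, r, n_runs=self.n_runs,
                                seed=(self.random_state or 0) + 1000 * r,
                                max_iter=self.max_iter,
                                check_every=self.check_every,
                                patience=self.patience)
            self.consensus_results_[r] = res
            self.cophenetic_[r] = res.cophenetic
        self.rank_ = select_rank({"self": self.cophenetic_})
        final = assign_final(self.consensus_results_[self.rank_])
        self.labels_ = np.array([final[str(i)] for i in range(X.shape[0])])
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @property
    def consensus_(self):
        check_is_fitted(self)
        return self.consensus_results_[self.rank_].consensus
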
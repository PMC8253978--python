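"""Majority-vote REO biomarkers, F-score forward selection, and the
sequential subtype classifier.

A *biomarker* for one subtype is an ordered set of directed gene pairs; a
sample votes for the subtype when strictly more than half of the pairs show
gene_hi > gene_lo in that sample. An *ensemble* holds one biomarker per
subtype plus an application order: biomarkers are applied in sequence and
the first one whose majority fires labels the sample; a sample that fires
none is left unassigned.

Evaluation follows the protocol's own (nonstandard) definitions:
``precision`` is the fraction of subtype samples correctly called positive
(i.e. sensitivity) and ``recall`` is the fraction of non-subtype samples
correctly called negative (i.e. specificity); the F-score is their harmonic
mean. ``standard_metrics=True`` switches to the conventional definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix
from .pairs import (DirectedGenePair, find_subtype_specific_pairs, reo,
                    reo_sign_matrix)

__all__ = [
    "Biomarker",
    "ClassifierEnsemble",
    "EvalMetrics",
    "UNASSIGNED",
    "evaluate",
    "f_score",
    "forward_select",
    "classify_sample",
    "classify_matrix",
    "REOSubtypeClassifier",
]

UNASSIGNED = "unassigned"


@dataclass
class Biomarker:
    """Per-subtype ordered pair set with a strict-majority voting rule."""

    subtype: str
    pairs: list[DirectedGenePair]
    vote_rule: str = "strict-majority"

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"biomarker for subtype {self.subtype!r} has no pairs")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError(f"duplicate pairs in biomarker for subtype {self.subtype!r}")
        if self.vote_rule != "strict-majority":
            raise ValueError(f"unknown vote rule {self.vote_rule!r}")

    def votes(self, sample: pd.Series) -> bool:
        """True when strictly more than half of the pairs show gene_hi > gene_lo."""
        hits = sum(1 for p in self.pairs if reo(sample, p) == +1)
        return 2 * hits > len(self.pairs)


@dataclass
class ClassifierEnsemble:
    """One biomarker per subtype plus the order in which they are applied."""

    biomarkers: dict[str, Biomarker]
    application_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.biomarkers:
            raise ValueError("ensemble has no biomarkers")
        if not self.application_order:
            self.application_order = sorted(self.biomarkers)
        if sorted(self.application_order) != sorted(self.biomarkers):
            raise ValueError("application_order must be a permutation of the biomarker subtypes")

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for b in self.biomarkers.values():
            for p in b.pairs:
                out |= {p.gene_hi, p.gene_lo}
        return sorted(out)


@dataclass
class EvalMetrics:
    precision: float
    recall: float
    f_score: float
    tp: int
    fp: int
    tn: int
    fn: int


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both inputs are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _metrics_from_calls(called: np.ndarray, is_subtype: np.ndarray,
                        standard_metrics: bool = False) -> EvalMetrics:
    tp = int(np.sum(called & is_subtype))
    fn = int(np.sum(~called & is_subtype))
    tn = int(np.sum(~called & ~is_subtype))
    fp = int(np.sum(called & ~is_subtype))
    if standard_metrics:
        num_p, den_p = tp, tp + fp
        num_r, den_r = tp, tp + fn
    else:
        num_p, den_p = tp, tp + fn   # fraction of subtype samples caught
        num_r, den_r = tn, tn + fp   # fraction of non-subtype samples rejected
    if den_p == 0 or den_r == 0:
        warnings.warn("empty subtype or complement group; affected metric reported as 0",
                      stacklevel=3)
    precision = num_p / den_p if den_p else 0.0
    recall = num_r / den_r if den_r else 0.0
    return EvalMetrics(precision=precision, recall=recall,
                       f_score=f_score(precision, recall),
                       tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate(pairs: list[DirectedGenePair], matrix: ExpressionMatrix,
             labels: dict[str, str], subtype: str,
             standard_metrics: bool = False) -> EvalMetrics:
    """Score a pair set as a one-vs-rest voter for ``subtype``.

    A sample is called subtype-positive iff strictly more than half of the
    pairs show gene_hi > gene_lo in it.
    """
    if not pairs:
        raise ValueError("cannot evaluate an empty pair set")
    samples = matrix.sample_ids
    signs = reo_sign_matrix(matrix, list(pairs), samples)
    called = 2 * (signs > 0).sum(axis=0) > len(pairs)
    is_subtype = np.array([labels[s] == subtype for s in samples])
    return _metrics_from_calls(called, is_subtype, standard_metrics)


def forward_select(candidates: list[DirectedGenePair], matrix: ExpressionMatrix,
                   labels: dict[str, str], subtype: str,
                   p_values: dict[DirectedGenePair, float] | None = None,
                   max_candidates: int | None = None) -> Biomarker:
    """Greedy forward selection of a pair subset maximizing the F-score.

    The single best pair seeds the set; each round tentatively adds every
    remaining candidate and keeps the one giving the largest strict F-score
    improvement; selection stops when no candidate improves F. Candidates
    are scanned in a deterministic order: descending single-pair F, ties by
    smaller stability p-value (when given) then lexicographic pair id.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("no candidate pairs to select from")
    samples = matrix.sample_ids
    is_subtype = np.array([labels[s] == subtype for s in samples])
    pos = (reo_sign_matrix(matrix, cands, samples) > 0)  # candidates x samples

    y_pos = is_subtype.astype(np.int64)
    y_neg = (~is_subtype).astype(np.int64)

    def f_of_counts(counts: np.ndarray, size: int) -> np.ndarray:
        called = (2 * counts > size).astype(np.int64)
        tp = called @ y_pos
        tn = (1 - called) @ y_neg
        prec = np.divide(tp, is_subtype.sum()) if is_subtype.sum() else np.zeros_like(tp, float)
        rec = np.divide(tn, (~is_subtype).sum()) if (~is_subtype).sum() else np.zeros_like(tn, float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
        return np.atleast_1d(f)

    f_single = f_of_counts(pos.astype(int), 1)
    pv = p_values or {}
    order = sorted(range(len(cands)),
                   key=lambda i: (-f_single[i], pv.get(cands[i], 1.0),
                                  (cands[i].gene_hi, cands[i].gene_lo)))
    if max_candidates is not None:
        order = order[:max_candidates]
    pos = pos[order]
    cands = [cands[i] for i in order]

    selected = [0]
    counts = pos[0].astype(int)
    best_f = float(f_of_counts(counts[None, :], 1)[0])
    remaining = list(range(1, len(cands)))
    while remaining:
        trial = counts[None, :] + pos[remaining].astype(int)
        fs = f_of_counts(trial, len(selected) + 1)
        j = int(np.argmax(fs))
        if fs[j] > best_f + 1e-12:
            pick = remaining.pop(j)
            selected.append(pick)
            counts += pos[pick].astype(int)
            best_f = float(fs[j])
        else:
            break
    return Biomarker(subtype=subtype, pairs=[cands[i] for i in selected])


def classify_sample(sample: pd.Series, ensemble: ClassifierEnsemble) -> str:
    """Label one sample: first biomarker (in application order) whose
    strict-majority vote fires wins; none firing leaves it unassigned."""
    missing = [g for g in ensemble.genes if g not in sample.index]
    if missing:
        raise KeyError(f"sample lacks biomarker genes: {missing}")
    for subtype in ensemble.application_order:
        if ensemble.biomarkers[subtype].votes(sample):
            return subtype
    return UNASSIGNED


def classify_matrix(matrix: ExpressionMatrix, ensemble: ClassifierEnsemble) -> dict[str, str]:
    """Vectorized classify_sample over every column of the matrix."""
    samples = matrix.sample_ids
    out = {s: UNASSIGNED for s in samples}
    undecided = np.ones(len(samples), dtype=bool)
    for subtype in ensemble.application_order:
        bm = ensemble.biomarkers[subtype]
        signs = reo_sign_matrix(matrix, bm.pairs, samples)
        fires = 2 * (signs > 0).sum(axis=0) > len(bm.pairs)
        hit = fires & undecided
        for i in np.flatnonzero(hit):
            out[samples[i]] = subtype
        undecided &= ~fires
    return out


class REOSubtypeClassifier(ClassifierMixin, BaseEstimator):
    """Rank-based subtype classifier trained from labeled expression data.

    scikit-learn style estimator over samples x genes input (a DataFrame
    whose columns are gene ids, or an array plus ``gene_names``). ``fit``
    discovers subtype-specific reversed gene pairs by binomial stable-pair
    testing at ``fdr_threshold`` and condenses each subtype's pairs into a
    compact biomarker by F-score forward selection. ``predict`` applies the
    biomarkers sequentially and returns the first firing subtype, or
    ``"unassigned"``.

    Parameters
    ----------
    fdr_threshold : BH FDR cutoff for stable-pair calls (default 1e-7).
    candidate_genes : optional list of gene ids forming the pair universe;
        by default all genes in X are used. All unordered pairs over this
        universe are tested — keep it to a few hundred genes.
    max_pairs : guard rail; raise if the pair universe exceeds this.
    max_candidates : cap on pairs entering forward selection per subtype.
    tie_policy : how exact expression ties enter the binomial test.
    gene_names : required when X is a bare array.

    Attributes
    ----------
    ensemble_ : trained ClassifierEnsemble
    specific_pairs_ : dict subtype -> list of StablePairResult
    metrics_ : dict subtype -> training EvalMetrics
    classes_ : sorted subtype labels seen in fit
    """

    def __init__(self, fdr_threshold: float = 1e-7,
                 candidate_genes: list[str] | None = None,
                 max_pairs: int = 10_000_000,
                 max_candidates: int | None = None,
                 tie_policy: str = "exclude",
                 gene_names: list[str] | None = None):
        self.fdr_threshold = fdr_threshold
        self.candidate_genes = candidate_genes
        self.max_pairs = max_pairs
        self.max_candidates = max_candidates
        self.tie_policy = tie_policy
        self.gene_names = gene_names

    def _to_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix(X.T)
        X = np.asarray(X, dtype=float)
        if self.gene_names is None:
            raise ValueError("array input needs gene_names")
        genes = list(self.gene_names)
        df = pd.DataFrame(X.T, index=genes,
                          columns=[f"s{i}" for i in range(X.shape[0])])
        return ExpressionMatrix(df)

    def fit(self, X, y):
        matrix = self._to_matrix(X)
        y = np.asarray(y)
        if len(y) != matrix.shape[1]:
            raise ValueError("y length must equal the number of samples")
        labels = {s: str(lab) for s, lab in zip(matrix.sample_ids, y)}
        self.classes_ = np.array(sorted({str(v) for v in y}))

        universe = self.candidate_genes or matrix.gene_ids
        missing = set(universe) - set(matrix.gene_ids)
        if missing:
            raise ValueError(f"candidate genes absent from X: {sorted(missing)[:5]}")
        n_pairs = len(universe) * (len(universe) - 1) // 2
        if n_pairs > self.max_pairs:
            raise ValueError(
                f"{n_pairs} candidate pairs exceed max_pairs={self.max_pairs}; "
                "restrict candidate_genes"
            )
        cand = [DirectedGenePair(a, b)
                for i, a in enumerate(universe) for b in universe[i + 1:]]

        self.specific_pairs_ = {}
        biomarkers = {}
        self.metrics_ = {}
        for subtype in self.classes_:
            hits = find_subtype_specific_pairs(
                matrix, labels, subtype, cand,
                fdr_threshold=self.fdr_threshold, tie_policy=self.tie_policy)
            self.specific_pairs_[subtype] = hits
            if not hits:
                raise ValueError(
                    f"no subtype-specific pairs found for {subtype!r} at "
                    f"FDR < {self.fdr_threshold}; more samples or a richer "
                    "candidate universe are needed"
                )
            bm = forward_select([h.pair for h in hits], matrix, labels, subtype,
                                p_values={h.pair: h.p_value for h in hits},
                                max_candidates=self.max_candidates)
            biomarkers[subtype] = bm
            self.metrics_[subtype] = evaluate(bm.pairs, matrix, labels, subtype)
        self.ensemble_ = ClassifierEnsemble(
            biomarkers=biomarkers, application_order=list(self.classes_))
        self.n_features_in_ = matrix.shape[0]
        return self

    def predict(self, X):
        check_is_fitted(self)
        matrix = self._to_matrix(X)
        calls = classify_matrix(matrix, self.ensemble_)
        return np.array([calls[s] for s in matrix.sample_ids])

    def score(self, X, y):
        """Fraction of samples assigned their true subtype (unassigned counts
        as wrong)."""
        pred = self.predict(X)
        return float(np.mean(pred == np.asarray([str(v) for v in y])))
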
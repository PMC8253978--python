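"""Voting, evaluation metrics, forward selection, and the ensemble classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reostrat import (Biomarker, ClassifierEnsemble, DirectedGenePair,
                      ExpressionMatrix, REOSubtypeClassifier, UNASSIGNED,
                      classify_matrix, classify_sample, evaluate,
                      forward_select, load_fixture_table1)
from reostrat.classifier import f_score

from oracles import greedy_forward_replay


def _matrix(df_rows: dict, n: int, prefix="s"):
    df = pd.DataFrame(df_rows).T
    df.columns = [f"{prefix}{i}" for i in range(n)]
    return ExpressionMatrix(df)


def _vote_instance(vote_rows: np.ndarray, is_subtype: np.ndarray):
    """Build an expression matrix in which pair i votes exactly vote_rows[i]."""
    n_pairs, n_samples = vote_rows.shape
    rows = {}
    pairs = []
    for i in range(n_pairs):
        hi, lo = f"hi{i}", f"lo{i}"
        rows[hi] = [2.0 if v else 1.0 for v in vote_rows[i]]
        rows[lo] = [1.5] * n_samples
        pairs.append(DirectedGenePair(hi, lo))
    m = _matrix(rows, n_samples)
    labels = {s: ("T" if flag else "F")
              for s, flag in zip(m.sample_ids, is_subtype)}
    return m, labels, pairs


class TestEvaluate:
    @given(st.floats(0.05, 1.0))
    def test_harmonic_mean_fixed_point(self, x):
        assert f_score(x, x) == pytest.approx(x)

    def test_f_between_precision_and_recall(self, rng):
        for _ in range(50):
            p, r = rng.uniform(0.01, 1.0, 2)
            f = f_score(p, r)
            assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12

    def test_counting_on_constructed_votes(self):
        votes = np.array([[1, 1, 1, 0, 1, 0, 0, 0]], dtype=bool)
        is_subtype = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        m, labels, pairs = _vote_instance(votes, is_subtype)
        res = evaluate(pairs, m, labels, "T")
        # 3 of 4 subtype samples caught, 3 of 4 non-subtype rejected
        assert (res.tp, res.fn, res.tn, res.fp) == (3, 1, 3, 1)
        assert res.precision == pytest.approx(0.75)
        assert res.recall == pytest.approx(0.75)
        assert res.f_score == pytest.approx(0.75)

    def test_standard_metrics_option(self):
        votes = np.array([[1, 1, 1, 0, 1, 0, 0, 0]], dtype=bool)
        is_subtype = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        m, labels, pairs = _vote_instance(votes, is_subtype)
        res = evaluate(pairs, m, labels, "T", standard_metrics=True)
        assert res.precision == pytest.approx(3 / 4)  # TP / (TP + FP)
        assert res.recall == pytest.approx(3 / 4)     # TP / (TP + FN)

    def test_even_biomarker_exact_half_does_not_fire(self):
        votes = np.array([[1, 1], [0, 1]], dtype=bool)  # sample0: 1 of 2 pairs
        is_subtype = np.array([1, 1], dtype=bool)
        m, labels, pairs = _vote_instance(votes, is_subtype)
        with pytest.warns(UserWarning):
            res = evaluate(pairs, m, labels, "T")
        assert res.tp == 1  # only sample1 (2 of 2) passes the strict majority

    def test_empty_complement_warns_and_zeroes(self):
        votes = np.array([[1, 1]], dtype=bool)
        is_subtype = np.array([1, 1], dtype=bool)
        m, labels, pairs = _vote_instance(votes, is_subtype)
        with pytest.warns(UserWarning, match="empty"):
            res = evaluate(pairs, m, labels, "T")
        assert res.recall == 0.0


class TestForwardSelect:
    def test_single_candidate(self):
        votes = np.array([[1, 0]], dtype=bool)
        m, labels, pairs = _vote_instance(votes, np.array([1, 0], dtype=bool))
        bm = forward_select(pairs, m, labels, "T")
        assert bm.pairs == pairs

    def test_constructed_three_candidate_instance(self):
        # A alone is the best seed; adding B improves; C never helps.
        is_subtype = np.array([1] * 5 + [0] * 5, dtype=bool)
        votes = np.array([
            [1, 1, 1, 1, 0, 1, 0, 0, 0, 0],   # A: F=.8; seeds the set
            [1, 1, 1, 1, 1, 0, 1, 1, 0, 0],   # B: F=.75 alone; {A,B}=.889
            [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],   # C: F=1/3; never helps
        ], dtype=bool)
        m, labels, pairs = _vote_instance(votes, is_subtype)
        bm = forward_select(pairs, m, labels, "T")
        sel, best = greedy_forward_replay(votes, is_subtype)
        assert {p.gene_hi for p in bm.pairs} == {f"hi{i}" for i in sel}
        got = evaluate(bm.pairs, m, labels, "T").f_score
        assert got == pytest.approx(best)
        # exhaustive check: no subset reachable by the greedy rule beats it
        from itertools import combinations
        for r in range(1, 4):
            for subset in combinations(range(3), r):
                rows = votes[list(subset)]
                called = rows.sum(axis=0) * 2 > len(subset)
                tp = np.sum(called & is_subtype)
                tn = np.sum(~called & ~is_subtype)
                f = f_score(tp / 5, tn / 5)
                if set(subset) == {i for i in sel}:
                    assert f == pytest.approx(got)

    def test_random_instances_match_stepwise_replay(self, rng):
        for trial in range(10):
            votes = rng.random((6, 24)) < 0.5
            is_subtype = np.arange(24) < 10
            # make candidate 0 clearly informative so the seed is unique
            votes[0] = is_subtype.copy()
            m, labels, pairs = _vote_instance(votes, is_subtype)
            bm = forward_select(pairs, m, labels, "T")
            f_impl = evaluate(bm.pairs, m, labels, "T").f_score
            _, f_replay = greedy_forward_replay(votes, is_subtype)
            assert f_impl == pytest.approx(f_replay), f"trial {trial}"

    def test_never_below_best_single(self, rng):
        votes = rng.random((8, 30)) < 0.4
        is_subtype = np.arange(30) < 12
        m, labels, pairs = _vote_instance(votes, is_subtype)
        bm = forward_select(pairs, m, labels, "T")
        best_single = max(evaluate([p], m, labels, "T").f_score for p in pairs)
        assert evaluate(bm.pairs, m, labels, "T").f_score >= best_single - 1e-12

    def test_empty_candidates_error(self, small_matrix):
        with pytest.raises(ValueError, match="no candidate"):
            forward_select([], small_matrix, {}, "1")


class TestClassify:
    def _toy_ensemble(self):
        return ClassifierEnsemble(
            biomarkers={
                "1": Biomarker("1", [DirectedGenePair("a", "b")]),
                "2": Biomarker("2", [DirectedGenePair("c", "d"),
                                     DirectedGenePair("e", "f"),
                                     DirectedGenePair("g", "h")]),
            },
            application_order=["1", "2"],
        )

    def test_first_firing_biomarker_wins(self):
        ens = self._toy_ensemble()
        s = pd.Series({"a": 2.0, "b": 1.0, "c": 2.0, "d": 1.0,
                       "e": 2.0, "f": 1.0, "g": 2.0, "h": 1.0})
        assert classify_sample(s, ens) == "1"  # subtype 2 also fires, but later

    def test_majority_counting(self):
        ens = self._toy_ensemble()
        s = pd.Series({"a": 1.0, "b": 2.0,           # biomarker 1 silent
                       "c": 2.0, "d": 1.0, "e": 2.0, "f": 1.0,  # 2 of 3
                       "g": 1.0, "h": 2.0})
        assert classify_sample(s, ens) == "2"

    def test_unassigned_when_nothing_fires(self):
        ens = self._toy_ensemble()
        s = pd.Series({k: 1.0 + 0.1 * i for i, k in enumerate("bdfh")} |
                      {k: 0.5 for k in "aceg"})
        assert classify_sample(s, ens) == UNASSIGNED

    def test_missing_gene_listed(self):
        ens = self._toy_ensemble()
        with pytest.raises(KeyError, match="'h'"):
            classify_sample(pd.Series({k: 1.0 for k in "abcdefg"}), ens)

    def test_matrix_classification_agrees_with_per_sample(self, rng):
        ens = self._toy_ensemble()
        genes = list("abcdefgh")
        df = pd.DataFrame(rng.uniform(0.5, 2.0, (8, 25)), index=genes,
                          columns=[f"s{i}" for i in range(25)])
        m = ExpressionMatrix(df)
        bulk = classify_matrix(m, ens)
        for s in m.sample_ids:
            assert bulk[s] == classify_sample(m.sample(s), ens)

    def test_reo_orientation_antisymmetry(self, rng):
        from reostrat import reo
        s = pd.Series(rng.uniform(0, 5, 6), index=list("abcdef"))
        for hi, lo in [("a", "b"), ("c", "f")]:
            p = DirectedGenePair(hi, lo)
            assert reo(s, p) == -reo(s, p.reversed())


class TestTable1Fixture:
    def test_published_pair_counts(self):
        ens = load_fixture_table1()
        assert [len(ens.biomarkers[s].pairs) for s in ("1", "2", "3")] == [1, 21, 19]
        assert ens.application_order == ["1", "2", "3"]

    def test_subtype1_pair_identity(self):
        ens = load_fixture_table1()
        assert ens.biomarkers["1"].pairs == [DirectedGenePair("MT-ND5", "RPS27")]

    def test_mtnd5_above_rps27_classifies_subtype1(self, rng):
        ens = load_fixture_table1()
        s = pd.Series(rng.uniform(1, 2, len(ens.genes)), index=ens.genes)
        s["MT-ND5"], s["RPS27"] = 10.0, 3.0
        assert classify_sample(s, ens) == "1"


class TestREOSubtypeClassifierEstimator:
    def test_sklearn_get_set_clone(self):
        from sklearn.base import clone
        est = REOSubtypeClassifier(fdr_threshold=1e-5, max_candidates=50)
        assert clone(est).get_params() == est.get_params()
        est.set_params(fdr_threshold=1e-7)
        assert est.fdr_threshold == 1e-7

    def test_fit_predict_recovers_planted_subtypes(self, tiny_study):
        spec, cohorts = tiny_study
        m = cohorts[0].matrix
        labels = cohorts[0].true_labels
        universe = [g for st_ in spec.subtypes
                    for half in spec.marker_genes(st_) for g in half]
        est = REOSubtypeClassifier(candidate_genes=universe)
        y = [labels[s] for s in m.sample_ids]
        est.fit(m, y)
        assert list(est.classes_) == ["1", "2", "3"]
        acc = est.score(m, y)
        assert acc >= 0.95
        preds = est.predict(m)
        assert set(preds) <= {"1", "2", "3", UNASSIGNED}

    def test_dataframe_and_array_inputs(self, tiny_study):
        spec, cohorts = tiny_study
        m = cohorts[0].matrix
        labels = cohorts[0].true_labels
        up, down = spec.marker_genes("1")
        universe = up[:5] + down[:5]
        y = [labels[s] for s in m.sample_ids]
        sub = m.values.loc[universe]
        df_est = REOSubtypeClassifier().fit(sub.T, ["1" if v == "1" else "rest"
                                                    for v in y])
        arr_est = REOSubtypeClassifier(gene_names=universe).fit(
            sub.T.to_numpy(), ["1" if v == "1" else "rest" for v in y])
        assert df_est.ensemble_.biomarkers.keys() == arr_est.ensemble_.biomarkers.keys()

    def test_pair_universe_guard(self, tiny_study):
        _, cohorts = tiny_study
        m = cohorts[0].matrix
        est = REOSubtypeClassifier(max_pairs=10)
        with pytest.raises(ValueError, match="max_pairs"):
            est.fit(m, [cohorts[0].true_labels[s] for s in m.sample_ids])

    def test_unfitted_predict_raises(self, small_matrix):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            REOSubtypeClassifier().predict(small_matrix)
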
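"""Confusion metrics, threshold grid search and descriptor ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from molprofiler.drugfilters import Direction
from molprofiler.screening import (
    ConfusionCounts, confusion, grid_search_threshold, metrics, rank_descriptors,
)

from conftest import brute_force_best_ga, metrics_by_hand


class TestConfusion:
    def test_all_correct(self):
        cc = confusion([True] * 10 + [False] * 10, [True] * 10 + [False] * 10)
        assert (cc.TP, cc.TN, cc.FP, cc.FN) == (10, 10, 0, 0)

    def test_all_inverted(self):
        cc = confusion([False] * 10 + [True] * 10, [True] * 10 + [False] * 10)
        assert cc.TP == 0 and cc.TN == 0 and cc.FP == 10 and cc.FN == 10

    def test_hand_tally(self):
        pred = [True, True, False, False, True, False]
        lab = [True, False, True, False, True, False]
        cc = confusion(pred, lab)
        assert (cc.TP, cc.TN, cc.FP, cc.FN) == (2, 2, 1, 1)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])
        with pytest.raises(ValueError):
            confusion([], [])


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(50, 50, 0, 0))
        assert m.SE == m.SP == m.GA == 1.0 and m.C == 1.0

    def test_hand_worked_table(self):
        m = metrics(ConfusionCounts(TP=40, TN=30, FP=20, FN=10))
        assert m.SE == pytest.approx(0.8)
        assert m.SP == pytest.approx(0.6)
        assert m.GA == pytest.approx(0.7)
        assert m.C == pytest.approx(1000 / math.sqrt(6_000_000), abs=1e-12)

    def test_anti_perfect_classification_gives_minus_one(self):
        m = metrics(ConfusionCounts(TP=0, TN=0, FP=10, FN=10))
        assert m.GA == 0.0 and m.C == pytest.approx(-1.0)

    def test_zero_denominators_flagged(self):
        # no actual positives: SE, PRE2(FN=0? -> TN+FN=10) ... SE and C undefined
        m = metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=0))
        assert math.isnan(m.SE) and math.isnan(m.C)
        assert "SE" in m.undefined and "C" in m.undefined

    @settings(max_examples=200, derandomize=True)
    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_matches_direct_formula_evaluation(self, tp, tn, fp, fn):
        cc = ConfusionCounts(tp, tn, fp, fn)
        if cc.total == 0:
            return
        m = metrics(cc)
        if not m.undefined:
            hand = metrics_by_hand(cc)
            for k, v in hand.items():
                assert getattr(m, k) == pytest.approx(v, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_class_swap_symmetry(self, tp, tn, fp, fn):
        cc = ConfusionCounts(tp, tn, fp, fn)
        if cc.total == 0:
            return
        m = metrics(cc)
        swapped = metrics(ConfusionCounts(TP=tn, TN=tp, FP=fn, FN=fp))
        if not m.undefined and not swapped.undefined:
            assert m.SE == pytest.approx(swapped.SP)
            assert m.PRE1 == pytest.approx(swapped.PRE2)
            assert m.GA == pytest.approx(swapped.GA)
            assert abs(m.C) == pytest.approx(abs(swapped.C))


class TestGridSearch:
    def test_separable_classes(self):
        f, m, _ = grid_search_threshold(np.array([0.1, 0.2, 0.3]),
                                        np.array([0.4, 0.5, 0.6]))
        assert m.GA == 1.0
        assert 0.3 < f.cutoff < 0.4
        assert f.direction == Direction.BELOW_IS_POSITIVE

    def test_identical_multisets_give_half(self):
        v = np.array([1.0, 2.0, 3.0])
        _, m, _ = grid_search_threshold(v, v.copy())
        assert m.GA == pytest.approx(0.5)

    def test_nan_values_excluded_and_counted(self):
        f, m, n_excl = grid_search_threshold(
            np.array([0.1, np.nan, 0.2]), np.array([0.5, 0.6, np.nan]))
        assert n_excl == 2 and m.GA == 1.0

    def test_all_nan_class_raises(self):
        with pytest.raises(ValueError):
            grid_search_threshold(np.array([np.nan]), np.array([1.0]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_equals_brute_force_maximum(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.3, 1.0, 120)
        neg = rng.normal(-0.3, 1.0, 130)
        _, m, _ = grid_search_threshold(pos, neg, criterion="GA")
        assert m.GA == pytest.approx(brute_force_best_ga(pos, neg), abs=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        pos = rng.normal(0.5, 1.0, 100)
        neg = rng.normal(-0.5, 1.0, 100)
        f0, m0, _ = grid_search_threshold(pos, neg)
        f1, m1, _ = grid_search_threshold(pos + 10.0, neg + 10.0)
        assert f1.cutoff == pytest.approx(f0.cutoff + 10.0)
        assert m1.GA == pytest.approx(m0.GA)


class TestRankDescriptors:
    def _tables(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        pos = pd.DataFrame({
            "informative": rng.normal(1.0, 0.5, n),
            "noise": rng.normal(0.0, 1.0, n),
        })
        neg = pd.DataFrame({
            "informative": rng.normal(-1.0, 0.5, n),
            "noise": rng.normal(0.0, 1.0, n),
        })
        return pos, neg

    def test_informative_column_ranked_first(self):
        pos, neg = self._tables()
        ranking = rank_descriptors(pos, neg)
        assert ranking.iloc[0].descriptor == "informative"
        assert ranking.iloc[0].GA > ranking.iloc[1].GA

    def test_pure_noise_stays_near_chance(self):
        rng = np.random.default_rng(1)
        pos = pd.DataFrame({f"n{k}": rng.normal(0, 1, 1000) for k in range(4)})
        neg = pd.DataFrame({f"n{k}": rng.normal(0, 1, 1000) for k in range(4)})
        ranking = rank_descriptors(pos, neg)
        assert (ranking.GA < 0.57).all()  # optimal cutoff overfits only mildly

    def test_deterministic_under_fixed_input(self):
        pos, neg = self._tables(seed=5)
        r1 = rank_descriptors(pos, neg)
        r2 = rank_descriptors(pos, neg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_report_has_full_metric_columns(self):
        pos, neg = self._tables()
        ranking = rank_descriptors(pos, neg)
        for col in ["descriptor", "direction", "cutoff", "TP", "TN", "FP", "FN",
                    "SE", "SP", "PRE1", "PRE2", "GA", "C"]:
            assert col in ranking.columns
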
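"""Survival statistics against hand calculations and library oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from attnsig.survival import (CutoffResult, ValidationError, auroc, best_cutoff,
                              chi_square_2x2, hazard_ratio, km_estimate,
                              logrank_test)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_censored_subject_leaves_risk_set(self):
        # hand product-limit: S(1) = 2/3, then 1 at risk at t=3 -> S(3) = 0
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert np.allclose(km.survival, [2 / 3, 0.0])
        assert km.survival_at(1.5) == pytest.approx(2 / 3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1, 2], [1, 1])

    def test_matches_lifelines_on_random_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 40).round(1)
        events = rng.integers(0, 2, 40)
        if events.sum() == 0:
            events[0] = 1
        km = km_estimate(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.event_times, km.survival):
            assert kmf.predict(t) == pytest.approx(s, abs=1e-9)


class TestLogRank:
    def test_identical_groups_are_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 30)
        e = rng.integers(0, 2, 30)
        g = rng.integers(0, 2, 30)
        e[:2] = 1
        g[:2] = [0, 1]
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_three_vs_three_hand_enumeration(self):
        # O/E/V over the 6 event times: O1=3, E1=1.15, V=0.6775
        t = [1, 2, 3, 4, 5, 6]
        e = [1] * 6
        g = [1, 1, 1, 0, 0, 0]
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx((3 - 1.15) ** 2 / 0.6775, rel=1e-10)

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 20)
        e = np.ones(20, dtype=int)
        g = rng.integers(0, 2, 20)
        a = logrank_test(t, e, g)
        b = logrank_test(t + 7.5, e, g)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 50).round(1)
        e = rng.integers(0, 2, 50)
        g = rng.integers(0, 2, 50)
        res = logrank_test(t, e, g)
        ref = lifelines.logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], [1, 1])


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_are_uninformative(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_four_point_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc([0.1, 0.2], [1, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_equals_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.choice(np.linspace(0, 1, 7), n)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        brute = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert auroc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        assert auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestBestCutoff:
    def test_bimodal_recovers_true_split(self):
        rng = np.random.default_rng(5)
        n = 40
        scores = np.r_[rng.uniform(0, 0.2, n // 2), rng.uniform(0.8, 1.0, n // 2)]
        times = np.r_[rng.exponential(5, n // 2), rng.exponential(50, n // 2)]
        events = np.ones(n, dtype=int)
        res = best_cutoff(scores, times, events)
        truth = logrank_test(times, events, (scores > 0.5).astype(int))
        assert res.p == pytest.approx(truth.p, rel=1e-12)

    def test_equals_exhaustive_grid_scan(self):
        rng = np.random.default_rng(6)
        scores = rng.random(25)
        times = rng.exponential(10, 25)
        events = rng.integers(0, 2, 25)
        events[:3] = 1
        res = best_cutoff(scores, times, events, min_group_frac=0.1)
        distinct = np.unique(scores)
        best_p = np.inf
        for cut in (distinct[:-1] + distinct[1:]) / 2:
            high = (scores > cut).astype(int)
            if min(high.sum(), 25 - high.sum()) < 2.5:
                continue
            best_p = min(best_p, logrank_test(times, events, high).p)
        assert res.p == pytest.approx(best_p, rel=1e-12)

    def test_infeasible_group_floor_rejected(self):
        with pytest.raises(ValidationError):
            best_cutoff([0.1, 0.2, 0.3], [1, 2, 3], [1, 1, 1], min_group_frac=0.5)

    def test_no_better_than_median_split_is_impossible(self):
        rng = np.random.default_rng(7)
        scores = rng.random(30)
        times = rng.exponential(10, 30)
        events = np.ones(30, dtype=int)
        res = best_cutoff(scores, times, events, min_group_frac=0.1)
        med = logrank_test(times, events, (scores > np.median(scores)).astype(int))
        assert res.p <= med.p + 1e-12


class TestHazardRatio:
    def test_identical_groups_give_unit_ratio(self):
        t = [1, 2, 3, 1, 2, 3]
        hr = hazard_ratio(t, [1] * 6, [0, 0, 0, 1, 1, 1])
        assert hr.hr == pytest.approx(1.0)

    def test_group_swap_inverts(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(5, 30)
        e = np.ones(30, dtype=int)
        g = rng.integers(0, 2, 30)
        a = hazard_ratio(t, e, g)
        b = hazard_ratio(t, e, 1 - g)
        assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-9)

    def test_three_vs_three_hand_ratio(self):
        # O1=3, E1=1.15, O2=3, E2=4.85 -> HR = 4.85/1.15
        hr = hazard_ratio([1, 2, 3, 4, 5, 6], [1] * 6, [1, 1, 1, 0, 0, 0])
        assert hr.hr == pytest.approx(4.85 / 1.15, rel=1e-10)

    def test_zero_event_group_is_flagged_not_raised(self):
        hr = hazard_ratio([1, 2, 10, 11], [1, 1, 0, 0], [0, 0, 1, 1])
        assert hr.flagged


class TestChiSquare:
    def test_independent_table_is_null(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_transpose_invariance(self):
        a, _ = chi_square_2x2([[12, 5], [7, 20]])
        b, _ = chi_square_2x2(np.array([[12, 5], [7, 20]]).T)
        assert a == pytest.approx(b, rel=1e-12)

    def test_direct_formula_example(self):
        stat, _ = chi_square_2x2([[20, 5], [5, 20]])
        assert stat == pytest.approx(18.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2([[0, 0], [5, 20]])
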
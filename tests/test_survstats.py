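"""Unit and property tests for the survival/screening statistics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pairsurv.survstats import (ZeroVarianceError, bh_fdr, hazard_ratio_oe,
                                hypergeom_enrichment, km_fit, logrank,
                                mann_whitney, median_split, pearson_r,
                                quartile_bins, survival_at)

from conftest import random_survival


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKmFit:
    def test_no_censoring_matches_empirical(self):
        curve = km_fit([10, 20, 30, 40], [1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # events at 6, 14, 44, 62; censoring at 21
        # S: 4/5, 4/5*3/4 = 3/5, 3/5*1/2 = 3/10, 0
        curve = km_fit([6, 44, 21, 14, 62], [1, 1, 0, 1, 1])
        np.testing.assert_allclose(curve.event_times, [6, 14, 44, 62])
        np.testing.assert_allclose(curve.survival, [0.8, 0.6, 0.3, 0.0])
        assert curve.survival[-1] == 0.0

    def test_single_censored_patient(self):
        with pytest.warns(UserWarning):
            curve = km_fit([50.0], [0])
        assert curve.no_events
        assert curve.event_times.size == 0
        assert survival_at(curve, 10)[0] == 1.0
        assert survival_at(curve, 100)[0] == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_fit([], [])

    def test_nonpositive_time_raises(self):
        with pytest.raises(ValueError):
            km_fit([0.0, 5.0], [1, 1])

    def test_at_risk_strictly_decreasing_and_survival_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t, s = random_survival(rng, 40)
            curve = km_fit(t, s)
            assert np.all(np.diff(curve.at_risk) < 0)
            assert np.all(np.diff(curve.survival) <= 0)
            assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_tied_death_and_censoring_death_first(self):
        # censored subject at t=10 still at risk for the death at t=10
        curve = km_fit([10, 10, 20], [1, 0, 1])
        np.testing.assert_allclose(curve.at_risk, [3, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_property_uncensored_equals_empirical(self, raw_times):
        times = np.asarray(raw_times, dtype=float)
        curve = km_fit(times, np.ones_like(times))
        n = times.size
        for t, s in zip(curve.event_times, curve.survival):
            assert abs(s - (times > t).sum() / n) < 1e-12


class TestSurvivalAt:
    def test_step_between_events(self):
        curve = km_fit([10, 20, 30, 40], [1, 1, 1, 1])
        assert survival_at(curve, 25) == (0.5, True)

    def test_before_first_event(self):
        curve = km_fit([10, 20, 30, 40], [1, 1, 1, 1])
        assert survival_at(curve, 5)[0] == 1.0

    def test_beyond_followup_carries_forward_flagged(self):
        curve = km_fit([10, 20, 30], [1, 1, 0])
        value, defined = survival_at(curve, 100)
        # oracle: step function value after the last event
        assert value == pytest.approx((1 - 1 / 3) * (1 - 1 / 2))
        assert not defined

    def test_exactly_at_event_time_right_continuous(self):
        curve = km_fit([10, 20, 30, 40], [1, 1, 1, 1])
        assert survival_at(curve, 20)[0] == 0.5

    def test_non_increasing_in_horizon(self):
        rng = np.random.default_rng(5)
        t, s = random_survival(rng, 50)
        curve = km_fit(t, s)
        horizons = np.linspace(1, t.max() * 1.2, 40)
        values = [survival_at(curve, h)[0] for h in horizons]
        assert np.all(np.diff(values) <= 0)

    def test_invalid_horizon(self):
        curve = km_fit([10], [1])
        with pytest.raises(ValueError):
            survival_at(curve, 0)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def brute_logrank_two_group(times, status, is_a):
    """Per-event-time 2x2 table oracle for the two-group statistic."""
    times = np.asarray(times, float)
    status = np.asarray(status, bool)
    is_a = np.asarray(is_a, bool)
    o_a = e_a = var = 0.0
    for t in np.unique(times[status]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & is_a).sum()
        d = (status & (times == t)).sum()
        d_a = (status & (times == t) & is_a).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    stat = (o_a - e_a) ** 2 / var
    return stat, sps.chi2.sf(stat, 1)


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [5, 10, 15, 20]
        s = [1, 1, 0, 1]
        r = logrank(["a"] * 4 + ["b"] * 4, t + t, s + s)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_observed_expected_sum_to_total_deaths(self):
        rng = np.random.default_rng(8)
        t, s = random_survival(rng, 60)
        g = rng.integers(0, 3, 60)
        r = logrank(g, t, s)
        assert r.observed.sum() == pytest.approx(s.sum())
        assert r.expected.sum() == pytest.approx(s.sum())

    def test_matches_brute_force_two_group_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            t, s = random_survival(rng, int(rng.integers(10, 60)))
            is_a = rng.random(t.size) < 0.5
            if is_a.all() or not is_a.any():
                continue
            r = logrank(np.where(is_a, "a", "b"), t, s)
            stat, p = brute_logrank_two_group(t, s, is_a)
            assert r.statistic == pytest.approx(stat, abs=1e-10)
            assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_separated_groups_vs_reference_implementation(self):
        from lifelines.statistics import logrank_test
        t_a, t_b = [1, 2, 3], [10, 20, 30]
        r = logrank(["a"] * 3 + ["b"] * 3, t_a + t_b, [1] * 6)
        ref = logrank_test(t_a, t_b, [1] * 3, [1] * 3)
        assert r.statistic == pytest.approx(ref.test_statistic, abs=1e-10)
        assert r.p_value == pytest.approx(ref.p_value, abs=1e-10)

    def test_multigroup_vs_reference_implementation(self):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(9)
        t, s = random_survival(rng, 80)
        g = rng.integers(0, 4, 80)
        r = logrank(g, t, s)
        ref = multivariate_logrank_test(t, g, s)
        assert r.df == 3
        assert r.statistic == pytest.approx(ref.test_statistic, abs=1e-10)
        assert r.p_value == pytest.approx(ref.p_value, abs=1e-10)

    def test_zero_events_null_result(self):
        r = logrank(["a", "a", "b", "b"], [1, 2, 3, 4], [0, 0, 0, 0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            logrank(["a", "a"], [1, 2], [1, 1])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(300):
            t = rng.exponential(50, 40)
            s = rng.random(40) < 0.8
            g = rng.integers(0, 2, 40)
            if len(np.unique(g)) < 2 or not s.any():
                continue
            ps.append(logrank(g, t, s).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestHazardRatioOE:
    def test_identical_groups_hr_one(self):
        t = [5, 10, 15, 20]
        s = [1, 1, 0, 1]
        r = hazard_ratio_oe(t, s, t, s)
        assert r.defined
        assert r.hr == pytest.approx(1.0)

    def test_swap_inverts_exactly(self):
        rng = np.random.default_rng(12)
        t_a, s_a = random_survival(rng, 30)
        t_b, s_b = random_survival(rng, 25, scale=60)
        fwd = hazard_ratio_oe(t_a, s_a, t_b, s_b)
        rev = hazard_ratio_oe(t_b, s_b, t_a, s_a)
        assert fwd.hr * rev.hr == pytest.approx(1.0, rel=1e-12)
        assert fwd.log_hr_se == pytest.approx(rev.log_hr_se)

    def test_true_hr_two_recovered(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            t_a = rng.exponential(0.5, 500)
            t_b = rng.exponential(1.0, 500)
            r = hazard_ratio_oe(t_a, np.ones(500), t_b, np.ones(500))
            hits += 1.7 <= r.hr <= 2.35
        assert hits >= 38

    def test_cox_cross_check(self):
        from lifelines import CoxPHFitter
        import pandas as pd
        rng = np.random.default_rng(2)
        t_a = rng.exponential(0.5, 400)
        t_b = rng.exponential(1.0, 400)
        r = hazard_ratio_oe(t_a, np.ones(400), t_b, np.ones(400))
        df = pd.DataFrame({"t": np.r_[t_a, t_b], "e": 1,
                           "x": np.r_[np.ones(400), np.zeros(400)]})
        cox_hr = float(np.exp(CoxPHFitter().fit(df, "t", "e").params_["x"]))
        # O/E is mildly shrunk toward 1 relative to Cox at HR = 2
        assert r.hr == pytest.approx(cox_hr, rel=0.10)

    def test_no_events_in_one_group_undefined(self):
        r = hazard_ratio_oe([1, 2, 3], [1, 1, 1], [10, 20, 30], [0, 0, 0])
        assert not r.defined
        assert np.isnan(r.hr)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            hazard_ratio_oe([], [], [1], [1])


# ---------------------------------------------------------------------------
# Quartile binning
# ---------------------------------------------------------------------------

class TestQuartileBins:
    def test_ranks_one_to_eight(self):
        qa = quartile_bins(np.arange(1, 9), "g")
        assert list(qa.bins) == ["Q4", "Q4", "Q3", "Q3", "Q2", "Q2", "Q1", "Q1"]

    def test_q1_is_highest_expression(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=100)
        qa = quartile_bins(v)
        assert v[qa.bins == "Q1"].min() > v[qa.bins == "Q2"].max()
        assert v[qa.bins == "Q4"].max() < v[qa.bins == "Q3"].min()

    def test_ties_at_cutpoint_go_low_and_partition(self):
        v = np.array([1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3], dtype=float)
        qa = quartile_bins(v)
        labels, counts = np.unique(qa.bins.astype(str), return_counts=True)
        assert counts.sum() == v.size  # nobody dropped
        # every tied value lands in a single bin
        for value in (1, 2, 3):
            assert len(set(qa.bins[v == value])) == 1

    def test_constant_values_raise(self):
        with pytest.raises(ZeroVarianceError):
            quartile_bins(np.full(10, 3.0), "flat")

    def test_too_few_patients_raise(self):
        with pytest.raises(ValueError):
            quartile_bins(np.arange(5))

    @given(st.permutations(list(range(16))))
    @settings(max_examples=50, deadline=None)
    def test_property_monotone_transform_invariance(self, perm):
        v = np.asarray(perm, dtype=float)
        base = quartile_bins(v).bins
        for transform in (lambda x: 3 * x + 7, lambda x: x ** 3,
                          np.exp, lambda x: x / (1 + np.abs(x))):
            assert list(quartile_bins(transform(v)).bins) == list(base)

    def test_median_split_ties_to_low(self):
        high = median_split(np.array([1.0, 2.0, 2.0, 3.0]))
        assert list(high) == [False, False, False, True]


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == 1.0

    def test_exact_separated(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/20 by enumeration

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n, m = rng.integers(2, 9, size=2)
            pool = rng.permutation(40)[: n + m].astype(float)
            x, y = pool[:n], pool[n:]
            _, p = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(6)
        x = np.round(rng.normal(size=40), 1)  # induce ties
        y = np.round(rng.normal(0.5, size=35), 1)
        _, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_power_large_shift(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 100)
        y = rng.normal(2, 1, 100)
        _, p = mann_whitney(x, y)
        assert p < 0.001

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Pearson, BH, hypergeometric
# ---------------------------------------------------------------------------

class TestPearson:
    def test_perfect_positive(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 5, 4])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


def brute_bh_rejections(p, alpha):
    """Classic step-up oracle: reject the k* smallest p-values."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    ranked = p[order]
    m = p.size
    k_star = 0
    for k in range(1, m + 1):
        if ranked[k - 1] <= k * alpha / m:
            k_star = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_preserves_input_order(self):
        p = [0.04, 0.01, 0.03, 0.02]
        q = bh_fdr(p)
        assert q[1] <= q[3] <= q[2] <= q[0]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_property_q_at_least_p_and_rejections_match_oracle(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        for alpha in (0.05, 0.25):
            np.testing.assert_array_equal(q <= alpha + 1e-12,
                                          brute_bh_rejections(p, alpha))

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestHypergeom:
    def test_worked_case(self):
        p, fold = hypergeom_enrichment(4, 5, 5, 20)
        assert p == pytest.approx(76 / 15504, abs=1e-12)
        assert fold == pytest.approx((4 / 5) / (5 / 20))

    def test_query_equals_background(self):
        p, fold = hypergeom_enrichment(5, 20, 5, 20)
        assert p == pytest.approx(1.0)
        assert fold == pytest.approx(1.0)

    def test_exact_fraction_oracle_small(self):
        from fractions import Fraction
        from math import comb
        for N in (5, 10, 15):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        p, _ = hypergeom_enrichment(k, n, K, N)
                        exact = sum(Fraction(comb(K, j) * comb(N - K, n - j),
                                             comb(N, n))
                                    for j in range(k, min(n, K) + 1))
                        assert abs(p - float(exact)) < 1e-12

    def test_invalid_k_raises(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(6, 5, 5, 20)
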
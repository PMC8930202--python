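"""Exact tests checked against brute-force enumeration oracles."""

import math
from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats as sps

from pairedomics.errors import ValidationError
from pairedomics.stats import (
    bh_fdr,
    fisher_exact_2x2,
    kaplan_meier,
    log_rank,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ------------------------------------------------- signed-rank oracle

def brute_force_signed_rank_p(diffs):
    """Two-sided exact p by full enumeration of sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonSignedRank:
    def test_eight_uniform_pairs_exact(self):
        # all-positive differences of distinct magnitudes: p = 2/2^8
        post = [10, 11, 12, 13, 14, 15, 16, 17]
        pre = [9.5, 9, 8, 7, 6, 5, 4, 3]
        res = wilcoxon_signed_rank(post, pre)
        assert res.exact
        assert res.p_value == pytest.approx(0.0078125, abs=1e-12)
        assert round(res.p_value, 4) == 0.0078

    def test_antisymmetric_differences(self):
        res = wilcoxon_signed_rank([1.0, -1.0])
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_zeros_dropped_before_ranking(self):
        res = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0])
        assert res.n_used == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        d = rng.normal(size=n).round(2)
        d = d[d != 0]
        if len(d) == 0:
            return
        res = wilcoxon_signed_rank(d)
        assert res.exact
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.integers(-3, 4, size=8).astype(float)
        d = d[d != 0]
        if len(d) == 0:
            return
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_type_one_error_near_nominal(self):
        # null: paired Gaussians, n = 8; exact test is conservative
        rng = np.random.default_rng(42)
        n_reps = 10_000
        d = rng.normal(size=(n_reps, 8))
        rejections = 0
        for row in d:
            if wilcoxon_signed_rank(row).p_value <= 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert 0.03 <= rate <= 0.06

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1.0, size=60)
        res = wilcoxon_signed_rank(d)
        assert not res.exact
        assert 0 <= res.p_value <= 1


# --------------------------------------------------- rank-sum oracle

def brute_force_rank_sum_p(x, y):
    """Exact p by enumerating all assignments of ranks to group x."""
    m, n = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:m].sum()
    all_ranks = list(range(1, m + n + 1))
    ws = np.array([sum(c) for c in combinations(all_ranks, m)])
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonRankSum:
    def test_small_exact_case(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_multisets(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_error(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        x = rng.normal(size=m)
        y = rng.normal(size=n)
        res = wilcoxon_rank_sum(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-12)


# ------------------------------------------------------ Fisher oracle

def brute_force_fisher_p(a, b, c, d):
    """Two-sided p by enumerating all tables at fixed margins."""
    row1, col1, N = a + b, a + c, a + b + c + d

    def pmf(k):
        return (
            math.comb(col1, k)
            * math.comb(N - col1, row1 - k)
            / math.comb(N, row1)
        )

    p_obs = pmf(a)
    lo = max(0, row1 + col1 - N)
    hi = min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-10))


class TestFisherExact:
    def test_diagonal_table_closed_form(self):
        _, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_no_association(self):
        _, p = fisher_exact_2x2([[2, 2], [2, 2]])
        assert p == pytest.approx(1.0)

    def test_negative_cell_error(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_small_margins(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(v) for v in rng.integers(0, 7, size=4))
        if a + b + c + d == 0:
            return
        _, p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(brute_force_fisher_p(a, b, c, d), abs=1e-10)

    def test_one_sided_greater_matches_scipy(self):
        table = [[8, 2], [1, 9]]
        _, p = fisher_exact_2x2(table, alternative="greater")
        assert p == pytest.approx(sps.fisher_exact(table, "greater")[1], abs=1e-12)

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            _, p = fisher_exact_2x2(t)
            assert p == pytest.approx(sps.fisher_exact(t)[1], abs=1e-9)


# ------------------------------------------------------------- BH FDR

class TestBhFdr:
    def test_step_up_formula(self):
        adj = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_order_preserved(self):
        p = [0.5, 0.001, 0.04]
        adj = bh_fdr(p)
        # smallest raw p gets smallest adjusted p, order of output = input
        assert adj[1] == adj.min()
        assert adj[1] == pytest.approx(0.003)

    def test_monotone_in_raw_values(self, rng):
        p = rng.uniform(size=30)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_error(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.1, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=25)
        assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])


# ----------------------------------------------------------- survival

class TestKaplanMeier:
    def test_forced_half_survival(self):
        # 12 events before t = 15, 12 censored after: S(15) = 0.5
        times = list(range(1, 13)) + [20] * 12
        events = [1] * 12 + [0] * 12
        curve = kaplan_meier(times, events)
        assert curve.survival_at(15) == pytest.approx(0.5)

    def test_all_censored_flat_at_one(self):
        curve = kaplan_meier([5, 6, 7], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(100) == 1.0

    def test_survival_non_increasing_and_starts_at_one(self, rng):
        t = rng.exponential(10, size=50)
        e = rng.random(50) < 0.7
        curve = kaplan_meier(t, e)
        assert curve.survival_at(0) == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(9)
        t = rng.exponential(10, size=40).round(1)
        e = rng.random(40) < 0.6
        if not e.any():
            e[0] = True
        curve = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(et).iloc[0]), abs=1e-9
            )


class TestLogRank:
    def test_identical_groups_null_distribution(self):
        # mean of the chi-square statistic under the null is 1 (1 df)
        rng = np.random.default_rng(11)
        stats_out = []
        for _ in range(100):
            t = rng.exponential(10, size=30)
            e = rng.random(30) < 0.8
            g = np.array(["a"] * 15 + ["b"] * 15)
            res = log_rank(t, e, g)
            if not np.isnan(res.statistic):
                stats_out.append(res.statistic)
        mean = np.mean(stats_out)
        se = np.sqrt(2.0 / len(stats_out))  # var of chi2_1 is 2
        assert abs(mean - 1.0) < 3 * se

    def test_no_events_flagged(self):
        res = log_rank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert "no_events" in res.flags
        assert np.isnan(res.p_value)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(2)
        t1 = rng.exponential(10, size=25)
        t2 = rng.exponential(20, size=25)
        t = np.concatenate([t1, t2])
        e = np.ones(50, dtype=bool)
        g = np.array(["a"] * 25 + ["b"] * 25)
        res = log_rank(t, e, g)
        ll = logrank_test(t1, t2, np.ones(25), np.ones(25))
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)
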
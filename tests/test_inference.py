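"""t tests from summaries, bootstrapped correlations, moderated regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from speechgaze.inference import (GroupSummary, InsufficientDataError,
                                  RankDeficiencyError, UndefinedCorrelationError,
                                  choose_t, composite_reading,
                                  fit_moderated_regression, pearson_r, pooled_t,
                                  welch_t)


class TestTTestsAgainstScipy:
    """scipy.stats.ttest_ind_from_stats is the independent oracle."""

    summaries = [
        (GroupSummary(12, 3.4, 1.1), GroupSummary(17, 2.9, 2.3)),
        (GroupSummary(29, 64.29, 16.89), GroupSummary(29, 70.33, 16.22)),
        (GroupSummary(5, -1.0, 0.5), GroupSummary(50, 4.0, 3.0)),
    ]

    @pytest.mark.parametrize("a,b", summaries)
    def test_pooled_matches_scipy(self, a, b):
        res = pooled_t(a, b)
        ref = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                         equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == a.n + b.n - 2

    @pytest.mark.parametrize("a,b", summaries)
    def test_welch_matches_scipy(self, a, b):
        res = welch_t(a, b)
        ref = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                         equal_var=False)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestTTestProperties:
    def test_identical_groups_zero(self):
        g = GroupSummary(20, 5.0, 2.0)
        res = pooled_t(g, g)
        assert res.t == 0.0
        assert res.d == 0.0

    def test_swap_negates_t_and_d_keeps_p(self):
        a, b = GroupSummary(15, 70.96, 13.08), GroupSummary(14, 57.15, 17.99)
        ab, ba = pooled_t(a, b), pooled_t(b, a)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.d == pytest.approx(-ba.d)
        assert ab.p == pytest.approx(ba.p)

    def test_welch_reduces_to_pooled_df_with_equal_n_and_sd(self):
        a, b = GroupSummary(20, 5.0, 2.0), GroupSummary(20, 7.0, 2.0)
        assert welch_t(a, b).df == pytest.approx(pooled_t(a, b).df)
        assert welch_t(a, b).t == pytest.approx(pooled_t(a, b).t)

    def test_welch_df_limit_as_one_variance_vanishes(self):
        """With one group's variance -> 0, Welch df -> (n-1) of the group
        that still varies."""
        a, b = GroupSummary(12, 5.0, 3.0), GroupSummary(40, 7.0, 1e-9)
        assert welch_t(a, b).df == pytest.approx(a.n - 1, rel=1e-6)

    def test_pooled_d_reported_in_both_variants(self):
        a, b = GroupSummary(29, 18.72, 14.37), GroupSummary(29, 17.45, 9.39)
        assert welch_t(a, b).d == pytest.approx(pooled_t(a, b).d)

    def test_variance_screen_switches_variant(self):
        a, b = GroupSummary(29, 18.72, 14.37), GroupSummary(29, 17.45, 9.39)
        assert choose_t(a, b).variant == "welch"
        c, d = GroupSummary(29, 64.29, 16.89), GroupSummary(29, 70.33, 16.22)
        assert choose_t(c, d).variant == "pooled"

    def test_insufficient_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            GroupSummary(1, 0.0, 1.0)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1, n_boot=100, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(3)
        res = pearson_r(rng.normal(size=2000), rng.normal(size=2000),
                        n_boot=0)
        assert abs(res.r) < 0.08

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        a = pearson_r(x, y, n_boot=500, seed=123)
        b = pearson_r(x, y, n_boot=500, seed=123)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_bootstrap_ci_covers_known_rho(self):
        """Generated rho = 0.5, n = 500: the 95% CI should contain the true
        value in at least 90% of seeds."""
        rho, n, seeds = 0.5, 500, 40
        hits = 0
        for s in range(seeds):
            rng = np.random.default_rng(1000 + s)
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
            res = pearson_r(x, y, n_boot=500, seed=s)
            hits += res.ci_low <= rho <= res.ci_high
        assert hits / seeds >= 0.90

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], n_boot=0)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            pearson_r([1.0, 2.0], [1.0, 2.0], n_boot=0)


def _simulate_fit(beta_int, n, seed, **kwargs):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    g = (np.arange(n) % 2).astype(float)
    y = 1.0 + 0.5 * x + 0.3 * g + beta_int * x * g + rng.normal(size=n)
    return fit_moderated_regression(y, x, g, n_boot=0, **kwargs)


class TestModeratedRegression:
    def test_zero_interaction_usually_reduced(self):
        """Type-I check: with no generating interaction the reduction rule
        should drop the interaction in about 95% of datasets."""
        reduced = sum(_simulate_fit(0.0, 200, s).reduced_reported
                      for s in range(100))
        assert reduced >= 85

    def test_strong_interaction_usually_retained(self):
        """Power check: a standardized interaction of 1 at n = 58 is kept in
        the large majority of datasets."""
        retained = sum(not _simulate_fit(1.0, 58, s).reduced_reported
                       for s in range(50))
        assert retained >= 45

    def test_constant_dummy_rank_deficient(self):
        rng = np.random.default_rng(0)
        with pytest.raises(RankDeficiencyError):
            fit_moderated_regression(rng.normal(size=30), rng.normal(size=30),
                                     np.zeros(30), n_boot=0)

    def test_recovers_known_coefficients(self):
        res = _simulate_fit(1.0, 5000, 7)
        assert res.full.params["x"] == pytest.approx(0.5, abs=0.08)
        assert res.full.params["x:group"] == pytest.approx(1.0, abs=0.08)

    def test_bootstrap_ci_seeded_and_bracketing(self):
        rng = np.random.default_rng(9)
        n = 120
        x = rng.normal(size=n)
        g = (np.arange(n) % 2).astype(float)
        y = 2.0 + 1.5 * x + rng.normal(size=n)
        a = fit_moderated_regression(y, x, g, n_boot=300, seed=5)
        b = fit_moderated_regression(y, x, g, n_boot=300, seed=5)
        assert a.full.bootstrap_ci == b.full.bootstrap_ci
        # the percentile CI surrounds the point estimate with sane width
        lo, hi = a.full.bootstrap_ci["x"]
        assert lo < a.full.params["x"] < hi
        assert 0.0 < hi - lo < 1.0

    def test_both_models_returned_with_reduction_flag(self):
        res = _simulate_fit(0.0, 300, 11)
        assert res.full is not None and res.reduced is not None
        assert "x:group" in res.full.terms
        assert "x:group" not in res.reduced.terms


class TestCompositeReading:
    def test_participant_at_both_means_scores_zero(self):
        df = pd.DataFrame({"reading1": [8.0, 10.0, 12.0],
                           "reading2": [18.0, 20.0, 22.0]})
        z = composite_reading(df)
        assert z.iloc[1] == pytest.approx(0.0)

    def test_one_sd_above_on_both_scores_two(self):
        # sample sd (ddof=1) of [9, 10, 11] is 1, so row 2 sits +1 SD on both
        df = pd.DataFrame({"reading1": [9.0, 10.0, 11.0],
                           "reading2": [19.0, 20.0, 21.0]})
        assert composite_reading(df).iloc[2] == pytest.approx(2.0)

    def test_missing_measure_dropped_with_warning(self):
        df = pd.DataFrame({"reading1": [1.0, 2.0, np.nan, 4.0],
                           "reading2": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning):
            z = composite_reading(df)
        assert len(z) == 3

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"reading1": [5.0, 5.0, 5.0],
                           "reading2": [1.0, 2.0, 3.0]})
        with pytest.raises(UndefinedCorrelationError):
            composite_reading(df)
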
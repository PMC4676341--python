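import numpy as np
import pytest
from scipy import stats

import npdkit as nk
from npdkit.errors import InsufficientDataError


class TestSummarize:
    def test_published_cf_pdmax_ci_reproduced(self):
        # construct any sample with mean -31.7, sd 9.5, n 11; the t-based CI
        # must reproduce the published (-38.1, -25.3) at one decimal
        x = _sample_with(mean=-31.7, sd=9.5, n=11)
        s = nk.summarize(x)
        assert round(s.ci_low, 1) == -38.1
        assert round(s.ci_high, 1) == -25.3

    def test_published_noncf_pdmax_ci_reproduced(self):
        x = _sample_with(mean=-16.4, sd=6.9, n=19)
        s = nk.summarize(x)
        assert round(s.ci_low, 1) == -19.7
        assert round(s.ci_high, 1) == -13.1

    def test_constant_sample_has_degenerate_ci(self):
        s = nk.summarize([5.0, 5.0, 5.0])
        assert s.sd == 0.0
        assert (s.ci_low, s.ci_high) == (5.0, 5.0)
        assert s.median == 5.0

    def test_single_observation_rejected(self):
        with pytest.raises(InsufficientDataError):
            nk.summarize([1.0])

    def test_ci_symmetric_and_ordered(self):
        rng = np.random.default_rng(0)
        s = nk.summarize(rng.normal(0, 3, 25))
        assert s.ci_high - s.mean == pytest.approx(s.mean - s.ci_low)
        assert s.minimum <= s.median <= s.maximum


def _sample_with(mean, sd, n):
    """Deterministic sample with exactly the requested mean and sample SD."""
    rng = np.random.default_rng(12345)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestOneWayAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        g = [1.0, 2.0, 3.0]
        res = nk.one_way_anova(g, g, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        f_res = nk.one_way_anova(a, b)
        t, p_t = stats.ttest_ind(a, b)
        assert f_res.statistic == pytest.approx(t**2, rel=1e-10)
        assert f_res.p_value == pytest.approx(p_t, rel=1e-10)

    def test_published_effect_sizes_give_tiny_p_in_most_seeds(self):
        # simulated three-arm cohorts at the published group sizes: the
        # between-group separation is strong enough that p < 0.001 nearly always
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            sim = nk.simulate_cohort(repeats=1, noise=nk.RepeatNoise(0, 0, 0),
                                     seed=seed)
            df = sim.truth
            groups = [df.loc[df["group"] == g, "pdmax"] for g in nk.DEFAULT_SIZES]
            if nk.one_way_anova(*groups).p_value < 0.001:
                hits += 1
        assert hits >= int(0.95 * n_seeds)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            nk.one_way_anova([1.0, 2.0], [3.0])


class TestScheffe:
    def test_identical_groups_all_pairwise_p_one(self):
        g = [1.0, 2.0, 3.0]
        res = nk.scheffe_pairwise(g, g, g)
        assert (res.pairwise["p_value"] == 1.0).all()

    def test_two_groups_reduces_to_anova(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 14)
        sch = nk.scheffe_pairwise(a, b)
        an = nk.one_way_anova(a, b)
        assert sch.statistic == pytest.approx(an.statistic, rel=1e-10)
        assert sch.p_value == pytest.approx(an.p_value, rel=1e-10)

    def test_conservative_relative_to_unadjusted_contrast(self):
        # Scheffé pairwise p is never smaller than the unadjusted p of the
        # same contrast with the same pooled MSE (the protected-t / LSD p):
        # P(F(k-1, nu) >= t^2/(k-1)) >= P(F(1, nu) >= t^2)
        rng = np.random.default_rng(4)
        k = 3
        for _ in range(20):
            groups = [rng.normal(rng.normal(0, 1), 1, rng.integers(4, 9))
                      for _ in range(k)]
            n_total = sum(len(g) for g in groups)
            res = nk.scheffe_pairwise(*groups, labels=["a", "b", "c"])
            for row in res.pairwise.itertuples(index=False):
                t_sq = row.statistic * (k - 1)
                p_lsd = stats.f.sf(t_sq, 1, n_total - k)
                assert row.p_value >= p_lsd - 1e-12

    def test_simulated_cohort_pattern_matches_published_contrasts(self):
        # CF separates from both other groups; non-CF vs healthy does not
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            sim = nk.simulate_cohort(repeats=1, noise=nk.RepeatNoise(0, 0, 0),
                                     seed=1000 + seed)
            df = sim.truth
            groups = {g: df.loc[df["group"] == g, "tcr"].to_numpy()
                      for g in nk.DEFAULT_SIZES}
            res = nk.scheffe_pairwise(*groups.values(), labels=list(groups))
            pw = res.pairwise.set_index(["group_1", "group_2"])["p_value"]
            if (pw[("CF", "non_CF")] < 0.01 and pw[("CF", "healthy")] < 0.01
                    and pw[("non_CF", "healthy")] > 0.05):
                hits += 1
        assert hits > n_seeds / 2


class TestLeveneAndKruskal:
    def test_identical_shape_groups_p_near_one(self):
        g = list(np.linspace(-1, 1, 9))
        lev = nk.levene_test(g, g, g)
        kw = nk.kruskal_wallis(g, g, g)
        assert lev.p_value > 0.99
        assert kw.p_value > 0.9

    def test_kruskal_matches_hand_computed_h(self):
        # three groups with ranks 1-3, 4-6, 7-9 and no ties:
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 = 7.2
        res = nk.kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert res.statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(7.2, 2)))

    def test_levene_equals_anova_on_absolute_deviations(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, s, 12) for s in (1.0, 2.0, 3.5)]
        lev = nk.levene_test(*groups)
        transformed = [np.abs(g - g.mean()) for g in groups]
        an = nk.one_way_anova(*transformed)
        assert lev.statistic == pytest.approx(an.statistic, rel=1e-10)
        assert lev.p_value == pytest.approx(an.p_value, rel=1e-10)

    def test_kruskal_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, 10) for m in (0.0, 0.5, 1.5)]
        base = nk.kruskal_wallis(*groups)
        trans = nk.kruskal_wallis(*[np.exp(g) for g in groups])
        assert trans.statistic == pytest.approx(base.statistic)


class TestShiftInvariance:
    def test_all_tests_invariant_to_constant_shift(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.3, 11) for m in (0.0, 1.0, 2.5)]
        shifted = [g + 100.0 for g in groups]
        for fn in (nk.one_way_anova, nk.levene_test, nk.kruskal_wallis):
            assert fn(*groups).statistic == pytest.approx(
                fn(*shifted).statistic, rel=1e-8)


class TestGroupComparisonModel:
    def test_fit_from_dataframe_reproduces_published_pattern(self):
        sim = nk.simulate_cohort(repeats=1, seed=21)
        df = nk.score_cohort(sim.cohort).to_dataframe()
        res = nk.GroupComparison.from_dataframe(df, value="tcr_mv").fit()
        assert {s.group for s in res.summaries} == {"CF", "non_CF", "healthy"}
        assert res.anova.p_value < 0.01
        text = res.summary()
        assert "Scheffé pairwise" in text and "ANOVA" in text

    def test_p_values_never_printed_as_zero(self):
        assert nk.format_p(1e-12) == "< 0.001"
        assert nk.format_p(0.02) == "0.020"
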
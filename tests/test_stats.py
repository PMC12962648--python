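"""ANOVA/Tukey, median split, Kaplan-Meier, log-rank, Cox PH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glymph.stats import (
    ConvergenceError,
    SurvivalData,
    anova_tukey,
    cox_fit,
    dichotomize_median,
    km_estimate,
    logrank,
)


def weibull_cohort(n, beta=0.0, censor_scale=None, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = 400.0 * rng.weibull(1.2, n) * np.exp(-beta * x / 1.2)
    if censor_scale:
        c = rng.uniform(0, censor_scale, n)
        return np.minimum(t, c), (t <= c).astype(int), x
    return t, np.ones(n, int), x


class TestAnovaTukey:
    def test_identical_group_distributions(self):
        vals = np.tile([1.0, 2.0, 3.0], 3)
        grp = np.repeat(["a", "b", "c"], 3)
        out = anova_tukey(vals, grp)
        assert out["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_two_groups_reduce_to_t_test(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 35)
        out = anova_tukey(np.concatenate([a, b]), np.repeat(["a", "b"], [40, 35]))
        t_p = sps.ttest_ind(a, b).pvalue
        assert out["pairwise"][("a", "b")] == pytest.approx(t_p, abs=1e-6)

    def test_shifted_group_detected(self, rng):
        groups = [rng.normal(0, 1, 50) for _ in range(3)] + [rng.normal(1.0, 1, 50)]
        vals = np.concatenate(groups)
        grp = np.repeat(["a", "b", "c", "d"], 50)
        out = anova_tukey(vals, grp)
        assert out["p"] < 1e-4
        assert out["pairwise"][("a", "d")] < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([1.0, 2.0], ["a", "b"])  # n=1 groups
        with pytest.raises(ValueError):
            anova_tukey([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])  # no variance


class TestDichotomizeMedian:
    def test_one_to_five(self):
        lab = dichotomize_median([1.0, 2.0, 3.0, 4.0, 5.0])
        assert list(lab) == ["low", "low", "low", "high", "high"]

    def test_even_n_distinct_values_balance(self, rng):
        v = rng.permutation(np.arange(20, dtype=float))
        lab = dichotomize_median(v)
        assert (lab == "high").sum() == (lab == "low").sum() == 10

    def test_ties_at_median_go_low(self):
        v = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 9.0])
        lab = dichotomize_median(v)
        oracle = np.where(v > np.median(v), "high", "low")
        assert list(lab) == list(oracle)
        assert (lab == "low").sum() == 4

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_median([2.0, 2.0, 2.0])


class TestKaplanMeier:
    def test_uncensored_steps_and_median_convention(self):
        km = km_estimate(SurvivalData(time=[1.0, 2.0, 3.0, 4.0], event=[1, 1, 1, 1]))
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        # S hits exactly 0.5 at t=2: median is the midpoint to the next event
        assert km.median_days == pytest.approx(2.5)

    def test_all_censored(self):
        km = km_estimate(SurvivalData(time=[5.0, 6.0, 7.0], event=[0, 0, 0]))
        assert km.times.size == 0
        assert np.isnan(km.median_days)

    def test_hand_computed_product_limit_with_censoring(self):
        # t=1 death (n=6), t=2 censored, t=3 death (n=4), t=5 death (n=2)
        sd = SurvivalData(
            time=[1.0, 2.0, 3.0, 3.5, 5.0, 6.0], event=[1, 0, 1, 0, 1, 0]
        )
        km = km_estimate(sd)
        assert np.allclose(km.times, [1.0, 3.0, 5.0])
        expect = [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 1 / 2]
        assert np.allclose(km.survival, expect)
        assert np.allclose(km.at_risk, [6, 4, 2])

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 50)
        km = km_estimate(SurvivalData(time=t, event=np.ones(50, int)))
        for tt, s in zip(km.times, km.survival):
            assert s == pytest.approx((t > tt).mean())

    def test_median_months_conversion(self):
        km = km_estimate(SurvivalData(time=[100.0, 200.0, 300.0], event=[1, 1, 1]))
        assert km.median_months == pytest.approx(km.median_days / 30.44)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 1, 0, 1] * 2)
        g = np.repeat(["a", "b"], 4)
        res = logrank(SurvivalData(time=t, event=e, group=g), compute_hr=False)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_o_minus_e(self):
        # 8 subjects, no censoring, no ties; O-E table computed by hand
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        e = np.ones(8, int)
        g = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        # at t=1..8: n1/n = 4/8,3/7,2/6,1/5,0/4,0/3,0/2,0/1; d=1 each
        e1 = 4 / 8 + 3 / 7 + 2 / 6 + 1 / 5
        v = sum(
            (n1 / n) * (1 - n1 / n) for n1, n in [(4, 8), (3, 7), (2, 6), (1, 5)]
        )
        chi2_hand = (4 - e1) ** 2 / v
        res = logrank(SurvivalData(time=t, event=e, group=g), compute_hr=False)
        assert res.chi2 == pytest.approx(chi2_hand, rel=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t, e, x = weibull_cohort(120, beta=0.4, censor_scale=800, seed=5)
        g = x > 0
        res = logrank(
            SurvivalData(time=t, event=e, group=np.where(g, "hi", "lo")),
            compute_hr=False,
        )
        ll = logrank_test(t[g], t[~g], e[g], e[~g])
        assert res.chi2 == pytest.approx(ll.test_statistic, rel=1e-10)
        assert res.p == pytest.approx(ll.p_value, rel=1e-10)

    def test_relabeling_invariance(self):
        t, e, x = weibull_cohort(60, beta=0.5, seed=7)
        g = np.where(x > 0, "one", "two")
        a = logrank(SurvivalData(time=t, event=e, group=g), compute_hr=False)
        g2 = np.where(x > 0, "two", "one")
        b = logrank(SurvivalData(time=t, event=e, group=g2), compute_hr=False)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)

    def test_zero_events_rejected(self):
        sd = SurvivalData(
            time=[1.0, 2.0, 3.0, 4.0], event=[0, 0, 0, 0],
            group=["a", "a", "b", "b"],
        )
        with pytest.raises(ValueError, match="events"):
            logrank(sd)


class TestCox:
    def test_matches_lifelines_continuous_times(self):
        from lifelines import CoxPHFitter

        t, e, x = weibull_cohort(250, beta=0.5, censor_scale=900, seed=1)
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": x, "z": rng.normal(size=250)})
        mine = cox_fit(t, e, X, standardize=False)
        df = X.assign(T=t, E=e)
        ref = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(mine.summary["beta"], ref.params_.values, atol=1e-5)
        assert np.allclose(mine.summary["se"], ref.standard_errors_.values, atol=1e-5)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        t, e, x = weibull_cohort(200, beta=0.5, censor_scale=900, seed=3)
        t = np.ceil(t / 50.0)  # heavy ties
        X = pd.DataFrame({"x": x})
        mine = cox_fit(t, e, X, ties="efron", standardize=False)
        ref = CoxPHFitter().fit(X.assign(T=t, E=e), "T", "E")
        assert mine.summary["beta"].iloc[0] == pytest.approx(
            ref.params_.iloc[0], abs=1e-5
        )

    def test_efron_equals_breslow_without_ties(self):
        t, e, x = weibull_cohort(150, beta=0.4, seed=4)
        X = pd.DataFrame({"x": x})
        a = cox_fit(t, e, X, ties="efron", standardize=False)
        b = cox_fit(t, e, X, ties="breslow", standardize=False)
        assert a.summary["beta"].iloc[0] == b.summary["beta"].iloc[0]

    def test_score_statistic_approximates_logrank(self):
        # known equivalence at beta=0 on two-group data without ties
        t, e, x = weibull_cohort(200, beta=0.6, seed=6)
        g = (x > 0).astype(float)
        res = logrank(
            SurvivalData(time=t, event=e, group=np.where(g > 0, "a", "b")),
            compute_hr=False,
        )
        _, grad, hess = _score_at_zero(t, e, g)
        score = float(grad**2 / -hess)
        assert abs(score - res.chi2) / res.chi2 < 0.01

    def test_standardized_hr_is_per_sd(self):
        t, e, x = weibull_cohort(300, beta=0.5, seed=8)
        X = pd.DataFrame({"x": 10.0 * x})  # inflate the natural scale
        per_sd = cox_fit(t, e, X, standardize=True)
        raw = cox_fit(t, e, X, standardize=False)
        sd = X["x"].std(ddof=0)
        assert per_sd.summary["beta"].iloc[0] == pytest.approx(
            raw.summary["beta"].iloc[0] * sd, rel=1e-4
        )
        assert bool(per_sd.summary["per_sd"].iloc[0])

    def test_hr_ci_contains_hr_and_p_in_unit_interval(self):
        t, e, x = weibull_cohort(100, beta=0.3, seed=9)
        res = cox_fit(t, e, pd.DataFrame({"x": x}))
        row = res.summary.iloc[0]
        assert row["ci_lo"] < row["hr"] < row["ci_hi"]
        assert 0 < row["p"] <= 1
        assert row["hr"] > 0

    def test_constant_covariate_rejected(self):
        t, e, _ = weibull_cohort(50, seed=10)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(t, e, pd.DataFrame({"c": np.ones(50)}))

    def test_perfect_separation_raises(self):
        # every decedent carries the largest covariate in its risk set:
        # the partial likelihood is monotone and beta runs away
        t = np.arange(1.0, 21.0)
        e = np.ones(20, int)
        x = -t.copy()
        with pytest.raises(ConvergenceError, match="monotone"):
            cox_fit(t, e, pd.DataFrame({"x": x}), standardize=False)

    def test_too_few_events_rejected(self):
        t = np.arange(1.0, 6.0)
        e = np.array([1, 0, 0, 0, 0])
        X = pd.DataFrame({"a": np.arange(5.0), "b": np.arange(5.0) ** 2})
        with pytest.raises(ValueError, match="events"):
            cox_fit(t, e, X)


def _score_at_zero(t, e, g):
    """Partial-likelihood value/gradient/Hessian at beta = 0 for a single
    covariate, using the module's own packing."""
    import glymph.stats as gs

    X = np.asarray(g, float).reshape(-1, 1)
    order = np.argsort(-np.asarray(t), kind="stable")
    ts, es, Xs = np.asarray(t)[order], np.asarray(e)[order], X[order]
    ev_times = np.unique(ts[es == 1])[::-1]
    risk_idx, grp_starts, grp_sizes, ev_x_sum, ev_members = [], [], [], [], []
    for tt in ev_times:
        k = np.searchsorted(-ts, -tt, side="right")
        risk_idx.append(k - 1)
        members = np.flatnonzero((ts == tt) & (es == 1))
        grp_starts.append(members[0])
        grp_sizes.append(members.size)
        ev_members.append(members)
        ev_x_sum.append(Xs[members].sum(axis=0))
    packed = (Xs, np.asarray(risk_idx), grp_starts, grp_sizes, ev_x_sum, ev_members, False)
    ll, grad, hess = gs._partial_lik(np.zeros(1), Xs, packed)
    return ll, grad[0], hess[0, 0]
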
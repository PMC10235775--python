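"""Kaplan-Meier, log-rank, Cox partial likelihood and the screening rule."""

import numpy as np
import pandas as pd
import pytest

import lifelines
from lifelines.statistics import logrank_test as ll_logrank

from combiscreen import simdata
from combiscreen.survscreen import (
    DegenerateSplitError,
    ScreenCriteria,
    cox_fit,
    cox_score_test,
    five_year_gap,
    km_estimate,
    logrank_test,
    median_split,
    risk_gene_lists,
    screen_genes,
)

# frozen 8-sample two-group oracle, computed by a brute-force hypergeometric
# tally over the pooled distinct event times
ORACLE_8SAMPLE = dict(
    low=dict(time=[1, 3, 5, 7], event=[1, 1, 1, 0]),
    high=dict(time=[2, 4, 6, 8], event=[1, 1, 0, 1]),
    chi2=0.36506362584696733,
    p=0.545707388017475,
)


class TestMedianSplit:
    def test_even_split(self):
        high = median_split([1, 2, 3, 4])
        assert list(high) == [False, False, True, True]

    def test_ties_go_low(self):
        high = median_split([1, 1, 2, 2])
        assert list(high) == [False, False, True, True]

    def test_constant_gene_rejected(self):
        with pytest.raises(DegenerateSplitError):
            median_split([5, 5, 5, 5])


class TestKaplanMeier:
    def test_product_limit_hand_example(self):
        curve = km_estimate([1, 2, 3], [1, 1, 0])
        assert np.allclose(curve.times, [1, 2])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3])
        assert curve.survival_at(2.5) == pytest.approx(1 / 3)
        assert curve.survival_at(0.5) == 1.0

    def test_no_events_flat_curve(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_no_censoring_reduces_to_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1.0, 50)
        curve = km_estimate(t, np.ones(50, dtype=int))
        for q in [0.2, 0.5, 1.0, 2.0]:
            assert curve.survival_at(q) == pytest.approx((t > q).mean())

    def test_nonincreasing_and_matches_lifelines(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10.0, 200)
        e = (rng.random(200) < 0.7).astype(int)
        t = np.where(e == 1, t, t * rng.random(200))
        curve = km_estimate(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-15)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for q in np.quantile(t, [0.1, 0.4, 0.7, 0.95]):
            assert curve.survival_at(q) == pytest.approx(float(kmf.predict(q)), abs=1e-10)

    def test_matches_exponential_survivor_function(self):
        """Large uncensored exponential cohort: sup-norm error below 0.02."""
        rng = np.random.default_rng(2)
        lam = 0.2
        t = rng.exponential(1 / lam, 5000)
        curve = km_estimate(t, np.ones(5000, dtype=int))
        grid = np.linspace(0.1, 15, 60)
        err = max(abs(curve.survival_at(x) - np.exp(-lam * x)) for x in grid)
        assert err < 0.02


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_frozen_brute_force_oracle(self):
        o = ORACLE_8SAMPLE
        chi2, p = logrank_test(
            o["low"]["time"], o["low"]["event"], o["high"]["time"], o["high"]["event"]
        )
        assert chi2 == pytest.approx(o["chi2"], abs=1e-12)
        assert p == pytest.approx(o["p"], abs=1e-12)

    def test_symmetric_in_group_labels(self, small_cohort):
        df = small_cohort
        g = df["group"] == 1
        a = logrank_test(df.time[~g], df.event[~g], df.time[g], df.event[g])
        b = logrank_test(df.time[g], df.event[g], df.time[~g], df.event[~g])
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_no_events_warns_p_one(self):
        chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_lifelines(self):
        for seed in range(5):
            df = simdata.simulate_two_group_cohort(150, hr=1.8, seed=seed)
            g = df["group"] == 1
            chi2, p = logrank_test(df.time[~g], df.event[~g], df.time[g], df.event[g])
            ref = ll_logrank(df.time[~g], df.time[g], df.event[~g], df.event[g])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestCox:
    def test_duplicated_data_null_identity(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 0, 1, 1, 0])
        x = np.concatenate([np.zeros(6), np.ones(6)])
        res = cox_fit(x, np.tile(t, 2), np.tile(e, 2))
        assert res.beta == pytest.approx(0.0, abs=1e-8)
        assert res.hr == pytest.approx(1.0, abs=1e-8)

    def test_parameter_recovery_true_hr_two(self):
        df = simdata.simulate_two_group_cohort(1000, hr=2.0, seed=7)
        res = cox_fit(df["group"], df["time"], df["event"])
        assert res.converged
        assert abs(res.hr - 2.0) / 2.0 < 0.10

    def test_matches_lifelines_untied(self, small_cohort):
        df = small_cohort
        res = cox_fit(df["group"], df["time"], df["event"])
        cph = lifelines.CoxPHFitter().fit(df[["time", "event", "group"]], "time", "event")
        assert res.beta == pytest.approx(cph.params_["group"], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_["group"], abs=1e-6)
        assert res.p == pytest.approx(cph.summary.loc["group", "p"], rel=1e-4)

    def test_matches_lifelines_efron_with_ties(self):
        rng = np.random.default_rng(8)
        t = rng.integers(1, 15, 120).astype(float)  # heavy ties
        e = (rng.random(120) < 0.7).astype(int)
        x = (rng.random(120) < 0.5).astype(float)
        res = cox_fit(x, t, e, ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")  # lifelines uses Efron
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_score_test_reproduces_logrank(self):
        for seed in range(10):
            df = simdata.simulate_two_group_cohort(200, hr=1.5, seed=seed)
            g = (df["group"] == 1).to_numpy()
            chi2, _ = logrank_test(
                df.time[~g], df.event[~g], df.time[g], df.event[g]
            )
            score, _ = cox_score_test(g.astype(float), df["time"], df["event"])
            assert abs(chi2 - score) < 1e-6

    def test_monotone_likelihood_flagged(self):
        # perfect separation of event order: group 1 always dies first
        t = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        e = np.ones(8, dtype=int)
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        res = cox_fit(x, t, e)
        assert not res.converged
        assert abs(res.beta) == pytest.approx(20.0)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="vary"):
            cox_fit([1, 1, 1], [1, 2, 3], [1, 1, 0])


class TestFiveYearGap:
    def test_identical_curves_zero_gap(self):
        c = km_estimate([1, 2, 3, 4], [1, 0, 1, 0])
        assert five_year_gap(c, c, 2.5).gap == 0.0

    def test_hand_difference(self):
        low = km_estimate([1, 10], [1, 0])    # S(1.5) = 1/2
        high = km_estimate([1, 2, 10, 11], [1, 1, 0, 0])  # S(1.5) = 3/4
        res = five_year_gap(low, high, 1.5)
        assert res.gap == pytest.approx(0.25)
        assert not res.extrapolated

    def test_horizon_before_first_event(self):
        low = km_estimate([5, 6], [1, 1])
        high = km_estimate([7, 8], [1, 1])
        assert five_year_gap(low, high, 1.0).gap == 0.0

    def test_extrapolation_flagged(self):
        low = km_estimate([1, 2], [1, 1])
        high = km_estimate([1, 30], [1, 0])
        assert five_year_gap(low, high, 10.0).extrapolated


@pytest.fixture(scope="module")
def planted_screen():
    spec = simdata.SurvivalSimSpec(
        n_samples=400, n_genes=40, frac_prognostic=0.1, seed=21
    )
    expr, surv, truth = simdata.simulate_survival_cohort(spec)
    screen = screen_genes(expr, surv, ScreenCriteria())
    return screen, truth


class TestScreen:
    def test_pass_rule_is_conjunction(self, planted_screen):
        screen, _ = planted_screen
        c = ScreenCriteria()
        expected = (
            (screen["km_p"] < c.km_alpha)
            & (screen["cox_p"] < c.cox_alpha)
            & (screen["gap_5yr"] > c.min_5yr_gap)
        )
        assert (screen["passed"] == expected).all()

    def test_planted_genes_recovered_with_matching_class(self, planted_screen):
        screen, truth = planted_screen
        planted = truth[truth["prognostic"]].set_index("gene")
        recovered = screen.loc[planted.index]
        assert recovered["passed"].mean() >= 0.75
        passed = recovered[recovered["passed"]]
        expect = np.where(planted.loc[passed.index, "beta"] > 0, "high_risk", "low_risk")
        assert (passed["risk_class"] == expect).all()

    def test_risk_class_none_unless_passed(self, planted_screen):
        screen, _ = planted_screen
        assert (screen.loc[~screen["passed"], "risk_class"] == "none").all()
        high, low = risk_gene_lists(screen)
        assert set(high) | set(low) == set(screen.index[screen["passed"]])

    def test_hr_direction_matches_risk_class(self, planted_screen):
        screen, _ = planted_screen
        passed = screen[screen["passed"]]
        assert ((passed["hr"] > 1) == (passed["risk_class"] == "high_risk")).all()

    def test_sample_mismatch_rejected(self):
        spec = simdata.SurvivalSimSpec(n_samples=20, n_genes=5, seed=1)
        expr, surv, _ = simdata.simulate_survival_cohort(spec)
        bad = surv.copy()
        bad.loc[0, "sample"] = "INTRUDER"
        with pytest.raises(ValueError, match="INTRUDER"):
            screen_genes(expr, bad)

    def test_constant_gene_skipped_with_nan_row(self):
        spec = simdata.SurvivalSimSpec(n_samples=30, n_genes=4, seed=2)
        expr, surv, _ = simdata.simulate_survival_cohort(spec)
        expr.iloc[0] = 3.14
        screen = screen_genes(expr, surv)
        row = screen.iloc[0]
        assert np.isnan(row["km_p"]) and not row["passed"]

    def test_null_cohort_rarely_passes(self):
        """beta = 0, 500 genes: at alpha 0.001 the triple rule passes at most
        about one gene per cohort on average."""
        counts = []
        for seed in range(20):
            spec = simdata.SurvivalSimSpec(
                n_samples=200, n_genes=500, frac_prognostic=0.0, seed=seed
            )
            expr, surv, _ = simdata.simulate_survival_cohort(spec)
            screen = screen_genes(expr, surv)
            counts.append(int(screen["passed"].sum()))
        assert float(np.mean(counts)) <= 1.0

    def test_continuous_covariate_recovers_per_unit_hr(self):
        # a single planted gene so no other gene acts as frailty
        spec = simdata.SurvivalSimSpec(
            n_samples=800, n_genes=2, frac_prognostic=0.5, beta=np.log(2), seed=5
        )
        expr, surv, truth = simdata.simulate_survival_cohort(spec)
        gene = truth[truth["beta"] > 0]["gene"].iloc[0]
        res = cox_fit(expr.loc[gene] - expr.loc[gene].mean(), surv["time"], surv["event"])
        assert abs(res.hr - 2.0) / 2.0 < 0.15
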
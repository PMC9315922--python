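import numpy as np
import pytest
from hypothesis import given, strategies as st

from mutspec.simulate import draw_survival
from mutspec.survival import (
    SurvivalSample,
    cox_fit,
    cox_score_test,
    format_p,
    km_fit,
    logrank_test,
    pairwise_logrank,
    ttft_report,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        """times 1,2,3,4 all events -> S = 0.75, 0.5, 0.25, 0; median 2."""
        c = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(c.survival_prob, [0.75, 0.5, 0.25, 0.0])
        assert c.median == 2

    def test_all_censored(self):
        c = km_fit([1, 2, 3], [0, 0, 0])
        assert c.event_times.size == 0
        assert c.median is None
        assert c.survival_at(10) == 1.0

    def test_single_event(self):
        c = km_fit([5.0], [1])
        assert c.survival_at(5.0) == 0.0 and c.median == 5.0

    def test_censoring_decrements_risk_without_drop(self):
        # event at 1 (n=4), censor at 2, event at 3 (n=2): S = 3/4, 3/8
        c = km_fit([1, 2, 3, 4], [1, 0, 1, 0])
        assert np.allclose(c.survival_prob, [0.75, 0.375])

    @given(st.integers(0, 1000))
    def test_no_censoring_equals_empirical(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(2.0, size=30)
        c = km_fit(t, np.ones(30, bool))
        for q in rng.uniform(0, 6, size=5):
            assert c.survival_at(q) == pytest.approx((t > q).mean())

    def test_accepts_samples(self):
        c = km_fit([SurvivalSample(1.0, True), SurvivalSample(2.0, False)])
        assert c.n_samples == 2

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_fit([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t, e = [1, 2, 3, 4], [1, 0, 1, 1]
        r = logrank_test(t, e, t, e)
        assert r.chi_square == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        ta = rng.uniform(1, 2, 50)
        tb = rng.uniform(10, 11, 50)
        ones = np.ones(50, bool)
        r = logrank_test(ta, ones, tb, ones)
        assert r.p_value < 1e-4

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(1, 40), rng.exponential(2, 40)
        ea = rng.uniform(size=40) < 0.7
        eb = rng.uniform(size=40) < 0.7
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.chi_square == pytest.approx(r2.chi_square)

    def test_invariant_under_monotone_rescaling(self):
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(1, 40), rng.exponential(2, 40)
        ea = rng.uniform(size=40) < 0.7
        eb = rng.uniform(size=40) < 0.7
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(np.exp(ta), ea, np.exp(tb), eb)
        assert r1.chi_square == pytest.approx(r2.chi_square)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [0, 0], [3], [0])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(7)
        ta, tb = rng.exponential(2, 60), rng.exponential(3, 60)
        ea = rng.uniform(size=60) < 0.6
        eb = rng.uniform(size=60) < 0.6
        ours = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_pairwise_matrix(self):
        rng = np.random.default_rng(8)
        groups = {
            k: (rng.exponential(s, 30), rng.uniform(size=30) < 0.8)
            for k, s in [("a", 1.0), ("b", 1.0), ("c", 5.0)]
        }
        mat = pairwise_logrank(groups)
        assert mat.shape == (3, 3)
        assert mat.loc["a", "b"] == mat.loc["b", "a"]
        assert mat.loc["a", "c"] < mat.loc["a", "b"]


class TestCox:
    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError, match="degenerate covariate"):
            cox_fit(np.ones(20), np.arange(1, 21), np.ones(20, bool))

    def test_binary_hr_recovery(self):
        """Two-arm exponential data with true HR 2.0 at n=2000."""
        rng = np.random.default_rng(10)
        x = (np.arange(2000) % 2).astype(float)
        t = rng.exponential(np.exp(-np.log(2.0) * x))
        fit = cox_fit(x, t, np.ones(2000, bool), names=["arm"])
        assert fit.converged
        assert 1.85 <= fit.hazard_ratios[0] <= 2.15

    def test_agrees_with_lifelines_no_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(11)
        n = 250
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.exp(-(0.5 * x1 - 0.3 * x2)))
        e = rng.uniform(size=n) < 0.75
        fit = cox_fit(np.column_stack([x1, x2]), t, e, names=["x1", "x2"])
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e.astype(int), "x1": x1, "x2": x2}), "t", "e"
        )
        np.testing.assert_allclose(fit.coef, cph.params_.values, rtol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, rtol=1e-5)

    def test_efron_ties_agree_with_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(12)
        n = 200
        x = rng.normal(size=n)
        # integer times force heavy ties
        t = np.ceil(rng.exponential(3 * np.exp(-0.4 * x))) + 1
        e = rng.uniform(size=n) < 0.8
        fit = cox_fit(x, t, e, names=["x"], ties="efron")
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e.astype(int), "x": x}), "t", "e"
        )
        # 1e-5: bounded by the reference optimizer's own stopping precision
        np.testing.assert_allclose(fit.coef, cph.params_.values, rtol=1e-5)

    def test_score_test_equals_logrank_breslow(self):
        # the identity is exact only without tied event times: with ties the
        # Mantel-Cox variance carries a (n-d)/(n-1) hypergeometric factor
        # that the Cox information at beta=0 does not
        rng = np.random.default_rng(13)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(2 * np.exp(-0.5 * x))
        e = rng.uniform(size=n) < 0.8
        chi2, _ = cox_score_test(x, t, e, ties="breslow")
        lr = logrank_test(t[x == 0], e[x == 0], t[x == 1], e[x == 1])
        assert chi2 == pytest.approx(lr.chi_square, rel=1e-9)

    def test_two_variable_recovery(self):
        """Additive log-hazard beta1*n_total + beta2*log_ratio with beta1 =
        -0.05, beta2 = 0 at n=3000: both recovered within 3 se."""
        rng = np.random.default_rng(14)
        n = 3000
        n_total = rng.integers(1, 37, n).astype(float)
        log_ratio = rng.normal(size=n)
        lp = -0.05 * n_total
        t, e = draw_survival(rng, lp, 1.0, 3.2, 0.12, 25.0)
        fit = cox_fit(
            np.column_stack([n_total, log_ratio]), t, e, names=["n_total", "log_ratio"]
        )
        assert abs(fit.coef[0] - (-0.05)) < 3 * fit.se[0]
        assert abs(fit.coef[1]) < 3 * fit.se[1]

    def test_wald_ci_and_hr_consistency(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=100)
        t = rng.exponential(np.exp(-0.3 * x))
        fit = cox_fit(x, t, np.ones(100, bool))
        lo, hi = fit.wald_ci_95[0]
        assert lo < fit.hazard_ratios[0] < hi
        assert fit.hazard_ratios[0] == pytest.approx(np.exp(fit.coef[0]))


class TestReport:
    def test_format_p_floor(self):
        assert format_p(0.00005) == "< 0.0001"
        assert format_p(0.0626) == "0.0626"

    def test_ttft_report_structure(self, fixture_table):
        rep = ttft_report(fixture_table, "ratio_group")
        assert set(rep["strata"]) == {"UNDEFINED", "LOW", "HIGH"}
        low = rep["strata"]["LOW"]
        assert low["n"] == 6 and 0 <= low["n_treated"] <= 6
        assert rep["pairwise_p"].shape == (3, 3)

    def test_empty_stratum_omitted(self, fixture_table):
        rep = ttft_report(fixture_table, "mutation_bin", order=["0", "13-15"])
        assert "13-15" not in rep["strata"]
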
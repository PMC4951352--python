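import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from reosig import survival as surv

from .oracles import cox_loglik_1d, harrell_c, km_product_limit, logrank_chi2


class TestKmCurve:
    def test_all_censored_is_flat_at_one(self):
        km = surv.km_curve([3.0, 5.0, 8.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_three_events_closed_form(self):
        km = surv.km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(
            km.loc[[1.0, 2.0, 3.0], "survival"], [2 / 3, 1 / 3, 0.0], rtol=1e-12
        )

    def test_matches_product_limit_loop(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 40).round(1) + 0.1
        events = rng.integers(0, 2, 40)
        km = surv.km_curve(times, events)
        oracle = km_product_limit(times, events)
        for t, s in oracle.items():
            assert km.loc[t, "survival"] == pytest.approx(s, rel=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            surv.km_curve([], [])


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        times = [2.0, 4.0, 6.0, 2.0, 4.0, 6.0]
        events = [1, 1, 0, 1, 1, 0]
        chi2, p = surv.logrank_test(times, events, [True, True, True, False, False, False])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_statistic(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(12, 30).round(1) + 0.1
        events = rng.integers(0, 2, 30)
        group = rng.random(30) < 0.5
        chi2, p = surv.logrank_test(times, events, group)
        expected = logrank_chi2(times, events, group)
        assert chi2 == pytest.approx(expected, abs=1e-8)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-8)

    def test_relabeling_groups_is_symmetric(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(12, 25) + 0.1
        events = rng.integers(0, 2, 25)
        group = rng.random(25) < 0.4
        assert surv.logrank_test(times, events, group)[0] == pytest.approx(
            surv.logrank_test(times, events, ~group)[0], rel=1e-10
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            surv.logrank_test([1.0, 2.0], [1, 1], [True, True])


class TestCoxFit:
    def test_constant_covariate_reported_by_name(self):
        with pytest.raises(ValueError, match="flat"):
            surv.cox_fit(
                [1.0, 2.0, 3.0, 4.0],
                [1, 1, 1, 0],
                pd.DataFrame({"flat": [1.0, 1.0, 1.0, 1.0], "x": [0.0, 1.0, 0.0, 1.0]}),
            )

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            surv.cox_fit([1.0, 2.0], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))

    def test_unknown_values_dropped_casewise(self):
        fit = surv.cox_fit(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [1, 1, 0, 1, 0, 1],
            pd.DataFrame({"x": [0.0, 1.0, "unknown", 1.0, 0.0, 1.0]}, dtype=object),
        )
        assert fit.n_used == 5

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(3)
        n, hr_true = 500, 3.0
        x = rng.random(n) < 0.5
        t_event = rng.exponential(1.0 / (0.02 * np.where(x, hr_true, 1.0)))
        t_cens = rng.exponential(50, n)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
        fit = surv.cox_fit(times, events, pd.DataFrame({"x": x.astype(float)}))
        assert 2.4 <= fit.hr("x") <= 3.75
        assert np.exp(fit.summary.loc["x", "coef"]) == pytest.approx(fit.hr("x"))

    def test_coefficient_matches_brute_force_likelihood_grid(self):
        # four observations, distinct times, continuous covariate: the 1-d
        # partial likelihood has an interior maximum found by grid/scalar search
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        x = [0.5, -1.0, 1.5, 0.0]
        fit = surv.cox_fit(times, events, pd.DataFrame({"x": x}))
        res = minimize_scalar(
            lambda b: -cox_loglik_1d(b, times, events, x), bounds=(-5, 5), method="bounded"
        )
        # agreement limited by lifelines' own Newton stopping tolerance
        assert fit.summary.loc["x", "coef"] == pytest.approx(res.x, abs=5e-4)


class TestCoxBinaryBatch:
    def test_matches_lifelines_per_pair(self):
        rng = np.random.default_rng(4)
        n = 150
        times = rng.exponential(40, n).round(1) + 0.1  # rounding forces ties
        events = rng.integers(0, 2, n)
        x = rng.random((10, n)) < rng.uniform(0.2, 0.8, (10, 1))
        batch = surv.cox_binary_batch(times, events, x)
        for i in range(10):
            fit = surv.cox_fit(times, events, pd.DataFrame({"x": x[i].astype(float)}))
            if batch.loc[i, "separated"]:
                continue
            assert batch.loc[i, "coef"] == pytest.approx(
                fit.summary.loc["x", "coef"], abs=1e-3
            )
            assert batch.loc[i, "p"] == pytest.approx(fit.p("x"), abs=1e-3)

    def test_flags_monotone_likelihood(self):
        # the covariate group is immortal: partial likelihood has no maximum
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([[False, False, False, True, True, True]])
        batch = surv.cox_binary_batch(times, events, x)
        assert bool(batch.loc[0, "separated"])

    def test_agrees_with_logrank_significance_ordering(self):
        # Wald (Cox) and score (log-rank) tests should order effect sizes the
        # same way across a sweep of simulated hazard ratios
        rng = np.random.default_rng(5)
        cox_p, lr_p = [], []
        for hr in np.linspace(1.0, 4.0, 30):
            n = 80
            x = rng.random(n) < 0.5
            t_event = rng.exponential(1.0 / (0.05 * np.where(x, hr, 1.0)))
            t_cens = rng.exponential(30, n)
            times = np.minimum(t_event, t_cens)
            events = (t_event <= t_cens).astype(int)
            fit = surv.cox_binary_batch(times, events, x[None, :])
            if fit.loc[0, "separated"]:
                continue
            cox_p.append(fit.loc[0, "p"])
            lr_p.append(surv.logrank_test(times, events, x)[1])
        rho = stats.spearmanr(cox_p, lr_p).statistic
        assert rho > 0.95


class TestCIndex:
    def test_perfect_ordering_without_censoring(self):
        times = [10.0, 8.0, 6.0, 4.0, 2.0]
        events = [1, 1, 1, 1, 1]
        risk = [1.0, 2.0, 3.0, 4.0, 5.0]  # higher risk, shorter survival
        assert surv.c_index(risk, times, events) == 1.0

    def test_constant_risk_scores_half(self):
        assert surv.c_index([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1]) == 0.5

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(10, 15) + 0.1
        events = rng.integers(0, 2, 15)
        risk = rng.integers(0, 3, 15).astype(float)
        assert surv.c_index(risk, times, events) == pytest.approx(
            harrell_c(risk, times, events), rel=1e-12
        )

    def test_complementarity_without_predictor_ties(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(10, 20) + 0.1
        events = rng.integers(0, 2, 20)
        risk = rng.normal(0, 1, 20)  # continuous: no ties
        c_pos = surv.c_index(risk, times, events)
        c_neg = surv.c_index(-risk, times, events)
        assert c_pos + c_neg == pytest.approx(1.0, abs=1e-12)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError):
            surv.c_index([1.0, 2.0], [5.0, 6.0], [0, 0])


class TestCompareGroups:
    def test_reports_consistent_summary(self, small_cohort):
        _, clinical, truth = small_cohort
        cohort = clinical[clinical["stage"] == "II"].index
        high = np.array([truth.latent_risk[s] == "high" for s in cohort])
        comp = surv.compare_groups(
            clinical.loc[cohort, "rfs_time"], clinical.loc[cohort, "rfs_event"], high
        )
        assert comp.hr > 1.0
        assert comp.ci95[0] <= comp.hr <= comp.ci95[1]
        assert 0.0 <= comp.c_index <= 1.0
        assert comp.n_high + comp.n_low == len(cohort)
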
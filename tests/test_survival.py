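"""Survival substrate: closed forms, cross-library oracles, the
residual-sum/log-rank identity."""
import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from esmdr.survival import (
    SurvivalData,
    fit_cox_null,
    km_curve,
    km_eval,
    logrank,
    martingale_residuals,
    null_martingale_residuals,
)

from conftest import random_survival


class TestCoxNull:
    def test_nelson_aalen_closed_form(self):
        data = SurvivalData([1, 2, 3, 4], [1, 1, 1, 1])
        fit = fit_cox_null(data)
        np.testing.assert_allclose(
            fit.baseline_cumhaz, np.cumsum([1 / 4, 1 / 3, 1 / 2, 1.0])
        )
        assert fit.beta.size == 0

    def test_null_beta_within_3se_of_zero(self, rng):
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        T = rng.exponential(1.0, n)  # true beta = 0
        C = rng.uniform(0, 2.5, n)
        data = SurvivalData(np.minimum(T, C), (T <= C).astype(int), x[:, None])
        fit = fit_cox_null(data)
        assert abs(fit.beta[0]) < 3 * fit.beta_se[0]

    def test_matches_lifelines_to_1e6(self, cox_dataset):
        fit = fit_cox_null(cox_dataset)
        df = pd.DataFrame(
            {"T": cox_dataset.time, "E": cox_dataset.status,
             "x0": cox_dataset.covariates[:, 0], "x1": cox_dataset.covariates[:, 1]}
        )
        cph = CoxPHFitter()
        cph.fit(df, "T", "E")
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-6)
        assert abs(fit.loglik - cph.log_likelihood_) < 1e-6

    def test_order_invariant(self, rng):
        data = random_survival(rng, n=80, p_cov=2)
        fit = fit_cox_null(data)
        perm = rng.permutation(data.n)
        fit_p = fit_cox_null(data.subset(perm))
        np.testing.assert_allclose(fit.beta, fit_p.beta, rtol=1e-10)
        np.testing.assert_allclose(fit.baseline_cumhaz, fit_p.baseline_cumhaz, rtol=1e-10)

    def test_error_cases(self):
        with pytest.raises(ValueError, match="no events"):
            fit_cox_null(SurvivalData([1, 2, 3], [0, 0, 0]))
        with pytest.raises(ValueError, match="constant"):
            fit_cox_null(SurvivalData([1, 2, 3], [1, 1, 0], np.ones((3, 1))))


class TestMartingaleResiduals:
    def test_censored_before_first_event_is_zero(self):
        data = SurvivalData([0.5, 1, 2], [0, 1, 1])
        r = null_martingale_residuals(data)
        assert r[0] == 0.0

    def test_all_events_closed_form(self):
        data = SurvivalData([1, 2, 3, 4], [1, 1, 1, 1])
        r = null_martingale_residuals(data)
        assert r[0] == pytest.approx(1 - 1 / 4)

    def test_bounded_above_and_zero_sum(self, rng):
        for _ in range(5):
            data = random_survival(rng, n=120, p_cov=1)
            r = null_martingale_residuals(data)
            assert np.all(r <= 1.0)
            assert abs(r.sum()) < 1e-8 * data.n

    def test_matches_lifelines_to_1e6(self, cox_dataset):
        fit = fit_cox_null(cox_dataset)
        ours = martingale_residuals(fit, cox_dataset).values
        df = pd.DataFrame(
            {"T": cox_dataset.time, "E": cox_dataset.status,
             "x0": cox_dataset.covariates[:, 0], "x1": cox_dataset.covariates[:, 1]}
        )
        cph = CoxPHFitter()
        cph.fit(df, "T", "E", fit_options={"precision": 1e-12})
        theirs = cph.compute_residuals(df, "martingale")["martingale"]
        np.testing.assert_allclose(ours, theirs.loc[df.index].values, atol=1e-6)

    def test_extrapolates_flat_beyond_last_event(self):
        data = SurvivalData([1, 2, 3], [1, 1, 0])
        fit = fit_cox_null(data)
        assert fit.cumhaz(100.0) == fit.cumhaz(2.0)


class TestLogRank:
    def test_identical_curves_zero(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        s = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = logrank(SurvivalData(t, s), g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_risk_tables(self):
        # group 1 events at (1, 2), group 0 events at (3, 4)
        data = SurvivalData([1, 2, 3, 4], [1, 1, 1, 1])
        res = logrank(data, np.array([1, 1, 0, 0]))
        # O-E = (1 - 2/4) + (1 - 1/3) + (0 - 0) + (0 - 0)
        assert res.observed - res.expected == pytest.approx(1 - 2 / 4 + 1 - 1 / 3)

    def test_matches_lifelines_to_1e6(self, rng):
        data = random_survival(rng, n=200)
        g = rng.integers(0, 2, 200).astype(bool)
        ours = logrank(data, g)
        theirs = logrank_test(data.time[g], data.time[~g], data.status[g], data.status[~g])
        assert ours.chi2 == pytest.approx(theirs.test_statistic, abs=1e-6)

    def test_degenerate_grouping_raises(self):
        data = SurvivalData([1, 2], [1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            logrank(data, np.array([1, 1]))


class TestResidualLogrankIdentity:
    """The method's central identity: the sum of null-fit martingale
    residuals over a group equals the group's log-rank O-E numerator."""

    def test_identity_exact(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 80))
            data = random_survival(rng, n=n)
            r = null_martingale_residuals(data)
            g = rng.integers(0, 2, n).astype(bool)
            if g.all() or not g.any():
                continue
            lr = logrank(data, g)
            oe = lr.observed - lr.expected
            assert r[g].sum() == pytest.approx(oe, rel=1e-8, abs=1e-10)


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        data = SurvivalData([1, 2, 3, 4], [1, 1, 1, 1])
        times, surv, at_risk = km_curve(data)["all"]
        np.testing.assert_allclose(surv, [3 / 4, 1 / 2, 1 / 4, 0.0])
        np.testing.assert_array_equal(at_risk, [4, 3, 2, 1])

    def test_all_censored_flat_one(self):
        data = SurvivalData([1, 2, 3], [1, 0, 0])
        sub = data.subset(np.array([1, 2]))
        times, surv, _ = km_curve(sub)["all"]
        assert times.size == 0
        assert km_eval(times, surv, 10.0) == 1.0

    def test_matches_lifelines_to_1e10(self, rng):
        data = random_survival(rng, n=150)
        times, surv, _ = km_curve(data)["all"]
        kmf = KaplanMeierFitter().fit(data.time, data.status)
        theirs = np.array([kmf.predict(t) for t in times])
        np.testing.assert_allclose(surv, theirs, atol=1e-10)

    def test_empty_group_raises(self):
        data = SurvivalData([1, 2], [1, 1])
        with pytest.raises(ValueError, match="empty group"):
            km_curve(data, np.array([1, 1]))
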
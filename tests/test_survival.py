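"""Survival-curve evaluation, censored MLE, and model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from lifelines import LogLogisticFitter

from psmcea.survival import (Family, NoMedianError, ParametricSurvival,
                             PseudoIPD, SurvivalDomainError, fit_all,
                             fit_least_squares, fit_mle,
                             loglogistic_from_scale_form,
                             loglogistic_to_scale_form, median_survival,
                             select_best, survival_at)
from psmcea.synthetic_data import FixtureSpec, simulate_ipd

from conftest import FAMILY_EXAMPLES


class TestClosedForms:
    @pytest.mark.parametrize("family,params", FAMILY_EXAMPLES.items(),
                             ids=[f.value for f in FAMILY_EXAMPLES])
    def test_survival_starts_at_one_and_decreases(self, family, params):
        m = ParametricSurvival(family, params)
        assert survival_at(m, 0.0) == pytest.approx(1.0)
        t = np.linspace(0.0, 120.0, 400)  # model horizon
        s = m.survival(t)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s > 0) & (s <= 1))

    def test_loglogistic_rate_form_closed_expression(self):
        # published intervention PFS curve at the trial's median PFS
        m = ParametricSurvival(Family.LOGLOGISTIC, (1.74, 0.0079))
        assert survival_at(m, 13.7) == pytest.approx(0.5711693758, abs=1e-9)

    def test_exponential_closed_form(self):
        m = ParametricSurvival(Family.EXPONENTIAL, (0.1,))
        assert survival_at(m, 10.0) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_negative_time_rejected(self):
        m = ParametricSurvival(Family.LOGLOGISTIC, (1.74, 0.0079))
        with pytest.raises(SurvivalDomainError, match="t"):
            survival_at(m, -1.0)

    @pytest.mark.parametrize("params", [(0.0, 0.1), (1.5, -2.0)])
    def test_invalid_params_rejected(self, params):
        with pytest.raises(SurvivalDomainError, match="params"):
            ParametricSurvival(Family.LOGLOGISTIC, params)

    @pytest.mark.parametrize("family,params", FAMILY_EXAMPLES.items(),
                             ids=[f.value for f in FAMILY_EXAMPLES])
    def test_density_integrates_to_cdf(self, family, params):
        # integral of f over (0, T) plus S(T) must equal 1
        m = ParametricSurvival(family, params)
        T = 5.0 * m.median()
        integral, _ = integrate.quad(m.density, 1e-12, T, limit=300)
        assert integral + survival_at(m, T) == pytest.approx(1.0, abs=1e-6)


class TestMedian:
    @pytest.mark.parametrize("params,expected", [
        ((1.74, 0.0079), 16.153264050683077),   # implied PFS median, months
        ((2.16, 0.0011), 23.42748177627104),    # implied OS median, months
    ])
    def test_loglogistic_median_closed_form(self, params, expected):
        m = ParametricSurvival(Family.LOGLOGISTIC, params)
        assert median_survival(m) == pytest.approx(expected, rel=1e-12)

    def test_exponential_median(self):
        m = ParametricSurvival(Family.EXPONENTIAL, (np.log(2.0),))
        assert median_survival(m) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("family,params", FAMILY_EXAMPLES.items(),
                             ids=[f.value for f in FAMILY_EXAMPLES])
    def test_median_consistent_with_survival(self, family, params):
        m = ParametricSurvival(family, params)
        assert survival_at(m, median_survival(m)) == pytest.approx(0.5, abs=1e-9)

    def test_plateauing_gompertz_has_no_median(self):
        # strongly negative shape: hazard decays, S plateaus above 0.5
        m = ParametricSurvival(Family.GOMPERTZ, (-1.0, 0.1))
        with pytest.raises(NoMedianError):
            median_survival(m)


class TestLogLogisticProperties:
    """Invariants over the whole valid log-logistic parameter space."""

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(g=st.floats(0.2, 8.0), lam=st.floats(1e-6, 10.0),
           t=st.floats(0.0, 500.0))
    def test_survival_in_unit_interval_and_exact_form(self, g, lam, t):
        m = ParametricSurvival(Family.LOGLOGISTIC, (g, lam))
        s = survival_at(m, t)
        assert 0.0 < s <= 1.0
        assert s == pytest.approx(1.0 / (1.0 + lam * t**g) if t > 0 else 1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(g=st.floats(0.2, 8.0), lam=st.floats(1e-6, 10.0))
    def test_median_and_scale_form_consistent(self, g, lam):
        m = ParametricSurvival(Family.LOGLOGISTIC, (g, lam))
        assert survival_at(m, median_survival(m)) == pytest.approx(0.5, abs=1e-9)
        alpha, beta = loglogistic_to_scale_form(m)
        back = loglogistic_from_scale_form(alpha, beta)
        assert back.params == pytest.approx(m.params, rel=1e-9)


class TestParameterizationConversion:
    def test_round_trip_both_ways(self):
        m = ParametricSurvival(Family.LOGLOGISTIC, (1.74, 0.0079))
        alpha, beta = loglogistic_to_scale_form(m)
        back = loglogistic_from_scale_form(alpha, beta)
        assert back.params == pytest.approx(m.params, rel=1e-12)
        # scale-form alpha is the median
        assert alpha == pytest.approx(median_survival(m), rel=1e-12)

    def test_scale_form_matches_rate_form_evaluation(self):
        alpha, beta = 16.0, 1.8
        m = loglogistic_from_scale_form(alpha, beta)
        t = np.array([1.0, 8.0, 16.0, 40.0])
        assert m.survival(t) == pytest.approx(1.0 / (1.0 + (t / alpha) ** beta))


class TestFitting:
    def test_exponential_mle_matches_closed_form(self, rng):
        times = rng.exponential(1.0 / 0.05, size=2000)
        data = PseudoIPD(times, np.ones_like(times, dtype=int))
        report = fit_mle(data, Family.EXPONENTIAL)
        assert report.converged
        assert report.fitted_params[0] == pytest.approx(1.0 / times.mean(), rel=1e-6)
        k, ll = 1, report.log_likelihood
        assert report.aic == pytest.approx(2 * k - 2 * ll, rel=1e-12)
        assert report.bic == pytest.approx(k * np.log(len(times)) - 2 * ll, rel=1e-12)

    def test_loglogistic_parameter_recovery(self):
        data = simulate_ipd(FixtureSpec(gamma=2.0, lam=0.001, n=5000, seed=42))
        report = fit_mle(data, Family.LOGLOGISTIC)
        g, lam = report.fitted_params
        assert g == pytest.approx(2.0, rel=0.05)
        assert lam == pytest.approx(0.001, rel=0.15)

    def test_recovery_under_censoring(self):
        data = simulate_ipd(FixtureSpec(gamma=1.74, lam=0.0079, n=5000,
                                        censoring_fraction=0.25, seed=7))
        report = fit_mle(data, Family.LOGLOGISTIC)
        assert report.fitted_params[0] == pytest.approx(1.74, rel=0.05)
        assert report.fitted_params[1] == pytest.approx(0.0079, rel=0.15)

    def test_matches_lifelines_loglogistic(self):
        # independent implementation cross-check (lifelines uses the scale form)
        data = simulate_ipd(FixtureSpec(gamma=1.74, lam=0.0079, n=2000,
                                        censoring_fraction=0.2, seed=3))
        ours = fit_mle(data, Family.LOGLOGISTIC)
        llf = LogLogisticFitter().fit(data.times, data.events)
        theirs = loglogistic_from_scale_form(llf.alpha_, llf.beta_)
        assert ours.fitted_params == pytest.approx(theirs.params, rel=1e-3)
        assert ours.log_likelihood == pytest.approx(llf.log_likelihood_, rel=1e-6)

    def test_loglogistic_wins_aic_on_loglogistic_data(self):
        data = simulate_ipd(FixtureSpec(gamma=2.0, lam=0.001, n=5000, seed=42))
        reports = fit_all(data)
        best = select_best(reports, "aic")
        assert best.family is Family.LOGLOGISTIC

    def test_too_few_records_rejected(self):
        data = PseudoIPD([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="at least 10"):
            fit_mle(data, Family.EXPONENTIAL)

    def test_all_censored_rejected(self):
        data = PseudoIPD(np.ones(20), np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="event"):
            fit_mle(data, Family.EXPONENTIAL)


class TestSelectBest:
    def test_argmin(self):
        reports = fit_all(
            simulate_ipd(FixtureSpec(gamma=2.0, lam=0.001, n=500, seed=0)),
            families=(Family.EXPONENTIAL, Family.WEIBULL),
        )
        best = select_best(reports, "aic")
        assert best.aic == min(r.aic for r in reports)

    def test_tie_breaks_by_family_order_and_is_flagged(self):
        from psmcea.survival import FitReport
        a = FitReport(Family.LOGLOGISTIC, (1.0, 1.0), -50.0, 100.0, 101.0, 20)
        b = FitReport(Family.WEIBULL, (1.0, 1.0), -50.0, 100.0, 101.0, 20)
        best = select_best([a, b], "aic")
        assert best.family is Family.WEIBULL  # earlier in enum order
        assert best.tie

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([], "aic")


class TestLeastSquaresRefit:
    def test_noiseless_refit_is_exact(self):
        m = ParametricSurvival(Family.LOGLOGISTIC, (1.74, 0.0079))
        t = np.linspace(0.0, 60.0, 41)
        refit = fit_least_squares(t, m.survival(t))
        assert refit.params == pytest.approx(m.params, rel=1e-6)


class TestTrialConsistency:
    """Medians implied by the published curve parameters, in months, must
    bracket the reported trial medians — the check that pins the time unit."""

    @pytest.mark.parametrize("params,trial_median", [
        ((1.74, 0.0079), 13.7),  # intervention PFS
        ((2.18, 0.0052), 10.4),  # control PFS
        ((2.02, 0.00099), 32.1),  # intervention OS
        ((2.16, 0.0011), 22.8),  # control OS
    ])
    def test_implied_median_near_trial_median(self, params, trial_median):
        implied = median_survival(ParametricSurvival(Family.LOGLOGISTIC, params))
        assert 0.6 < implied / trial_median < 1.6
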
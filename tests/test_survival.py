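"""Flexible parametric PH model: closed forms, likelihood, and MLE recovery."""

import numpy as np
import pytest

from jointrisk.errors import UnfittableError, ValidationError
from jointrisk.splines import KnotSet, basis_value
from jointrisk.survival import (
    FlexPHModel,
    SurvivalDataset,
    baseline_cum_hazard,
    cum_hazard,
    event_probability,
    fit,
    hazard,
    log_likelihood,
)

from conftest import make_exponential_dataset

EMPTY = np.array([])


def exp_model(rate=1.0, shape=1.0):
    return FlexPHModel(
        beta=EMPTY,
        gamma=np.array([np.log(rate), shape]),
        knots=KnotSet(-3.0, 3.0),
    )


class TestBaselineCumHazard:
    def test_unit_exponential(self, unit_exp_model):
        assert baseline_cum_hazard(unit_exp_model, 3.0) == pytest.approx(3.0)

    def test_rate_scaled_exponential(self):
        assert baseline_cum_hazard(exp_model(rate=0.2), 5.0) == pytest.approx(1.0)

    def test_spline_term_composes_with_basis(self):
        knots = KnotSet(0.0, 2.0, (1.0,))
        model = FlexPHModel(beta=EMPTY, gamma=np.array([0.0, 1.0, 0.3]), knots=knots)
        nu1 = basis_value(knots, 1.0)[0]
        assert baseline_cum_hazard(model, np.e) == pytest.approx(np.exp(1 + 0.3 * nu1))

    def test_identity_scale_returns_literal_sum(self):
        model = FlexPHModel(
            beta=EMPTY, gamma=np.array([0.5, 0.25]), knots=KnotSet(-3.0, 3.0),
            scale="identity",
        )
        t = 2.0
        assert baseline_cum_hazard(model, t) == pytest.approx(0.5 + 0.25 * np.log(t))

    def test_nonpositive_time_rejected(self, unit_exp_model):
        with pytest.raises(ValidationError):
            baseline_cum_hazard(unit_exp_model, 0.0)
        with pytest.raises(ValidationError):
            baseline_cum_hazard(unit_exp_model, -1.0)

    def test_gamma_length_must_match_knots(self):
        with pytest.raises(ValidationError):
            FlexPHModel(beta=EMPTY, gamma=np.array([0.0, 1.0]),
                        knots=KnotSet(0.0, 2.0, (1.0,)))


class TestCumHazardAndProbability:
    def test_zero_beta_reduces_to_baseline(self, unit_exp_model):
        model = FlexPHModel(
            beta=np.zeros(2), gamma=unit_exp_model.gamma, knots=unit_exp_model.knots
        )
        x = np.array([1.3, -0.7])
        for t in (0.5, 1.0, 7.0):
            assert cum_hazard(model, x, t) == pytest.approx(
                baseline_cum_hazard(model, t)
            )

    def test_log_two_linear_predictor_doubles_hazard(self, unit_exp_model):
        model = FlexPHModel(
            beta=np.array([np.log(2.0)]), gamma=unit_exp_model.gamma,
            knots=unit_exp_model.knots,
        )
        assert cum_hazard(model, np.array([1.0]), 1.0) == pytest.approx(2.0)

    def test_proportional_hazards_structure(self, unit_exp_model):
        model = FlexPHModel(
            beta=np.array([0.5]), gamma=unit_exp_model.gamma,
            knots=unit_exp_model.knots,
        )
        lam1 = cum_hazard(model, np.array([1.0]), 4.0)
        lam2 = cum_hazard(model, np.array([3.0]), 4.0)
        assert lam2 / lam1 == pytest.approx(np.exp(0.5 * 2.0))

    def test_dimension_mismatch(self, unit_exp_model):
        with pytest.raises(ValidationError):
            cum_hazard(unit_exp_model, np.array([1.0]), 1.0)

    def test_event_probability_closed_form(self, unit_exp_model):
        assert event_probability(unit_exp_model, EMPTY, 1.0) == pytest.approx(
            1 - np.exp(-1), abs=1e-12
        )

    def test_event_probability_limits(self):
        tiny = exp_model(rate=1e-14)
        huge = exp_model(rate=1e14)
        assert event_probability(tiny, EMPTY, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert event_probability(huge, EMPTY, 1.0) == pytest.approx(1.0)


class TestHazard:
    def test_constant_for_unit_exponential(self, unit_exp_model):
        for t in (0.2, 1.0, 5.0):
            assert hazard(unit_exp_model, EMPTY, t) == pytest.approx(1.0)

    def test_weibull_closed_form(self):
        # Lambda0 = 0.2 t^2 -> h(1) = 0.4
        assert hazard(exp_model(rate=0.2, shape=2.0), EMPTY, 1.0) == pytest.approx(0.4)

    def test_matches_finite_difference_of_cum_hazard(self):
        knots = KnotSet(np.log(0.1), np.log(20.0), (0.0,))
        model = FlexPHModel(
            beta=np.array([0.4]), gamma=np.array([-1.0, 0.9, 0.1]), knots=knots
        )
        x = np.array([1.0])
        for t in (0.3, 1.0, 2.5, 8.0):
            h = 1e-6 * t
            fd = (cum_hazard(model, x, t + h) - cum_hazard(model, x, t - h)) / (2 * h)
            assert hazard(model, x, t) == pytest.approx(fd, rel=1e-5)


class TestLogLikelihood:
    def test_single_censored_row(self, unit_exp_model):
        data = SurvivalDataset(np.empty((1, 0)), [2.0], [0], ())
        assert log_likelihood(unit_exp_model, data) == pytest.approx(-2.0)

    def test_single_event_row(self, unit_exp_model):
        data = SurvivalDataset(np.empty((1, 0)), [2.0], [1], ())
        assert log_likelihood(unit_exp_model, data) == pytest.approx(-2.0)

    def test_maximised_at_closed_form_exponential_mle(self):
        data = make_exponential_dataset(rate=0.5, n=400, seed=4)
        rate_hat = data.n_events / data.time.sum()
        ll_hat = log_likelihood(exp_model(rate=rate_hat), data)
        for factor in (0.9, 0.95, 1.05, 1.1):
            assert log_likelihood(exp_model(rate=rate_hat * factor), data) < ll_hat

    def test_sentinel_for_nonpositive_event_hazard(self):
        model = FlexPHModel(
            beta=EMPTY, gamma=np.array([0.0, -1.0]), knots=KnotSet(-3.0, 3.0)
        )
        data = SurvivalDataset(np.empty((1, 0)), [1.0], [1], ())
        assert log_likelihood(model, data) <= -1e9


class TestFit:
    def test_exponential_rate_recovery(self):
        data = make_exponential_dataset(rate=0.2, n=5000, seed=1)
        model = fit(data, m=0)
        closed_form = data.n_events / data.time.sum()
        assert np.exp(model.gamma[0]) == pytest.approx(closed_form, rel=0.05)
        assert 0.95 <= model.gamma[1] <= 1.05
        assert model.converged

    def test_weibull_equivalence_with_independent_mle(self):
        # m = 0 is exactly Weibull: cross-check against lifelines' fitter
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        t = 2.0 * rng.weibull(1.5, 5000)
        data = SurvivalDataset(np.empty((5000, 0)), t, np.ones(5000, int), ())
        model = fit(data, m=0)
        wf = lifelines.WeibullFitter().fit(t, np.ones(5000))
        # H(t) = (t/lambda)^rho  <->  gamma1 = rho, gamma0 = -rho log lambda
        assert model.gamma[1] == pytest.approx(wf.rho_, abs=1e-3)
        assert np.exp(-model.gamma[0] / model.gamma[1]) == pytest.approx(
            wf.lambda_, abs=1e-3 * wf.lambda_
        )

    def test_binary_covariate_recovery_with_censoring(self):
        rng = np.random.default_rng(12)
        n = 5000
        x = rng.integers(0, 2, n).astype(float)[:, None]
        true_beta = 0.7
        t = rng.exponential(1.0 / (0.2 * np.exp(true_beta * x[:, 0])))
        censor = 5.0
        d = (t <= censor).astype(int)
        data = SurvivalDataset(x, np.minimum(t, censor), d, ("grp",))
        model = fit(data, m=0)
        assert 0.6 <= model.beta[0] <= 0.8

    def test_refit_is_bit_identical(self):
        data = make_exponential_dataset(rate=0.3, n=500, seed=9, censor=4.0)
        m1 = fit(data, m=1)
        m2 = fit(data, m=1)
        assert np.array_equal(m1.beta, m2.beta)
        assert np.array_equal(m1.gamma, m2.gamma)

    def test_covariate_shift_invariance(self):
        rng = np.random.default_rng(5)
        n = 1500
        x = rng.normal(size=(n, 1))
        t = rng.exponential(1.0 / (0.3 * np.exp(0.5 * x[:, 0])))
        d = np.ones(n, int)
        data = SurvivalDataset(x, t, d, ("z",))
        shifted = SurvivalDataset(x + 10.0, t, d, ("z",))
        m_orig = fit(data, m=1)
        m_shift = fit(shifted, m=1)
        for i in range(20):
            lam0 = cum_hazard(m_orig, x[i], t[i])
            lam1 = cum_hazard(m_shift, x[i] + 10.0, t[i])
            assert lam1 == pytest.approx(lam0, rel=1e-4)

    def test_bias_shrinks_with_sample_size(self):
        def beta_err(n, seed):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(n, 1))
            t = rng.exponential(1.0 / (0.2 * np.exp(0.6 * x[:, 0])))
            data = SurvivalDataset(x, t, np.ones(n, int), ("z",))
            return abs(fit(data, m=0).beta[0] - 0.6)

        errs_small = np.mean([beta_err(500, s) for s in range(5)])
        errs_large = np.mean([beta_err(5000, s) for s in range(5)])
        assert errs_large < errs_small

    def test_no_events_unfittable(self):
        data = SurvivalDataset(np.empty((3, 0)), [1.0, 2.0, 3.0], [0, 0, 0], ())
        with pytest.raises(UnfittableError):
            fit(data, m=0)

    def test_collinear_covariates_unfittable(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(100, 1))
        X = np.hstack([x, 2 * x])
        data = SurvivalDataset(X, rng.exponential(1, 100), np.ones(100, int),
                               ("a", "b"))
        with pytest.raises(UnfittableError):
            fit(data, m=0)

    def test_fitted_event_probability_monotone_in_time(self, small_cohort):
        from jointrisk.filters import apply_filters, recode_competing_event
        kept = apply_filters(small_cohort).kept
        for target in ("death", "revision"):
            ds = recode_competing_event(kept, target)
            model = fit(ds, m=2)
            assert model.baseline_monotone
            tgrid = np.linspace(ds.time.min(), ds.time.max(), 100)
            x = ds.X[0]
            probs = event_probability(model, x, tgrid)
            assert np.all(np.diff(probs) >= -1e-12)


class TestDatasetValidation:
    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalDataset(np.empty((2, 0)), [0.0, 1.0], [1, 1], ())

    def test_event_indicator_must_be_binary(self):
        with pytest.raises(ValidationError):
            SurvivalDataset(np.empty((2, 0)), [1.0, 2.0], [1, 2], ())
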
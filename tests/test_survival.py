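"""Survivor function, cycle-probability conversion, sampling and MLE fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from kidneyce import (
    ConvergenceError,
    FittingError,
    ParametricFit,
    SurvivalDataset,
    WeibullParams,
    cycle_transition_probability,
    fit_parametric,
    fit_summary_table,
    sample_time_to_event,
    select_best_fit,
    survival_at,
)
from kidneyce.survival import inverse_survival

WL = WeibullParams(0.0315, 1.4346)
GF = WeibullParams(0.0698, 0.3944)

positive_params = st.builds(
    WeibullParams,
    rate_lambda=st.floats(1e-3, 5.0),
    shape_gamma=st.floats(0.2, 4.0),
)


class TestSurvivalAt:
    def test_waitlist_mortality_at_five_years(self):
        # frozen from direct evaluation of exp(-lambda * t**gamma)
        assert survival_at(WL, 5.0) == pytest.approx(0.7283341257078796, abs=1e-12)

    def test_exponential_subfamily_closed_form(self):
        assert survival_at(WeibullParams(0.1, 1.0), 10.0) == pytest.approx(math.exp(-1))

    @given(positive_params)
    def test_starts_at_one_and_is_nonincreasing(self, p):
        t = np.linspace(0, 50, 201)
        s = survival_at(p, t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= 0) & (s <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(WL, -0.1)


class TestCycleTransitionProbability:
    def test_first_cycle_reduces_to_cumulative_incidence(self):
        p = cycle_transition_probability(GF, cycle_end=1.0, cycle_length=1.0)
        assert p == pytest.approx(1 - math.exp(-0.0698), abs=1e-12)
        assert p == pytest.approx(1 - survival_at(GF, 1.0), abs=1e-15)

    def test_memoryless_when_shape_is_one(self):
        p = WeibullParams(0.2, 1.0)
        probs = [cycle_transition_probability(p, t, 0.5) for t in (0.5, 1.0, 7.5, 40.0)]
        assert probs == pytest.approx([1 - math.exp(-0.1)] * 4, abs=1e-14)

    def test_cycle_end_before_cycle_length_rejected(self):
        with pytest.raises(ValueError):
            cycle_transition_probability(GF, cycle_end=0.4, cycle_length=0.5)

    @given(positive_params, st.integers(1, 60), st.sampled_from([0.125, 0.25, 0.5, 1.0]))
    def test_telescoping_back_to_survivor_function(self, p, n_cycles, u):
        """Product of per-cycle survival probabilities telescopes to S(K*u)."""
        surv = 1.0
        for k in range(1, n_cycles + 1):
            surv *= 1.0 - cycle_transition_probability(p, k * u, u)
        assert surv == pytest.approx(survival_at(p, n_cycles * u), abs=1e-12)


class TestSampling:
    def test_inverse_transform_identity(self):
        # U forced to exp(-lambda) must map to T = 1 exactly
        for p in (WL, GF, WeibullParams(0.5, 2.0)):
            assert inverse_survival(p, math.exp(-p.rate_lambda)) == pytest.approx(1.0)

    def test_sampled_times_match_analytic_survivor_function(self, rng):
        p = WeibullParams(0.0502, 0.9305)
        t = sample_time_to_event(p, rng, size=100_000)
        assert np.all(t > 0)
        d = stats.kstest(t, lambda x: 1.0 - survival_at(p, x)).statistic
        assert d < 0.01

    def test_exponential_mean(self, rng):
        t = sample_time_to_event(WeibullParams(0.1, 1.0), rng, size=100_000)
        assert t.mean() == pytest.approx(10.0, rel=0.02)


class TestDatasetValidation:
    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            SurvivalDataset(np.array([1.0, 0.0]), np.array([True, True]))

    def test_csv_roundtrip(self, tmp_path):
        data = SurvivalDataset(np.array([1.5, 2.0, 0.25]), np.array([True, False, True]))
        data.to_csv(tmp_path / "d.csv")
        back = SurvivalDataset.read_csv(tmp_path / "d.csv")
        np.testing.assert_allclose(back.times, data.times)
        np.testing.assert_array_equal(back.events, data.events)


class TestFitting:
    def test_uncensored_exponential_matches_closed_form_mle(self, rng):
        rate = 0.13
        t = rng.exponential(1 / rate, size=4000)
        data = SurvivalDataset(t, np.ones(t.size, dtype=bool))
        fit = fit_parametric(data, "exponential")
        # closed form: rate_hat = events / total observed time
        assert fit.params.rate_lambda == pytest.approx(t.size / t.sum(), rel=1e-6)
        assert fit.params.shape_gamma == 1.0

    def test_weibull_parameter_recovery(self, rng):
        true = WeibullParams(0.0698, 0.3944)
        t = sample_time_to_event(true, rng, size=5000)
        fit = fit_parametric(SurvivalDataset(t, np.ones(t.size, bool)), "weibull")
        est = fit.params
        assert abs(est.rate_lambda - true.rate_lambda) < 3 * est.se_lambda
        assert abs(est.shape_gamma - true.shape_gamma) < 3 * est.se_gamma
        assert est.se_lambda > 0 and est.se_gamma > 0

    def test_weibull_shape_near_one_on_exponential_data(self, rng):
        t = rng.exponential(10.0, size=5000)
        fit = fit_parametric(SurvivalDataset(t, np.ones(t.size, bool)), "weibull")
        assert abs(fit.params.shape_gamma - 1.0) < 3 * fit.params.se_gamma

    def test_information_criteria_identity(self, rng):
        t = rng.weibull(1.3, 500) * 8
        data = SurvivalDataset(t, np.ones(t.size, bool))
        for family in ("exponential", "weibull", "log-logistic", "log-normal"):
            fit = fit_parametric(data, family)
            assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.n_params)
            assert fit.aic - fit.bic == pytest.approx(
                2 * fit.n_params - fit.n_params * math.log(fit.n_obs)
            )

    def test_weibull_likelihood_dominates_exponential(self, rng):
        """The exponential is the shape=1 sub-family, so its ML cannot exceed Weibull's."""
        t = sample_time_to_event(WeibullParams(0.05, 1.6), rng, size=800)
        cens = t > 12.0
        data = SurvivalDataset(np.minimum(t, 12.0), ~cens)
        f_w = fit_parametric(data, "weibull")
        f_e = fit_parametric(data, "exponential")
        assert f_w.log_likelihood >= f_e.log_likelihood - 1e-6

    def test_no_events_raises_fitting_error(self):
        data = SurvivalDataset(np.ones(20), np.zeros(20, bool))
        with pytest.raises(FittingError):
            fit_parametric(data, "weibull")

    def test_unknown_family_rejected(self):
        data = SurvivalDataset(np.ones(20), np.ones(20, bool))
        with pytest.raises(ValueError):
            fit_parametric(data, "gompertz")


def _fit(family, aic_half, bic_half, n_params=2, n_obs=1000):
    # build a ParametricFit with the requested AIC/BIC via its log-likelihood
    ll = -(aic_half - 2 * n_params) / 2
    fit = ParametricFit(family, None, ll, n_params, n_obs)
    assert fit.aic == pytest.approx(aic_half)
    return fit


class TestSelectBestFit:
    def test_graft_failure_model_comparison_prefers_weibull(self):
        # AIC values of the four families for the graft-failure transition
        n = 1000
        fits = [
            _fit("exponential", 1060.2, None, 1, n),
            _fit("weibull", 896.1, None, 2, n),
            _fit("log-logistic", 898.4, None, 2, n),
            _fit("log-normal", 909.0, None, 2, n),
        ]
        assert select_best_fit(fits).family == "weibull"
        assert select_best_fit(fits).aic == pytest.approx(896.1)

    def test_aic_tie_broken_by_bic(self):
        # same AIC, different n_params => different BIC; lower BIC wins
        a = ParametricFit("weibull", None, -450.0, 2, 1000)
        b = ParametricFit("exponential", None, -451.0, 1, 1000)
        assert b.aic == pytest.approx(a.aic)
        assert b.bic < a.bic
        assert select_best_fit([a, b]).family == "exponential"

    def test_single_fit_returned(self):
        f = _fit("weibull", 100.0, None)
        assert select_best_fit([f]) is f

    def test_mismatched_dataset_sizes_rejected(self):
        with pytest.raises(ValueError):
            select_best_fit([_fit("weibull", 10, None, 2, 100), _fit("exponential", 12, None, 1, 200)])


def test_fit_summary_table_layout(rng):
    t1 = sample_time_to_event(WeibullParams(0.07, 0.4), rng, size=400)
    t2 = sample_time_to_event(WeibullParams(0.03, 1.4), rng, size=400)
    table = fit_summary_table(
        {
            "graft_failure": SurvivalDataset(t1, np.ones(t1.size, bool)),
            "death_waitlisted": SurvivalDataset(t2, np.ones(t2.size, bool)),
        }
    )
    assert list(table.index) == ["graft_failure", "death_waitlisted"]
    for fam in ("exponential", "weibull", "log-logistic", "log-normal"):
        assert f"aic_{fam}" in table.columns and f"bic_{fam}" in table.columns
    # BIC >= AIC for n >= 8 at these parameter counts
    assert (table.filter(like="bic_").to_numpy() >= table.filter(like="aic_").to_numpy() - 1e-9).all()
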
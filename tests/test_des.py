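"""Discrete-event simulation: accrual closed forms, determinism, distributions."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats

import kidneyce as k
from kidneyce import DESConfig, WeibullParams, run_population, simulate_patient
from kidneyce.des import (
    _patient_from_uniforms,
    stabilization_curve,
    stable_population_size,
)

FAR = {  # hazards so small that no event occurs within any tested horizon
    name: WeibullParams(1e-12, 1.0)
    for name in (
        "graft_failure",
        "death_post_transplant",
        "death_post_graft_failure",
        "death_waitlisted",
    )
}


class TestSinglePatient:
    def test_waitlist_survivor_cost_is_discounted_annuity(self, econ):
        """A patient on dialysis for the whole 5-yr horizon accrues the
        closed-form annuity 81,689 * (1 - 1.05^-5) / ln(1.05); frozen value
        computed independently by numeric quadrature."""
        hist = _patient_from_uniforms(
            "waitlist", FAR, econ, 5.0, np.array([[0.5]])
        )
        assert hist.discounted_cost == pytest.approx(362440.4895615, rel=1e-9)
        assert hist.discounted_qaly == pytest.approx(
            0.70 / 81689.0 * hist.discounted_cost, rel=1e-12
        )
        assert hist.intervals == (("waitlisted_on_dialysis", 0.0, 5.0),)
        assert hist.events == ()

    def test_immediate_death_accrues_nothing(self, transitions, econ):
        # a uniform draw of ~1 maps to an event time of ~0
        u = np.array([[0.5, 1.0 - 1e-12, 0.5]])
        hist = _patient_from_uniforms("transplant", transitions, econ, 5.0, u)
        assert hist.discounted_cost == pytest.approx(0.0, abs=1.0)
        assert hist.discounted_qaly == pytest.approx(0.0, abs=1e-4)
        assert hist.events[-1][0] == "death"

    def test_same_seed_bit_identical(self, transitions, econ):
        a = simulate_patient("transplant", transitions, econ, 20.0, np.random.default_rng(7))
        b = simulate_patient("transplant", transitions, econ, 20.0, np.random.default_rng(7))
        assert a == b

    def test_graft_failure_path_intervals_partition_horizon(self, transitions, econ):
        # force an early graft failure and late death on dialysis
        u = np.array([[0.999, 0.5, 0.5]])
        hist = _patient_from_uniforms("transplant", transitions, econ, 5.0, u)
        assert hist.events[0][0] == "graft_failure"
        starts = [iv[1] for iv in hist.intervals]
        ends = [iv[2] for iv in hist.intervals]
        assert starts[0] == 0.0
        assert starts[1:] == ends[:-1]
        assert ends[-1] <= 5.0
        times = [t for _, t in hist.events]
        assert times == sorted(times)

    def test_year1_lump_sum_switch_charges_full_first_year_cost(self, transitions, econ):
        u = np.array([[0.5, 1.0 - 1e-12, 0.5]])  # immediate death
        lump = _patient_from_uniforms("transplant", transitions, econ, 5.0, u, True)
        accrued = _patient_from_uniforms("transplant", transitions, econ, 5.0, u, False)
        assert lump.discounted_cost == pytest.approx(econ.cost_transplant_year1, abs=1.0)
        assert accrued.discounted_cost == pytest.approx(0.0, abs=1.0)


class TestPopulation:
    def test_population_mean_equals_mean_of_patient_histories(self, transitions, econ):
        cfg = DESConfig(n_patients=500, horizon=5.0, seed=42)
        pop = run_population("transplant", transitions, econ, cfg)
        rng = np.random.default_rng(cfg.seed)
        u = rng.uniform(size=(cfg.n_patients, 3))
        costs = [
            _patient_from_uniforms("transplant", transitions, econ, 5.0, u[i : i + 1]).discounted_cost
            for i in range(cfg.n_patients)
        ]
        assert pop.result.discounted_cost == pytest.approx(np.mean(costs), rel=1e-12)

    def test_zero_hazards_deterministic_annuity(self, econ):
        pop = run_population("waitlist", FAR, econ, DESConfig(200, 5.0, 3))
        assert pop.patients["discounted_cost"].std() == pytest.approx(0.0, abs=1e-9)
        assert pop.result.discounted_cost == pytest.approx(362440.4895615, rel=1e-9)
        assert pop.event_proportions["death"] == 0.0

    def test_qaly_equals_restricted_survival_when_utilities_one(self, transitions):
        """With utilities 1, costs 0 and no discounting, mean QALY is mean
        time alive within the horizon (accounting identity), which converges
        to the survivor-function integral."""
        econ1 = replace(
            k.default_econ(),
            utility_transplant=1.0,
            utility_dialysis=1.0,
            cost_transplant_year1=0.0,
            cost_transplant_followup=0.0,
            cost_dialysis=0.0,
            discount_rate=0.0,
        )
        pop = run_population(
            "waitlist", k.default_transitions(), econ1, DESConfig(100_000, 5.0, 11)
        )
        t_death = pop.patients["time_death"].fillna(5.0)
        assert pop.result.discounted_qaly == pytest.approx(t_death.mean(), rel=1e-12)
        # frozen quadrature of the survivor integral over [0, 5]
        exact = 4.40919716637824
        mc_se = t_death.std() / math.sqrt(len(t_death))
        assert abs(pop.result.discounted_qaly - exact) < 3 * mc_se

    def test_event_times_match_weibull_survivor(self, transitions, econ):
        pop = run_population(
            "waitlist", transitions, econ, DESConfig(100_000, 1000.0, 5)
        )
        t = pop.patients["time_death"].dropna().to_numpy()
        p = transitions["death_waitlisted"]
        d = stats.kstest(t, lambda x: 1.0 - k.survival_at(p, x)).statistic
        assert d < 0.01

    def test_density_mass_equals_event_proportion(self, transitions, econ):
        """The retained event-time sample integrates to the event proportion."""
        pop = run_population("transplant", transitions, econ, DESConfig(5000, 5.0, 8))
        n_gf = pop.patients["time_graft_failure"].notna().sum()
        assert n_gf / 5000 == pytest.approx(pop.event_proportions["graft_failure"])
        n_death = pop.patients["time_death"].notna().sum()
        assert n_death / 5000 == pytest.approx(pop.event_proportions["death"])


class TestStabilization:
    def test_curve_rows_and_stable_flag(self, transitions, econ):
        sizes = [200, 400, 800, 1600]
        curve = stabilization_curve("transplant", transitions, econ, sizes, 17, 5.0)
        assert list(curve["n_patients"]) == sizes
        n_star = stable_population_size(curve, tolerance=0.05)
        assert n_star is None or n_star in sizes

    def test_single_size_gives_single_row(self, transitions, econ):
        curve = stabilization_curve("waitlist", transitions, econ, [300], 1, 5.0)
        assert len(curve) == 1

    def test_non_increasing_sizes_rejected(self, transitions, econ):
        with pytest.raises(ValueError):
            stabilization_curve("waitlist", transitions, econ, [400, 400], 1, 5.0)

    def test_nmb_standard_error_shrinks_with_population(self, transitions, econ):
        """SE of mean NMB scales ~1/sqrt(n): quadrupling n roughly halves it."""
        def ses(n, reps=40):
            vals = [
                run_population(
                    "transplant", transitions, econ, DESConfig(n, 5.0, 1000 + r)
                ).result.nmb
                for r in range(reps)
            ]
            return np.std(vals, ddof=1)

        se_small, se_large = ses(250), ses(1000)
        assert se_large < se_small
        assert se_small / se_large == pytest.approx(2.0, rel=0.5)
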
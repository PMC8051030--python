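"""Patient-level discrete-event simulation of both strategies.

Each patient walks the event graph in continuous time.  Transplant arm:
latent times to graft failure (T1) and to death with a functioning graft
(T2) are drawn independently from their Weibull distributions; the earlier
one (before the horizon) occurs.  After graft failure the time to death on
dialysis (T3) is drawn with the clock reset to the graft-failure instant —
unlike the cohort Markov engine, the simulation has memory.  Waitlist arm: a
single time to death on dialysis (T4).  Exact latent-time ties (a
probability-zero event) resolve as death.

Costs and QALYs accrue continuously over state-occupancy intervals,
discounted at the continuous rate ``ln(1 + r)`` (annual-equivalent to the
Markov engine's 5% per year) with closed-form interval integrals.  The
first-year transplant cost accrues at its annual rate over ``[0, 1)`` — a
patient dying at month six incurs half of it — unless ``year1_lump_sum`` is
set, in which case it is charged in full at time zero.  Accrual is truncated
at the horizon.

Randomness: each patient consumes one row of a ``(n, k)`` uniform matrix
drawn from a single seeded generator (k = 3 latent times for the transplant
arm, 1 for the waitlist arm), so results do not depend on iteration order
and the vectorised population path is bit-identical to simulating patients
one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .economics import EconParams, ModelResult, discounted_integral, nmb
from .survival import WeibullParams, inverse_survival

__all__ = [
    "DESConfig",
    "PatientHistory",
    "PopulationResult",
    "simulate_patient",
    "run_population",
    "stabilization_curve",
    "stable_population_size",
]

_N_UNIFORMS = {"transplant": 3, "waitlist": 1}


@dataclass(frozen=True)
class DESConfig:
    """Population size, horizon and seed for one simulation run."""

    n_patients: int = 4000
    horizon: float = 5.0
    seed: int = 0
    year1_lump_sum: bool = False

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


@dataclass(frozen=True)
class PatientHistory:
    """One simulated patient: events, occupancy intervals, discounted accruals.

    ``events`` is an ordered list of ``(event, time)`` with event in
    {'graft_failure', 'death'}; ``intervals`` partitions
    ``[0, min(death, horizon)]`` into ``(state, start, end)`` pieces.
    """

    arm: str
    events: tuple[tuple[str, float], ...]
    intervals: tuple[tuple[str, float, float], ...]
    discounted_cost: float
    discounted_qaly: float


def _latent_times(
    arm: str, params: Mapping[str, WeibullParams], u: np.ndarray
) -> dict[str, np.ndarray]:
    """Map uniform draws (one row per patient) to latent event times."""
    if arm == "waitlist":
        return {"death": inverse_survival(params["death_waitlisted"], u[:, 0])}
    return {
        "graft_failure": inverse_survival(params["graft_failure"], u[:, 0]),
        "death_with_graft": inverse_survival(params["death_post_transplant"], u[:, 1]),
        "death_after_failure": inverse_survival(params["death_post_graft_failure"], u[:, 2]),
    }


def _accrue(
    arm: str,
    econ: EconParams,
    horizon: float,
    t_leave_initial: np.ndarray,
    had_graft_failure: np.ndarray,
    t_end_dialysis: np.ndarray,
    year1_lump_sum: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised discounted cost/QALY accrual given resolved state intervals."""
    r = econ.discount_rate
    if arm == "waitlist":
        cost = discounted_integral(econ.cost_dialysis, 0.0, t_leave_initial, r)
        qaly = discounted_integral(econ.utility_dialysis, 0.0, t_leave_initial, r)
        return np.asarray(cost), np.asarray(qaly)

    t_graft = t_leave_initial
    if year1_lump_sum:
        cost = np.full_like(t_graft, econ.cost_transplant_year1)
        cost += discounted_integral(econ.cost_transplant_followup, 1.0,
                                    np.maximum(t_graft, 1.0), r)
    else:
        cost = np.asarray(
            discounted_integral(econ.cost_transplant_year1, 0.0, np.minimum(t_graft, 1.0), r)
        )
        cost += discounted_integral(econ.cost_transplant_followup, 1.0,
                                    np.maximum(t_graft, 1.0), r)
    qaly = np.asarray(discounted_integral(econ.utility_transplant, 0.0, t_graft, r))
    on_dialysis = had_graft_failure
    cost += np.where(
        on_dialysis,
        discounted_integral(econ.cost_dialysis, t_graft, t_end_dialysis, r),
        0.0,
    )
    qaly += np.where(
        on_dialysis,
        discounted_integral(econ.utility_dialysis, t_graft, t_end_dialysis, r),
        0.0,
    )
    return cost, qaly


def _resolve(
    arm: str, latent: dict[str, np.ndarray], horizon: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resolve latent times into interval endpoints within the horizon.

    Returns ``(t_leave_initial, had_graft_failure, t_end_dialysis, t_death)``
    where ``t_death`` is NaN for patients alive at the horizon and times are
    truncated at the horizon.  Ties between graft failure and death with a
    functioning graft resolve as death.
    """
    if arm == "waitlist":
        t_death_latent = latent["death"]
        t_leave = np.minimum(t_death_latent, horizon)
        died = t_death_latent < horizon
        t_death = np.where(died, t_death_latent, np.nan)
        return t_leave, np.zeros_like(t_leave, dtype=bool), t_leave, t_death

    t1 = latent["graft_failure"]
    t2 = latent["death_with_graft"]
    t3 = latent["death_after_failure"]
    gf = (t1 < t2) & (t1 < horizon)
    t_leave = np.minimum(np.minimum(t1, t2), horizon)
    t_death_latent = np.where(gf, t1 + t3, t2)
    t_end_dialysis = np.where(gf, np.minimum(t_death_latent, horizon), t_leave)
    died = t_death_latent < horizon
    t_death = np.where(died, t_death_latent, np.nan)
    return t_leave, gf, t_end_dialysis, t_death


def simulate_patient(
    arm: str,
    params: Mapping[str, WeibullParams],
    econ: EconParams,
    horizon: float,
    rng: np.random.Generator,
    year1_lump_sum: bool = False,
) -> PatientHistory:
    """Simulate one patient, drawing its uniforms from ``rng``."""
    u = rng.uniform(size=(1, _N_UNIFORMS[arm]))
    return _patient_from_uniforms(arm, params, econ, horizon, u, year1_lump_sum)


def _patient_from_uniforms(
    arm, params, econ, horizon, u, year1_lump_sum=False
) -> PatientHistory:
    latent = _latent_times(arm, params, u)
    t_leave, gf, t_end_d, t_death = _resolve(arm, latent, horizon)
    cost, qaly = _accrue(arm, econ, horizon, t_leave, gf, t_end_d, year1_lump_sum)
    t_leave, gf, t_end_d, t_death = (
        float(t_leave[0]), bool(gf[0]), float(t_end_d[0]), float(t_death[0]),
    )

    events: list[tuple[str, float]] = []
    intervals: list[tuple[str, float, float]] = []
    if arm == "waitlist":
        intervals.append(("waitlisted_on_dialysis", 0.0, t_leave))
        if not np.isnan(t_death):
            events.append(("death", t_death))
    else:
        intervals.append(("functioning_graft", 0.0, t_leave))
        if gf:
            events.append(("graft_failure", t_leave))
            intervals.append(("dialysis_post_graft_failure", t_leave, t_end_d))
        if not np.isnan(t_death):
            events.append(("death", t_death))
    return PatientHistory(
        arm=arm,
        events=tuple(events),
        intervals=tuple(intervals),
        discounted_cost=float(cost[0]),
        discounted_qaly=float(qaly[0]),
    )


@dataclass(frozen=True)
class PopulationResult:
    """A population run: per-arm means, event proportions, per-patient table.

    ``event_proportions`` maps event name to the fraction of patients
    experiencing it within the horizon; ``patients`` has one row per patient
    with event times (NaN if the event did not occur) and discounted
    accruals.
    """

    result: ModelResult
    event_proportions: dict[str, float]
    patients: pd.DataFrame


def run_population(
    arm: str,
    params: Mapping[str, WeibullParams],
    econ: EconParams,
    cfg: DESConfig,
) -> PopulationResult:
    """Simulate ``cfg.n_patients`` independent patients (vectorised)."""
    rng = np.random.default_rng(cfg.seed)
    u = rng.uniform(size=(cfg.n_patients, _N_UNIFORMS[arm]))
    latent = _latent_times(arm, params, u)
    t_leave, gf, t_end_d, t_death = _resolve(arm, latent, cfg.horizon)
    cost, qaly = _accrue(arm, econ, cfg.horizon, t_leave, gf, t_end_d, cfg.year1_lump_sum)

    died = ~np.isnan(t_death)
    proportions = {"death": float(died.mean())}
    table = {
        "patient_id": np.arange(cfg.n_patients),
        "time_death": t_death,
        "discounted_cost": cost,
        "discounted_qaly": qaly,
    }
    if arm == "transplant":
        proportions["graft_failure"] = float(gf.mean())
        table["time_graft_failure"] = np.where(gf, t_leave, np.nan)
    patients = pd.DataFrame(table).set_index("patient_id")

    mean_cost = float(cost.mean())
    mean_qaly = float(qaly.mean())
    result = ModelResult(
        arm=arm,
        discounted_cost=mean_cost,
        discounted_qaly=mean_qaly,
        nmb=nmb(mean_cost, mean_qaly, econ.wtp),
    )
    return PopulationResult(result=result, event_proportions=proportions, patients=patients)


def stabilization_curve(
    arm: str,
    params: Mapping[str, WeibullParams],
    econ: EconParams,
    population_sizes,
    seed: int,
    horizon: float = 5.0,
) -> pd.DataFrame:
    """Mean NMB of independent runs at each population size.

    Used to pick the smallest population whose NMB estimate has settled;
    each size gets an independent random substream.
    """
    sizes = list(population_sizes)
    if not sizes:
        raise ValueError("population_sizes must be non-empty")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("population_sizes must be strictly increasing")
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    rows = []
    for n, child in zip(sizes, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        pop = run_population(
            arm, params, econ, DESConfig(n_patients=n, horizon=horizon, seed=sub_seed)
        )
        rows.append({"n_patients": n, "nmb": pop.result.nmb})
    return pd.DataFrame(rows)


def stable_population_size(curve: pd.DataFrame, tolerance: float = 0.025) -> int | None:
    """Smallest n from which NMB stays within ``tolerance`` of the largest-n value.

    The band is relative to the magnitude of the largest-n estimate.  Returns
    ``None`` if even the final point's predecessors never enter the band.
    """
    nmb_ref = float(curve["nmb"].iloc[-1])
    scale = abs(nmb_ref)
    if scale == 0.0:
        return int(curve["n_patients"].iloc[0])
    within = (curve["nmb"] - nmb_ref).abs() / scale <= tolerance
    # find the earliest index from which every later point is within band
    stable_from = None
    for i in range(len(curve)):
        if within.iloc[i:].all():
            stable_from = int(curve["n_patients"].iloc[i])
            break
    return stable_from
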
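"""Deterministic cohort Markov models of the two strategies.

Transplant arm: three states — ``functioning_graft``,
``dialysis_post_graft_failure`` (return to dialysis after graft failure) and
``dead``.  Waitlist arm: two states — ``waitlisted_on_dialysis`` and
``dead``.  ``dead`` is absorbing.  Per-cycle transition probabilities are
time-dependent, derived from rate-scale Weibull survivor functions via
``1 - S(t) / S(t - u)``.

Clock convention: every transition probability is evaluated on a single
cohort clock (time since model start).  For death after graft failure this
is an approximation forced by the memoryless cohort structure — the model
cannot condition on *when* a patient's graft failed without tunnel states —
and it is the main structural difference from the discrete-event engine,
which resets the clock at graft failure.

Accrual and discounting: with the half-cycle correction enabled (the
default) each cycle credits the life-table average of its start- and
end-of-cycle occupancies, discounted at the cycle midpoint with annual
factor ``(1 + r)^(-t)``.  With it disabled, end-of-cycle occupancy is
credited and discounted at the cycle end.  The first-year transplant cost is
accrued at its annual-equivalent rate over however many cycles make up the
first year, so total first-year spending is identical across cycle lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .economics import EconParams, ModelResult, discount_factor, nmb
from .survival import WeibullParams, cycle_transition_probability

__all__ = [
    "TRANSPLANT_STATES",
    "WAITLIST_STATES",
    "MarkovSpec",
    "CycleConfig",
    "CohortTrace",
    "transition_matrix_at",
    "run_cohort",
]

TRANSPLANT_STATES = ("functioning_graft", "dialysis_post_graft_failure", "dead")
WAITLIST_STATES = ("waitlisted_on_dialysis", "dead")

_REQUIRED_TRANSITIONS = {
    "transplant": ("graft_failure", "death_post_transplant", "death_post_graft_failure"),
    "waitlist": ("death_waitlisted",),
}


@dataclass(frozen=True)
class MarkovSpec:
    """One arm's state space and transition parameters."""

    arm: str
    transition_params: Mapping[str, WeibullParams]

    def __post_init__(self):
        if self.arm not in _REQUIRED_TRANSITIONS:
            raise ValueError(f"arm must be 'transplant' or 'waitlist', got {self.arm!r}")
        missing = [
            t for t in _REQUIRED_TRANSITIONS[self.arm] if t not in self.transition_params
        ]
        if missing:
            raise ValueError(f"{self.arm} arm missing transition parameters: {missing}")

    @property
    def states(self) -> tuple[str, ...]:
        return TRANSPLANT_STATES if self.arm == "transplant" else WAITLIST_STATES

    @classmethod
    def transplant(cls, params: Mapping[str, WeibullParams]) -> "MarkovSpec":
        return cls("transplant", params)

    @classmethod
    def waitlist(cls, params: Mapping[str, WeibullParams]) -> "MarkovSpec":
        return cls("waitlist", params)


@dataclass(frozen=True)
class CycleConfig:
    """Cycle length and horizon (years); horizon must be a whole number of cycles."""

    cycle_length: float = 1.0
    horizon: float = 5.0
    half_cycle_correction: bool = True

    def __post_init__(self):
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.horizon < 0:
            raise ValueError("horizon must be non-negative")
        n = self.horizon / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"horizon {self.horizon} is not an integer multiple of "
                f"cycle_length {self.cycle_length}"
            )

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))


@dataclass
class CohortTrace:
    """Cycle-by-cycle record of a cohort run.

    ``occupancy`` holds state-occupancy proportions at the *end* of each
    cycle (row 0 is the initial distribution).  ``increments`` holds
    per-cycle undiscounted and discounted cost and QALY accruals plus the
    per-cycle inflow of new graft failures and deaths (cumulative-incidence
    building blocks).
    """

    states: tuple[str, ...]
    occupancy: pd.DataFrame
    increments: pd.DataFrame

    @property
    def discounted_cost(self) -> float:
        return float(self.increments["cost_discounted"].sum())

    @property
    def discounted_qaly(self) -> float:
        return float(self.increments["qaly_discounted"].sum())

    def cumulative_incidence(self, event: str) -> float:
        """Total incidence of ``event`` ('graft_failure' or 'death') over the run."""
        return float(self.increments[f"new_{event}"].sum())


class TransitionOverflowError(ValueError):
    """Competing per-cycle exit probabilities exceed 1 — cycle too coarse."""


def transition_matrix_at(
    spec: MarkovSpec, cycle_end: float, cycle_length: float
) -> np.ndarray:
    """Row-stochastic transition matrix for the cycle ending at ``cycle_end``.

    Off-diagonal entries are per-cycle probabilities from the arm's Weibull
    survivor functions evaluated on the cohort clock; the diagonal absorbs
    the remainder and the ``dead`` row is an identity row.
    """
    tp = {
        name: cycle_transition_probability(p, cycle_end, cycle_length)
        for name, p in spec.transition_params.items()
    }
    if spec.arm == "waitlist":
        p_death = tp["death_waitlisted"]
        return np.array([[1.0 - p_death, p_death], [0.0, 1.0]])

    p_gf = tp["graft_failure"]
    p_death_tx = tp["death_post_transplant"]
    p_death_gf = tp["death_post_graft_failure"]
    if p_gf + p_death_tx > 1.0:
        raise TransitionOverflowError(
            f"competing exits from functioning_graft sum to {p_gf + p_death_tx:.4f} > 1 "
            f"at cycle_end={cycle_end}; shorten the cycle"
        )
    return np.array(
        [
            [1.0 - p_gf - p_death_tx, p_gf, p_death_tx],
            [0.0, 1.0 - p_death_gf, p_death_gf],
            [0.0, 0.0, 1.0],
        ]
    )


def _state_cost_rates(spec: MarkovSpec, econ: EconParams, cycle_end: float) -> np.ndarray:
    """Annual cost accrual rate per state for the cycle ending at ``cycle_end``."""
    if spec.arm == "waitlist":
        return np.array([econ.cost_dialysis, 0.0])
    graft_rate = (
        econ.cost_transplant_year1
        if cycle_end <= 1.0 + 1e-9
        else econ.cost_transplant_followup
    )
    return np.array([graft_rate, econ.cost_dialysis, 0.0])


def _state_utilities(spec: MarkovSpec, econ: EconParams) -> np.ndarray:
    if spec.arm == "waitlist":
        return np.array([econ.utility_dialysis, 0.0])
    return np.array([econ.utility_transplant, econ.utility_dialysis, 0.0])


def run_cohort(
    spec: MarkovSpec, cfg: CycleConfig, econ: EconParams
) -> tuple[ModelResult, CohortTrace]:
    """Propagate the cohort and accumulate discounted costs and QALYs.

    The cohort starts with probability 1 in the initial state
    (``functioning_graft`` or ``waitlisted_on_dialysis``).
    """
    states = spec.states
    n_states = len(states)
    u = cfg.cycle_length
    K = cfg.n_cycles
    util = _state_utilities(spec, econ)

    occ = np.zeros((K + 1, n_states))
    occ[0, 0] = 1.0
    rows = []
    for k in range(1, K + 1):
        t_end = k * u
        M = transition_matrix_at(spec, t_end, u)
        occ[k] = occ[k - 1] @ M
        # inflow accounting for cumulative incidence
        if spec.arm == "transplant":
            new_gf = occ[k - 1, 0] * M[0, 1]
            new_death = occ[k - 1, 0] * M[0, 2] + occ[k - 1, 1] * M[1, 2]
        else:
            new_gf = 0.0
            new_death = occ[k - 1, 0] * M[0, 1]

        if cfg.half_cycle_correction:
            credited = 0.5 * (occ[k - 1] + occ[k])
            t_disc = t_end - 0.5 * u
        else:
            credited = occ[k]
            t_disc = t_end
        df = float(discount_factor(t_disc, econ.discount_rate))
        cost_rates = _state_cost_rates(spec, econ, t_end)
        cost_undisc = u * float(credited @ cost_rates)
        qaly_undisc = u * float(credited @ util)
        rows.append(
            {
                "cycle": k,
                "time_end": t_end,
                "cost_undiscounted": cost_undisc,
                "qaly_undiscounted": qaly_undisc,
                "cost_discounted": df * cost_undisc,
                "qaly_discounted": df * qaly_undisc,
                "new_graft_failure": new_gf,
                "new_death": new_death,
            }
        )

    occupancy = pd.DataFrame(occ, columns=list(states))
    occupancy.index.name = "cycle"
    increments = pd.DataFrame(
        rows,
        columns=[
            "cycle",
            "time_end",
            "cost_undiscounted",
            "qaly_undiscounted",
            "cost_discounted",
            "qaly_discounted",
            "new_graft_failure",
            "new_death",
        ],
    ).set_index("cycle")
    trace = CohortTrace(states=states, occupancy=occupancy, increments=increments)
    cost = trace.discounted_cost
    qaly = trace.discounted_qaly
    result = ModelResult(
        arm=spec.arm,
        discounted_cost=cost,
        discounted_qaly=qaly,
        nmb=nmb(cost, qaly, econ.wtp),
    )
    return result, trace
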
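"""Economic evaluation layer: discounting, NMB, incremental analysis, PSA.

All monetary values are 2020 Australian dollars; effects are
quality-adjusted life years (QALYs).  Net monetary benefit is
``NMB = WTP * QALY - cost`` with a willingness-to-pay threshold of
AUD 28,000 per QALY, and both costs and QALYs are discounted at 5% per
year.  The incremental comparison follows the cost-saving sign convention:
``delta_cost = comparator_cost - intervention_cost`` (positive = saving) and
``delta_effect = intervention_qaly - comparator_qaly``, so a dominant
intervention has both deltas positive and
``delta_nmb = wtp * delta_effect + delta_cost``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .survival import WeibullParams

__all__ = [
    "EconParams",
    "ModelResult",
    "IncrementalResult",
    "PSADistributions",
    "PSAResult",
    "discount_factor",
    "discounted_integral",
    "nmb",
    "incremental",
    "run_psa",
]


@dataclass(frozen=True)
class EconParams:
    """Utilities, annual cost rates, WTP threshold and discount rate.

    Utilities are QALY weights per year in a health state; costs are annual
    accrual rates in AUD.  ``cost_transplant_year1`` applies during the first
    year after transplantation, ``cost_transplant_followup`` thereafter while
    the graft functions; ``cost_dialysis`` applies in every dialysis state
    (waitlisted or post graft failure).
    """

    utility_transplant: float = 0.82
    utility_dialysis: float = 0.70
    cost_transplant_year1: float = 115_725.0
    cost_transplant_followup: float = 16_110.0
    cost_dialysis: float = 81_689.0
    wtp: float = 28_000.0
    discount_rate: float = 0.05

    def __post_init__(self):
        for name in ("utility_transplant", "utility_dialysis"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {u}")
        for name in ("cost_transplant_year1", "cost_transplant_followup", "cost_dialysis"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")

    @property
    def continuous_rate(self) -> float:
        """Continuously-compounded rate ``ln(1 + r)`` equivalent to the annual rate."""
        return math.log1p(self.discount_rate)


def discount_factor(t, annual_rate: float):
    """Discrete-time discount factor ``(1 + r)**(-t)`` at time ``t`` years."""
    return (1.0 + annual_rate) ** (-np.asarray(t, dtype=float))


def discounted_integral(rate_per_year: float, start, end, annual_rate: float):
    """Closed-form present value of a constant accrual over ``[start, end]``.

    Integrates ``rate_per_year * exp(-r_c t)`` with the continuous rate
    ``r_c = ln(1 + annual_rate)``; handles a zero discount rate exactly.
    Vectorised over ``start``/``end``.
    """
    a = np.asarray(start, dtype=float)
    b = np.asarray(end, dtype=float)
    rc = math.log1p(annual_rate)
    if rc == 0.0:
        out = rate_per_year * (b - a)
    else:
        out = rate_per_year * (np.exp(-rc * a) - np.exp(-rc * b)) / rc
    return out if (a.ndim or b.ndim) else float(out)


@dataclass(frozen=True)
class ModelResult:
    """Per-arm discounted totals for one model run."""

    arm: str
    discounted_cost: float
    discounted_qaly: float
    nmb: float


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison of intervention vs comparator.

    ``delta_cost`` is the cost saving (comparator minus intervention),
    ``delta_effect`` the QALY gain, per the reporting convention for a
    cost-saving intervention.  ``dominance`` is one of ``"dominant"``,
    ``"dominated"``, ``"icer"`` or ``"undefined"`` (identical arms); ``icer``
    is populated only in the ``"icer"`` case.
    """

    delta_cost: float
    delta_effect: float
    delta_nmb: float
    dominance: str
    icer: float | None = None


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * qaly - cost``."""
    return wtp * qaly - cost


def incremental(intervention: ModelResult, comparator: ModelResult) -> IncrementalResult:
    """Incremental cost-effectiveness of ``intervention`` against ``comparator``.

    Dominance follows the cost-effectiveness plane: cheaper and more
    effective is dominant; costlier and less effective is dominated;
    otherwise an ICER (incremental cost per QALY gained) is reported.
    """
    delta_cost = comparator.discounted_cost - intervention.discounted_cost
    delta_effect = intervention.discounted_qaly - comparator.discounted_qaly
    delta_nmb = intervention.nmb - comparator.nmb
    if delta_cost == 0.0 and delta_effect == 0.0:
        return IncrementalResult(0.0, 0.0, delta_nmb, "undefined")
    if delta_cost >= 0.0 and delta_effect >= 0.0:
        return IncrementalResult(delta_cost, delta_effect, delta_nmb, "dominant")
    if delta_cost <= 0.0 and delta_effect <= 0.0:
        return IncrementalResult(delta_cost, delta_effect, delta_nmb, "dominated")
    icer = -delta_cost / delta_effect
    return IncrementalResult(delta_cost, delta_effect, delta_nmb, "icer", icer=icer)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSADistributions:
    """Joint uncertainty distributions for the 14 model parameters.

    Each Weibull rate and shape is an independent normal centred on its
    baseline with its standard error (draws truncated to be positive by
    redrawing); each utility is uniform over its 95% CI (clamped to [0, 1]);
    each cost is uniform over baseline +/- ``cost_fraction``.  No covariance
    between parameters is modelled — only marginal uncertainties are
    available — which in particular ignores the negative correlation typical
    of jointly-fitted rate/shape pairs.
    """

    transitions: Mapping[str, WeibullParams]
    econ: EconParams
    utility_transplant_ci: tuple[float, float] = (0.74, 0.90)
    utility_dialysis_ci: tuple[float, float] = (0.62, 0.78)
    cost_fraction: float = 0.15

    def draw(self, rng: np.random.Generator) -> tuple[dict[str, WeibullParams], EconParams]:
        """One joint parameter draw."""

        def _positive_normal(mean: float, sd: float) -> float:
            if sd == 0.0:
                return mean
            x = rng.normal(mean, sd)
            while x <= 0.0:
                x = rng.normal(mean, sd)
            return x

        transitions = {
            name: replace(
                p,
                rate_lambda=_positive_normal(p.rate_lambda, p.se_lambda),
                shape_gamma=_positive_normal(p.shape_gamma, p.se_gamma),
            )
            for name, p in self.transitions.items()
        }

        def _uniform_ci(lo: float, hi: float) -> float:
            return float(np.clip(rng.uniform(lo, hi), 0.0, 1.0))

        def _uniform_cost(baseline: float) -> float:
            return rng.uniform(baseline * (1 - self.cost_fraction),
                               baseline * (1 + self.cost_fraction))

        econ = replace(
            self.econ,
            utility_transplant=_uniform_ci(*self.utility_transplant_ci),
            utility_dialysis=_uniform_ci(*self.utility_dialysis_ci),
            cost_transplant_year1=_uniform_cost(self.econ.cost_transplant_year1),
            cost_transplant_followup=_uniform_cost(self.econ.cost_transplant_followup),
            cost_dialysis=_uniform_cost(self.econ.cost_dialysis),
        )
        return transitions, econ


@dataclass(frozen=True)
class PSAResult:
    """Summary of a probabilistic sensitivity analysis.

    ``iterations`` holds one row per successful iteration with per-arm
    discounted cost/QALY/NMB and the incremental NMB; summary statistics are
    means, 2.5/97.5 percentiles and the fraction of iterations in which the
    transplant arm has the higher NMB.
    """

    iterations: pd.DataFrame
    n_failed: int

    def _col(self, col: str) -> np.ndarray:
        return self.iterations[col].to_numpy()

    @property
    def mean(self) -> pd.Series:
        return self.iterations.mean()

    def percentiles(self, q=(2.5, 97.5)) -> pd.DataFrame:
        return self.iterations.quantile([x / 100 for x in q])

    @property
    def prob_transplant_preferred(self) -> float:
        return float((self._col("nmb_transplant") > self._col("nmb_waitlist")).mean())


def run_psa(
    model: Callable[[str, Mapping[str, WeibullParams], EconParams], ModelResult],
    dists: PSADistributions,
    n_iter: int,
    seed: int,
    max_failure_fraction: float = 0.01,
) -> PSAResult:
    """Monte-Carlo PSA: redraw parameters, evaluate both arms, summarise NMB.

    ``model(arm, transitions, econ)`` evaluates one arm (``"transplant"`` or
    ``"waitlist"``) under one parameter draw and returns a
    :class:`ModelResult`.  A failing iteration is recorded and skipped; the
    run aborts if more than ``max_failure_fraction`` of iterations fail.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(n_iter):
        transitions, econ = dists.draw(rng)
        try:
            tx = model("transplant", transitions, econ)
            wl = model("waitlist", transitions, econ)
        except Exception:
            n_failed += 1
            if n_failed > max_failure_fraction * n_iter:
                raise RuntimeError(
                    f"PSA aborted: {n_failed}/{n_iter} iterations failed "
                    f"(> {max_failure_fraction:.0%})"
                )
            continue
        rows.append(
            {
                "cost_transplant": tx.discounted_cost,
                "qaly_transplant": tx.discounted_qaly,
                "nmb_transplant": tx.nmb,
                "cost_waitlist": wl.discounted_cost,
                "qaly_waitlist": wl.discounted_qaly,
                "nmb_waitlist": wl.nmb,
                "delta_nmb": tx.nmb - wl.nmb,
            }
        )
    return PSAResult(iterations=pd.DataFrame(rows), n_failed=n_failed)
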
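"""Default model parameters.

Weibull rate/shape estimates (with standard errors) for the four transitions,
fitted to Australian registry cohorts of KDPI > 74 transplant recipients,
dialysis patients and waitlisted patients; utilities with their 95% CIs; and
2020 AUD cost rates with +/- 15% uncertainty ranges.  These defaults define
the base case evaluated throughout the package.
"""

from __future__ import annotations

from .economics import EconParams, PSADistributions
from .survival import WeibullParams

__all__ = [
    "TRANSITIONS",
    "DEFAULT_ECON",
    "UTILITY_TRANSPLANT_CI",
    "UTILITY_DIALYSIS_CI",
    "COST_FRACTION",
    "default_transitions",
    "default_econ",
    "default_psa_distributions",
]

#: Rate-scale Weibull parameters per transition: S(t) = exp(-lambda t^gamma).
TRANSITIONS: dict[str, WeibullParams] = {
    "graft_failure": WeibullParams(0.0698, 0.3944, 0.0072, 0.0345),
    "death_post_transplant": WeibullParams(0.0502, 0.9305, 0.0059, 0.0572),
    "death_post_graft_failure": WeibullParams(0.0922, 1.1161, 0.0027, 0.0153),
    "death_waitlisted": WeibullParams(0.0315, 1.4346, 0.0039, 0.0654),
}

DEFAULT_ECON = EconParams()

UTILITY_TRANSPLANT_CI = (0.74, 0.90)
UTILITY_DIALYSIS_CI = (0.62, 0.78)
COST_FRACTION = 0.15


def default_transitions() -> dict[str, WeibullParams]:
    """A fresh copy of the default transition parameters."""
    return dict(TRANSITIONS)


def default_econ() -> EconParams:
    return DEFAULT_ECON


def default_psa_distributions() -> PSADistributions:
    return PSADistributions(
        transitions=default_transitions(),
        econ=DEFAULT_ECON,
        utility_transplant_ci=UTILITY_TRANSPLANT_CI,
        utility_dialysis_ci=UTILITY_DIALYSIS_CI,
        cost_fraction=COST_FRACTION,
    )
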
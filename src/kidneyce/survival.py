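"""Parametric survival models for decision-analytic modelling.

Fits right-censored time-to-event data with four parametric families
(exponential, Weibull, log-logistic, log-normal), selects among them by
information criteria, and converts a fitted Weibull into the two objects the
downstream engines need:

* per-cycle transition probabilities for a cohort Markov model, via the
  survivor-function ratio ``1 - S(t) / S(t - u)`` (the standard conversion of
  a parametric survivor function into time-dependent cycle probabilities);
* continuous event-time samplers for a discrete-event simulation, via
  inverse-transform sampling.

The Weibull survivor function is parameterized on the *rate* scale
throughout: ``S(t) = exp(-lambda * t**gamma)`` with rate ``lambda > 0`` and
shape ``gamma > 0``, time in years.  Fitting backends that use the scale
parameterization ``S(t) = exp(-(t / scale)**shape)`` are converted with
``lambda = scale**(-shape)`` and delta-method standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import (
    ExponentialFitter,
    LogLogisticFitter,
    LogNormalFitter,
    WeibullFitter,
)
from lifelines.exceptions import ConvergenceError as _LifelinesConvergenceError

__all__ = [
    "FAMILIES",
    "WeibullParams",
    "SurvivalDataset",
    "ParametricFit",
    "FittingError",
    "ConvergenceError",
    "fit_parametric",
    "fit_all_families",
    "select_best_fit",
    "fit_summary_table",
    "survival_at",
    "cycle_transition_probability",
    "sample_time_to_event",
]

FAMILIES = ("exponential", "weibull", "log-logistic", "log-normal")


class FittingError(ValueError):
    """Raised when a dataset cannot be fitted (e.g. no observed events)."""


class ConvergenceError(RuntimeError):
    """Raised when maximum-likelihood optimisation fails to converge.

    Carries the backend's last iterate, when available, in ``last_params``.
    """

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class WeibullParams:
    """Rate-scale Weibull parameters for one transition.

    ``S(t) = exp(-rate_lambda * t**shape_gamma)``; standard errors accompany
    the point estimates for probabilistic sensitivity analysis.
    """

    rate_lambda: float
    shape_gamma: float
    se_lambda: float = 0.0
    se_gamma: float = 0.0

    def __post_init__(self):
        if not (self.rate_lambda > 0 and math.isfinite(self.rate_lambda)):
            raise ValueError(f"rate_lambda must be positive, got {self.rate_lambda}")
        if not (self.shape_gamma > 0 and math.isfinite(self.shape_gamma)):
            raise ValueError(f"shape_gamma must be positive, got {self.shape_gamma}")
        if self.se_lambda < 0 or self.se_gamma < 0:
            raise ValueError("standard errors must be non-negative")


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored time-to-event records.

    ``times`` are strictly positive years; ``events`` flags observed events
    (``True``) versus right-censored records (``False``).
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=bool)
        if times.ndim != 1 or events.shape != times.shape:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if times.size == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("all times must be strictly positive and finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @classmethod
    def from_records(cls, records: Iterable[tuple[float, bool]]) -> "SurvivalDataset":
        recs = list(records)
        return cls(
            np.array([t for t, _ in recs], dtype=float),
            np.array([e for _, e in recs], dtype=bool),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "SurvivalDataset":
        """Read a ``time,event`` CSV (event coded 0/1)."""
        df = pd.read_csv(path)
        if not {"time", "event"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns 'time' and 'event'")
        return cls(df["time"].to_numpy(float), df["event"].to_numpy(int).astype(bool))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time": self.times, "event": self.events.astype(int)}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ParametricFit:
    """A fitted parametric survival model with information criteria.

    ``params`` is family-specific: a :class:`WeibullParams` for the
    exponential and Weibull families (the exponential is the ``gamma = 1``
    sub-family), a plain mapping of the backend's natural parameters for the
    log-logistic and log-normal families.
    """

    family: str
    params: object
    log_likelihood: float
    n_params: int
    n_obs: int
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "aic", -2.0 * self.log_likelihood + 2.0 * self.n_params)
        object.__setattr__(
            self, "bic", -2.0 * self.log_likelihood + self.n_params * math.log(self.n_obs)
        )


# ---------------------------------------------------------------------------
# Weibull survivor function, cycle probabilities, sampling
# ---------------------------------------------------------------------------

def survival_at(p: WeibullParams, t):
    """Survivor function ``S(t) = exp(-lambda * t**gamma)`` at time(s) ``t``.

    Vectorised over ``t``; raises on negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-p.rate_lambda * t_arr**p.shape_gamma)
    return out if t_arr.ndim else float(out)

def cycle_transition_probability(p: WeibullParams, cycle_end, cycle_length):
    """Per-cycle transition probability ``1 - S(t) / S(t - u)``.

    ``cycle_end`` is the time at the end of the cycle on the model clock and
    ``cycle_length`` the cycle width ``u``; both in years.  Equals
    ``1 - exp(lambda * ((t - u)**gamma - t**gamma))`` and lies in [0, 1].
    """
    t = np.asarray(cycle_end, dtype=float)
    u = np.asarray(cycle_length, dtype=float)
    if np.any(u <= 0):
        raise ValueError("cycle_length must be positive")
    if np.any(t < u):
        raise ValueError("cycle_end must be >= cycle_length")
    lam, gam = p.rate_lambda, p.shape_gamma
    out = 1.0 - np.exp(lam * ((t - u) ** gam - t**gam))
    return out if (t.ndim or u.ndim) else float(out)

def sample_time_to_event(p: WeibullParams, rng: np.random.Generator, size=None):
    """Draw Weibull event times by inverse-transform sampling.

    ``T = (-ln(U) / lambda)**(1/gamma)`` for ``U ~ Uniform(0, 1)``, so that
    ``P(T > t) = exp(-lambda * t**gamma)``.
    """
    u = rng.uniform(size=size)
    return inverse_survival(p, u)

def inverse_survival(p: WeibullParams, u):
    """Map uniform draw(s) ``u`` to event times: the quantile of ``1 - u``.

    ``inverse_survival(p, exp(-lambda)) == 1`` exactly; used by the samplers
    so that a forced uniform reproduces a forced event time.
    """
    u_arr = np.asarray(u, dtype=float)
    out = (-np.log(u_arr) / p.rate_lambda) ** (1.0 / p.shape_gamma)
    return out if u_arr.ndim else float(out)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

_FITTERS = {
    "exponential": ExponentialFitter,
    "weibull": WeibullFitter,
    "log-logistic": LogLogisticFitter,
    "log-normal": LogNormalFitter,
}


def _weibull_params_from_fitter(fitter: WeibullFitter) -> WeibullParams:
    # lifelines: S(t) = exp(-(t/lambda_)**rho_); convert to the rate scale.
    scale = float(fitter.lambda_)
    shape = float(fitter.rho_)
    rate = scale ** (-shape)
    cov = fitter.variance_matrix_.loc[["lambda_", "rho_"], ["lambda_", "rho_"]].to_numpy()
    # delta method for rate = scale**(-shape)
    grad = np.array([-shape * scale ** (-shape - 1.0), -rate * math.log(scale)])
    var_rate = float(grad @ cov @ grad)
    se_rate = math.sqrt(max(var_rate, 0.0))
    se_shape = math.sqrt(max(float(cov[1, 1]), 0.0))
    return WeibullParams(rate, shape, se_rate, se_shape)


def _exponential_params_from_fitter(fitter: ExponentialFitter) -> WeibullParams:
    # lifelines: S(t) = exp(-t/lambda_); rate = 1/lambda_, shape fixed at 1.
    scale = float(fitter.lambda_)
    rate = 1.0 / scale
    se_scale = math.sqrt(float(fitter.variance_matrix_.loc["lambda_", "lambda_"]))
    return WeibullParams(rate, 1.0, se_scale / scale**2, 0.0)


def fit_parametric(data: SurvivalDataset, family: str) -> ParametricFit:
    """Maximum-likelihood fit of one parametric family under right-censoring.

    Censored records contribute the survivor function ``S(t)`` to the
    likelihood, observed events the density ``f(t)``.  Standard errors come
    from the observed information matrix of the backend.

    Raises
    ------
    FittingError
        If the dataset contains no observed events.
    ConvergenceError
        If the optimiser fails; ``last_params`` holds the last iterate when
        the backend exposes one.
    """
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if data.n_events == 0:
        raise FittingError("cannot fit a survival model with no observed events")
    fitter = _FITTERS[family]()
    try:
        fitter.fit(data.times, event_observed=data.events.astype(int))
    except _LifelinesConvergenceError as exc:
        raise ConvergenceError(
            f"{family} fit failed to converge: {exc}",
            last_params=getattr(fitter, "params_", None),
        ) from exc

    n_params = len(fitter._fitted_parameter_names)
    if family == "exponential":
        params: object = _exponential_params_from_fitter(fitter)
        n_params = 1
    elif family == "weibull":
        params = _weibull_params_from_fitter(fitter)
    else:
        params = {
            name: float(getattr(fitter, name)) for name in fitter._fitted_parameter_names
        }
    return ParametricFit(
        family=family,
        params=params,
        log_likelihood=float(fitter.log_likelihood_),
        n_params=n_params,
        n_obs=len(data),
    )


def fit_all_families(data: SurvivalDataset) -> list[ParametricFit]:
    """Fit all four families to the same dataset."""
    return [fit_parametric(data, family) for family in FAMILIES]


def select_best_fit(fits: Sequence[ParametricFit]) -> ParametricFit:
    """Pick the fit with the lowest AIC; ties by lowest BIC, then parsimony.

    All fits must refer to the same dataset (checked via ``n_obs``).
    """
    if len(fits) == 0:
        raise ValueError("no fits to select from")
    sizes = {f.n_obs for f in fits}
    if len(sizes) > 1:
        raise ValueError(f"fits computed on datasets of different sizes: {sorted(sizes)}")
    return min(fits, key=lambda f: (f.aic, f.bic, f.n_params))


def fit_summary_table(datasets: Mapping[str, SurvivalDataset]) -> pd.DataFrame:
    """AIC/BIC comparison table: one row per dataset, family x {AIC, BIC} columns."""
    rows = {}
    for label, data in datasets.items():
        fits = fit_all_families(data)
        row = {}
        for f in fits:
            row[f"aic_{f.family}"] = f.aic
            row[f"bic_{f.family}"] = f.bic
        rows[label] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "transition"
    return out
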
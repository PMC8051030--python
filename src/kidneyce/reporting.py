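"""Study orchestration and reporting.

One configured call runs every model variant in the comparison — four
Markov configurations (two cycle lengths x two horizons), the
discrete-event simulation at both horizons, and the probabilistic
sensitivity analyses — and writes the comparison artifacts:

* ``table4.csv`` — per model/horizon/arm: base-case discounted cost, QALY,
  incremental cost saving and QALY gain, dominance classification, PSA mean
  NMB and incremental NMB, and each Markov quantity's % change from the DES
  value (computed on unrounded values);
* ``stabilization.csv`` + figure — DES NMB versus population size;
* ``event_proportions.csv`` + figure — per model: fraction experiencing each
  event within the horizon, with % difference from DES;
* ``densities.csv`` + figure — DES time-to-event samples and their means;
* ``manifest.json`` — seeds, configuration and package version, sufficient
  to reproduce every CSV bit-for-bit.

Monetary values in ``table4.csv`` are reported rounded to the nearest
AUD 1,000 (columns suffixed ``_rounded``) alongside full precision; all
derived quantities use full precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .defaults import (
    COST_FRACTION,
    UTILITY_DIALYSIS_CI,
    UTILITY_TRANSPLANT_CI,
    default_econ,
    default_transitions,
)
from .des import DESConfig, run_population, stabilization_curve, stable_population_size
from .economics import EconParams, PSADistributions, incremental, run_psa
from .markov import CohortTrace, CycleConfig, MarkovSpec, run_cohort
from .survival import WeibullParams

__all__ = ["StudyConfig", "run_study", "event_proportions", "load_config", "save_config"]


@dataclass(frozen=True)
class StudyConfig:
    """Full study configuration; defaults reproduce the six base-case runs.

    ``markov_runs`` pairs (cycle length, horizon) in years; ``des_horizons``
    lists the DES horizons.  PSA iteration counts are separate for the two
    engines because a DES iteration is far more expensive; the DES PSA also
    uses its own (usually reduced) population size per iteration.
    """

    econ: EconParams = field(default_factory=default_econ)
    transitions: Mapping[str, WeibullParams] = field(default_factory=default_transitions)
    markov_runs: tuple[tuple[float, float], ...] = ((1.0, 5.0), (0.5, 5.0), (1.0, 20.0), (0.5, 20.0))
    des_horizons: tuple[float, ...] = (5.0, 20.0)
    des_n_patients: int = 4000
    psa_iterations_markov: int = 5000
    psa_iterations_des: int = 500
    psa_des_n_patients: int = 1000
    stabilization_sizes: tuple[int, ...] = (250, 500, 1000, 2000, 3000, 4000, 6000, 8000)
    stabilization_horizon: float = 5.0
    seed: int = 20200415


def _seed_from(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31 - 1))


def event_proportions(
    markov_traces: Mapping[tuple[float, float], Mapping[str, CohortTrace]],
    des_results: Mapping[float, Mapping[str, "object"]],
) -> pd.DataFrame:
    """Per model/horizon/arm: cumulative event proportions, vs the DES value.

    For the DES the proportion is the fraction of simulated patients with
    the event before the horizon; for a Markov trace it is the cumulative
    inflow into the event (dead occupancy for death; cumulative entries into
    the post-graft-failure dialysis state for graft failure).
    """
    rows = []
    for horizon, by_arm in des_results.items():
        for arm, pop in by_arm.items():
            for event, prop in pop.event_proportions.items():
                rows.append(
                    {
                        "model": "des",
                        "cycle_length": np.nan,
                        "horizon": horizon,
                        "arm": arm,
                        "event": event,
                        "proportion": prop,
                    }
                )
    for (cycle, horizon), by_arm in markov_traces.items():
        for arm, trace in by_arm.items():
            events = {"death": trace.cumulative_incidence("death")}
            if arm == "transplant":
                events["graft_failure"] = trace.cumulative_incidence("graft_failure")
            for event, prop in events.items():
                rows.append(
                    {
                        "model": f"markov_{cycle:g}yr",
                        "cycle_length": cycle,
                        "horizon": horizon,
                        "arm": arm,
                        "event": event,
                        "proportion": prop,
                    }
                )
    df = pd.DataFrame(rows)
    des_ref = (
        df[df["model"] == "des"]
        .set_index(["horizon", "arm", "event"])["proportion"]
        .rename("des_proportion")
    )
    df = df.join(des_ref, on=["horizon", "arm", "event"])
    df["pct_diff_from_des"] = 100.0 * (df["proportion"] - df["des_proportion"]) / df["des_proportion"]
    df.loc[df["model"] == "des", "pct_diff_from_des"] = 0.0
    return df


def _markov_evaluator(cycle: float, horizon: float):
    def evaluate(arm, transitions, econ):
        spec = (
            MarkovSpec.transplant(transitions)
            if arm == "transplant"
            else MarkovSpec.waitlist(transitions)
        )
        result, _ = run_cohort(spec, CycleConfig(cycle, horizon), econ)
        return result

    return evaluate


def _des_evaluator(horizon: float, n_patients: int, seed_seq: np.random.SeedSequence):
    def evaluate(arm, transitions, econ):
        child = seed_seq.spawn(1)[0]  # spawn tracking gives a fresh substream per call
        cfg = DESConfig(
            n_patients=n_patients, horizon=horizon, seed=_seed_from(child)
        )
        return run_population(arm, transitions, econ, cfg).result

    return evaluate


def run_study(cfg: StudyConfig, outdir: str | Path, make_figures: bool = True) -> dict:
    """Run every configured engine and write the comparison artifacts.

    Returns a dict with the main tables (also written as CSV under
    ``outdir``).  Any engine failure propagates with the failing run in the
    exception message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    ss_des, ss_psa_markov, ss_psa_des, ss_stab = root.spawn(4)

    dists = PSADistributions(
        transitions=cfg.transitions,
        econ=cfg.econ,
        utility_transplant_ci=UTILITY_TRANSPLANT_CI,
        utility_dialysis_ci=UTILITY_DIALYSIS_CI,
        cost_fraction=COST_FRACTION,
    )

    # --- base cases ---------------------------------------------------------
    markov_results: dict[tuple[float, float], dict] = {}
    markov_traces: dict[tuple[float, float], dict] = {}
    for cycle, horizon in cfg.markov_runs:
        by_arm_res, by_arm_trace = {}, {}
        for arm in ("transplant", "waitlist"):
            try:
                spec = (
                    MarkovSpec.transplant(cfg.transitions)
                    if arm == "transplant"
                    else MarkovSpec.waitlist(cfg.transitions)
                )
                res, trace = run_cohort(spec, CycleConfig(cycle, horizon), cfg.econ)
            except Exception as exc:
                raise RuntimeError(
                    f"markov run failed (cycle={cycle}, horizon={horizon}, arm={arm})"
                ) from exc
            by_arm_res[arm], by_arm_trace[arm] = res, trace
        markov_results[(cycle, horizon)] = by_arm_res
        markov_traces[(cycle, horizon)] = by_arm_trace

    des_seeds = {h: _seed_from(s) for h, s in zip(cfg.des_horizons, ss_des.spawn(len(cfg.des_horizons)))}
    des_results: dict[float, dict] = {}
    for horizon in cfg.des_horizons:
        by_arm = {}
        for arm in ("transplant", "waitlist"):
            try:
                by_arm[arm] = run_population(
                    arm,
                    cfg.transitions,
                    cfg.econ,
                    DESConfig(cfg.des_n_patients, horizon, des_seeds[horizon]),
                )
            except Exception as exc:
                raise RuntimeError(
                    f"des run failed (horizon={horizon}, arm={arm})"
                ) from exc
        des_results[horizon] = by_arm

    # --- PSA ----------------------------------------------------------------
    psa_results: dict[str, dict] = {"markov": {}, "des": {}}
    markov_psa_seeds = ss_psa_markov.spawn(len(cfg.markov_runs))
    for (cycle, horizon), s in zip(cfg.markov_runs, markov_psa_seeds):
        psa_results["markov"][(cycle, horizon)] = run_psa(
            _markov_evaluator(cycle, horizon),
            dists,
            cfg.psa_iterations_markov,
            _seed_from(s),
        )
    des_psa_seeds = ss_psa_des.spawn(len(cfg.des_horizons))
    for horizon, s in zip(cfg.des_horizons, des_psa_seeds):
        psa_results["des"][horizon] = run_psa(
            _des_evaluator(horizon, cfg.psa_des_n_patients, s.spawn(1)[0]),
            dists,
            cfg.psa_iterations_des,
            _seed_from(s),
        )

    # --- Table 4 analogue ---------------------------------------------------
    rows = []
    for horizon in cfg.des_horizons:
        model_runs: list[tuple[str, dict, object]] = [
            (f"markov_{cycle:g}yr", markov_results[(cycle, horizon)], psa_results["markov"][(cycle, horizon)])
            for cycle, h in cfg.markov_runs
            if h == horizon
        ]
        model_runs.append(
            ("des", {a: p.result for a, p in des_results[horizon].items()}, psa_results["des"][horizon])
        )
        for model, by_arm, psa in model_runs:
            inc = incremental(by_arm["transplant"], by_arm["waitlist"])
            psa_mean = psa.mean
            for arm in ("transplant", "waitlist"):
                res = by_arm[arm]
                rows.append(
                    {
                        "horizon": horizon,
                        "model": model,
                        "arm": arm,
                        "cost": res.discounted_cost,
                        "qaly": res.discounted_qaly,
                        "nmb": res.nmb,
                        "delta_cost": inc.delta_cost if arm == "transplant" else np.nan,
                        "delta_effect": inc.delta_effect if arm == "transplant" else np.nan,
                        "dominance": inc.dominance if arm == "transplant" else "",
                        "psa_mean_nmb": psa_mean[f"nmb_{arm}"],
                        "psa_delta_nmb": psa_mean["delta_nmb"] if arm == "transplant" else np.nan,
                    }
                )
    table4 = pd.DataFrame(rows)
    des_ref = (
        table4[table4["model"] == "des"]
        .set_index(["horizon", "arm"])[["nmb", "psa_mean_nmb", "psa_delta_nmb"]]
        .rename(columns=lambda c: f"des_{c}")
    )
    table4 = table4.join(des_ref, on=["horizon", "arm"])
    for col in ("psa_mean_nmb", "psa_delta_nmb"):
        table4[f"pct_change_{col}_from_des"] = 100.0 * (
            table4[col] - table4[f"des_{col}"]
        ) / table4[f"des_{col}"].abs()
        table4.loc[table4["model"] == "des", f"pct_change_{col}_from_des"] = 0.0
    table4 = table4.drop(columns=[c for c in table4.columns if c.startswith("des_")])
    for col in ("cost", "delta_cost", "nmb", "psa_mean_nmb", "psa_delta_nmb"):
        table4[f"{col}_rounded"] = (table4[col] / 1000).round() * 1000

    # --- stabilization ------------------------------------------------------
    stab_seed = _seed_from(ss_stab)
    stab = stabilization_curve(
        "transplant",
        cfg.transitions,
        cfg.econ,
        cfg.stabilization_sizes,
        stab_seed,
        horizon=cfg.stabilization_horizon,
    )
    stab["stable_from_n"] = stable_population_size(stab)

    # --- event proportions and densities ------------------------------------
    props = event_proportions(markov_traces, des_results)
    density_rows = []
    for horizon, by_arm in des_results.items():
        for arm, pop in by_arm.items():
            cols = [c for c in pop.patients.columns if c.startswith("time_")]
            for col in cols:
                times = pop.patients[col].dropna()
                event = col.removeprefix("time_")
                density_rows.append(
                    pd.DataFrame(
                        {
                            "horizon": horizon,
                            "arm": arm,
                            "event": event,
                            "time": times.to_numpy(),
                        }
                    )
                )
    densities = pd.concat(density_rows, ignore_index=True)

    # --- write artifacts ----------------------------------------------------
    table4.to_csv(outdir / "table4.csv", index=False)
    stab.to_csv(outdir / "stabilization.csv", index=False)
    props.to_csv(outdir / "event_proportions.csv", index=False)
    densities.to_csv(outdir / "densities.csv", index=False)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "des_seeds": des_seeds,
        "stabilization_seed": stab_seed,
        "config": {
            "markov_runs": list(map(list, cfg.markov_runs)),
            "des_horizons": list(cfg.des_horizons),
            "des_n_patients": cfg.des_n_patients,
            "psa_iterations_markov": cfg.psa_iterations_markov,
            "psa_iterations_des": cfg.psa_iterations_des,
            "psa_des_n_patients": cfg.psa_des_n_patients,
            "econ": asdict(cfg.econ),
            "transitions": {k: asdict(v) for k, v in cfg.transitions.items()},
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    if make_figures:
        _make_figures(outdir, table4, stab, props, densities)

    return {
        "table4": table4,
        "stabilization": stab,
        "event_proportions": props,
        "densities": densities,
        "markov_traces": markov_traces,
        "des_results": des_results,
        "psa": psa_results,
    }


def _make_figures(outdir: Path, table4, stab, props, densities) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(stab["n_patients"], stab["nmb"], marker="o")
    ax.axvline(stab["stable_from_n"].iloc[0], color="red", linestyle="--")
    ax.set_xlabel("simulated patients")
    ax.set_ylabel("NMB (AUD)")
    ax.set_title("DES transplant-arm NMB stabilization")
    fig.tight_layout()
    fig.savefig(outdir / "stabilization.svg")
    plt.close(fig)

    fig, axes = plt.subplots(1, props["horizon"].nunique(), figsize=(10, 4), squeeze=False)
    for ax, (horizon, sub) in zip(axes.ravel(), props.groupby("horizon")):
        piv = sub.pivot_table(
            index=["arm", "event"], columns="model", values="proportion"
        )
        piv.plot.bar(ax=ax)
        ax.set_title(f"horizon {horizon:g} yr")
        ax.set_ylabel("proportion with event")
    fig.tight_layout()
    fig.savefig(outdir / "event_proportions.svg")
    plt.close(fig)

    groups = list(densities.groupby(["arm", "event"]))
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.5), squeeze=False)
    for ax, ((arm, event), sub) in zip(axes.ravel(), groups):
        for horizon, hsub in sub.groupby("horizon"):
            ax.hist(hsub["time"], bins=40, density=True, alpha=0.5, label=f"{horizon:g} yr")
            ax.axvline(hsub["time"].mean(), linestyle=":")
        ax.set_title(f"{arm}: time to {event}")
        ax.set_xlabel("years")
        ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "densities.svg")
    plt.close(fig)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def save_config(cfg: StudyConfig, path: str | Path) -> None:
    import yaml

    data = {
        "seed": cfg.seed,
        "econ": asdict(cfg.econ),
        "transitions": {k: asdict(v) for k, v in cfg.transitions.items()},
        "markov_runs": [list(r) for r in cfg.markov_runs],
        "des_horizons": list(cfg.des_horizons),
        "des_n_patients": cfg.des_n_patients,
        "psa_iterations_markov": cfg.psa_iterations_markov,
        "psa_iterations_des": cfg.psa_iterations_des,
        "psa_des_n_patients": cfg.psa_des_n_patients,
        "stabilization_sizes": list(cfg.stabilization_sizes),
        "stabilization_horizon": cfg.stabilization_horizon,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> StudyConfig:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    kwargs: dict = {}
    if "econ" in data:
        kwargs["econ"] = EconParams(**data["econ"])
    if "transitions" in data:
        kwargs["transitions"] = {
            k: WeibullParams(**v) for k, v in data["transitions"].items()
        }
    if "markov_runs" in data:
        kwargs["markov_runs"] = tuple(tuple(map(float, r)) for r in data["markov_runs"])
    if "des_horizons" in data:
        kwargs["des_horizons"] = tuple(map(float, data["des_horizons"]))
    if "stabilization_sizes" in data:
        kwargs["stabilization_sizes"] = tuple(map(int, data["stabilization_sizes"]))
    for key in (
        "seed",
        "des_n_patients",
        "psa_iterations_markov",
        "psa_iterations_des",
        "psa_des_n_patients",
        "stabilization_horizon",
    ):
        if key in data:
            kwargs[key] = data[key]
    return StudyConfig(**kwargs)
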
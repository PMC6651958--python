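"""Derived metrics, deaths-averted tables, back-cast checks and the pipeline.

The headline policy question is whether projected prevalence meets a 30%
relative reduction against the 2010 anchor:

    relative reduction (%) = 100 * (anchor - projected) / anchor
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .engine import ProjectionResult, StateArrays, project
from .errors import ConfigurationError
from .fixtures import (
    default_rate_tables,
    initial_prevalence_arrays,
    load_anchors,
    load_default_config,
)
from .mortality import MortalitySchedule, RelativeRiskTable
from .policies import scenario_from_config
from .rates import build_rate_schedule
from .synthetic import (
    SynthParams,
    entrants_from_population,
    generate_mortality_schedule,
    generate_population,
    generate_rr_table,
    population_age_profile,
)

logger = logging.getLogger(__name__)


def _as_percent(value: float, what: str) -> float:
    """Normalize a prevalence or target given as a proportion to percent."""
    if value <= 1.0:
        logger.info("%s given as proportion (%.4f); interpreting as %.2f%%", what, value, 100 * value)
        return 100.0 * value
    return float(value)


def relative_reduction(anchor: float, projected: float) -> float:
    """Percent reduction of ``projected`` relative to ``anchor``.

    Both arguments must share a convention (both percent or both
    proportions); the anchor must be positive.
    """
    if anchor <= 0:
        raise ConfigurationError(f"anchor prevalence must be positive, got {anchor}")
    return 100.0 * (anchor - projected) / anchor


def target_prevalence(anchor: float, reduction: float) -> float:
    """Prevalence implied by a relative-reduction target (reduction may be
    given as 0.30 or 30)."""
    frac = reduction / 100.0 if reduction > 1.0 else reduction
    return anchor * (1.0 - frac)


@dataclass(frozen=True)
class TargetCheck:
    """Outcome of one scenario against the relative-reduction target."""

    scenario: str
    anchor_prevalence: float  # percent
    projected_prevalence: float  # percent
    target_reduction: float  # percent
    achieved_reduction: float  # percent
    passed: bool


def check_target(
    anchor: float,
    projected: float,
    target: float = 0.30,
    scenario: str = "",
) -> TargetCheck:
    """Evaluate a projected prevalence against the reduction target.

    Percent and proportion conventions are both accepted and normalized
    once (a 0.385 anchor and a 38.5 anchor mean the same thing).
    """
    anchor_pct = _as_percent(anchor, "anchor prevalence")
    projected_pct = projected * 100.0 if anchor <= 1.0 and projected <= 1.0 else float(projected)
    target_pct = target * 100.0 if target <= 1.0 else float(target)
    achieved = relative_reduction(anchor_pct, projected_pct)
    return TargetCheck(
        scenario=scenario,
        anchor_prevalence=anchor_pct,
        projected_prevalence=projected_pct,
        target_reduction=target_pct,
        achieved_reduction=achieved,
        passed=achieved >= target_pct,
    )


@dataclass
class AvertedTable:
    """Deaths averted per scenario and year, with cumulative and percentage rows.

    ``yearly_*`` frames are indexed by year with one column per scenario
    (plus the baseline deaths column in the all-cause frame);
    ``reduction_pct`` is cumulative averted deaths as a percentage of
    cumulative baseline all-cause deaths.
    """

    yearly_all_cause: pd.DataFrame
    yearly_attributable: pd.DataFrame
    cumulative_all_cause: pd.Series
    cumulative_attributable: pd.Series
    reduction_pct_all_cause: pd.Series
    reduction_pct_attributable: pd.Series


def averted_table(baseline: ProjectionResult, scenarios: Mapping[str, ProjectionResult]) -> AvertedTable:
    """Tabulate deaths averted by each scenario relative to the baseline.

    Emits both conventions: averted all-cause deaths (baseline total deaths
    minus scenario total deaths) and averted smoking-attributable deaths.
    Cumulative cells are exact sums of the yearly cells.
    """
    years = baseline.death_years()
    for name, res in scenarios.items():
        if res.death_years() != years:
            raise ConfigurationError(f"scenario {name!r} horizon differs from baseline")

    all_cause = pd.DataFrame(index=pd.Index(years, name="year"))
    all_cause["baseline_deaths"] = [baseline.total_deaths(y) for y in years]
    attributable = pd.DataFrame(index=pd.Index(years, name="year"))
    attributable["baseline_attributable"] = [baseline.attributable.get(y, 0.0) for y in years]
    for name, res in scenarios.items():
        all_cause[name] = [baseline.total_deaths(y) - res.total_deaths(y) for y in years]
        attributable[name] = [
            baseline.attributable.get(y, 0.0) - res.attributable.get(y, 0.0) for y in years
        ]

    cum_all = all_cause.sum(axis=0)
    cum_attr = attributable.sum(axis=0)
    base_cum = cum_all["baseline_deaths"]
    scen_cols = list(scenarios)
    red_all = 100.0 * cum_all[scen_cols] / base_cum
    red_attr = 100.0 * cum_attr[scen_cols] / base_cum
    return AvertedTable(
        yearly_all_cause=all_cause,
        yearly_attributable=attributable,
        cumulative_all_cause=cum_all,
        cumulative_attributable=cum_attr,
        reduction_pct_all_cause=red_all,
        reduction_pct_attributable=red_attr,
    )


def backcast_validate(
    predicted: ProjectionResult | Mapping[int, float],
    observed: Mapping[int, float],
) -> pd.DataFrame:
    """Compare model-predicted prevalence (%) with observed survey values.

    Returns a frame (year, predicted, observed, difference) for the survey
    years; purely descriptive, no pass/fail threshold.
    """
    if isinstance(predicted, ProjectionResult):
        pred = {y: predicted.prevalence(y) for y in predicted.years}
    else:
        pred = {int(y): float(v) for y, v in predicted.items()}
    rows = []
    for year in sorted(observed):
        y = int(year)
        if y not in pred:
            raise ConfigurationError(f"observed year {y} outside the projection horizon")
        rows.append({
            "year": y,
            "predicted": pred[y],
            "observed": float(observed[year]),
            "difference": pred[y] - float(observed[year]),
        })
    return pd.DataFrame(rows)


def run_projections(config: dict | None = None, seed: int = 0) -> dict[str, ProjectionResult]:
    """Build the synthetic world from the config and project every scenario.

    Returns {scenario name: ProjectionResult}, baseline included. The base
    year is initialized by applying the packaged survey state prevalences to
    the synthetic base-year population.
    """
    cfg = dict(load_default_config())
    if config:
        cfg.update(config)
    if cfg.get("relapse_rate") is None:
        raise ConfigurationError("config must set relapse_rate explicitly")
    sex = cfg.get("sex", "male")
    base_year = int(cfg["base_year"])
    horizon_end = int(cfg["horizon_end"])

    synth_cfg = dict(cfg.get("synthetic") or {})
    params = SynthParams(base_year=base_year, horizon_end=horizon_end, seed=seed, **synth_cfg)
    population = generate_population(params)
    mortality = MortalitySchedule(generate_mortality_schedule(params))
    rr = RelativeRiskTable(generate_rr_table(params))
    entrants = entrants_from_population(population, sex)

    cess, init = default_rate_tables(sex)
    schedule = build_rate_schedule(cess, init, relapse=float(cfg["relapse_rate"]), sex=sex)

    pop0 = population_age_profile(population, sex, base_year)
    p_n, p_c, p_f = initial_prevalence_arrays(sex)
    initial = StateArrays.from_prevalence(pop0, p_n, p_c, p_f)

    results: dict[str, ProjectionResult] = {}
    for block in cfg["scenarios"]:
        scen = scenario_from_config(block)
        name = block.get("name", scen.label)
        results[name] = project(
            initial, schedule, mortality, rr, entrants, scen,
            base_year=base_year, horizon_end=horizon_end, sex=sex,
        )
    return results


def run_pipeline(config: dict | None = None, seed: int = 0, out_dir: str | Path = "out") -> dict:
    """Full run: synthetic inputs, all scenarios, tables, target checks.

    Writes trajectory.csv, attributable.csv, averted_*.csv,
    target_checks.json and manifest.json under ``out_dir``; returns the
    manifest.
    """
    cfg = dict(load_default_config())
    if config:
        cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results = run_projections(cfg, seed=seed)
    if "baseline" not in results:
        raise ConfigurationError("config must include a baseline (identity) scenario")
    baseline = results["baseline"]
    others = {k: v for k, v in results.items() if k != "baseline"}

    trajectory = pd.concat(
        [res.states_df().assign(scenario=name) for name, res in results.items()],
        ignore_index=True,
    )
    trajectory.to_csv(out / "trajectory.csv", index=False)
    deaths = pd.concat([res.deaths_df() for res in results.values()], ignore_index=True)
    deaths.to_csv(out / "attributable.csv", index=False)

    table = averted_table(baseline, others)
    table.yearly_all_cause.to_csv(out / "averted_all_cause.csv")
    table.yearly_attributable.to_csv(out / "averted_attributable.csv")

    anchors = load_anchors()
    anchor = float(cfg.get("anchor_prevalence_2010", anchors["anchor_prevalence_2010_male"]))
    target = float(cfg.get("target_relative_reduction", anchors["target_relative_reduction"]))
    horizon_end = int(cfg["horizon_end"])
    checks = [
        asdict(check_target(anchor, res.prevalence(horizon_end), target, scenario=name))
        for name, res in results.items()
    ]
    (out / "target_checks.json").write_text(json.dumps(checks, indent=2))

    manifest = {
        "package": "smokesim",
        "version": __version__,
        "seed": seed,
        "sex": cfg.get("sex", "male"),
        "base_year": cfg["base_year"],
        "horizon_end": horizon_end,
        "relapse_rate": cfg["relapse_rate"],
        "anchor_prevalence_2010": anchor,
        "target_relative_reduction": target,
        "scenarios": [b.get("name") for b in cfg["scenarios"]],
        "clipped_strata": {name: res.clipped_strata for name, res in results.items()},
        "prevalence_2025": {name: res.prevalence(horizon_end) for name, res in results.items()},
        "cumulative_attributable": {name: res.cumulative_attributable() for name, res in results.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def plot_prevalence(results: Mapping[str, ProjectionResult], path: str | Path) -> None:
    """Trajectory figure: prevalence (%) per scenario over the horizon."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, res in results.items():
        series = res.prevalence_series()
        ax.plot(series.index, series.values, marker="o", markersize=3, label=name)
    ax.set_xlabel("year")
    ax.set_ylabel("current-smoker prevalence (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "relative_reduction",
    "target_prevalence",
    "TargetCheck",
    "check_target",
    "AvertedTable",
    "averted_table",
    "backcast_validate",
    "run_projections",
    "run_pipeline",
    "plot_prevalence",
]
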
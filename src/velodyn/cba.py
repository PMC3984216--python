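"""Cumulative scenario-vs-baseline accounting, monetization and
benefit-cost ratios.

Sign convention throughout: cumulative outcomes are scenario minus
baseline, integrated (trapezoid) over the policy window, so a negative
entry is a saving. Monetization preserves signs; the net benefit flips
the sign so that savings come out positive. No discounting and no
inflation are applied (a discount-rate option exists but defaults to 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .config import ScenarioConfig, UnitValues

__all__ = ["CumulativeOutcomes", "accumulate", "monetize", "benefit_cost_ratio",
           "summary_table", "BCR_UNDEFINED"]

BCR_UNDEFINED = float("nan")

# trajectory column -> cumulative outcome field
_OUTCOME_COLUMNS = {
    "fatal": "cyclist_fatalities",
    "serious": "cyclist_serious_injuries",
    "car_occupant_fatalities": "car_occupant_fatalities",
    "air_deaths": "air_deaths",
    "air_hospitalizations": "air_hospitalizations",
    "air_copd": "air_copd",
    "air_cancers": "air_cancers",
    "air_rad": "restricted_activity_days",
    "deaths_averted_pa": "pa_deaths_averted",
    "lv_vkt": "lv_vkt_km",
    "ghg_total_t": "ghg_tonnes",
    "fuel_cost_nzd": "fuel_cost_nzd",
}


@dataclass
class CumulativeOutcomes:
    """Cumulative scenario-minus-baseline counts over the policy window."""

    cyclist_fatalities: float = 0.0
    cyclist_serious_injuries: float = 0.0
    car_occupant_fatalities: float = 0.0
    air_deaths: float = 0.0
    air_hospitalizations: float = 0.0
    air_copd: float = 0.0
    air_cancers: float = 0.0
    restricted_activity_days: float = 0.0
    pa_deaths_averted: float = 0.0
    lv_vkt_km: float = 0.0
    ghg_tonnes: float = 0.0
    fuel_cost_nzd: float = 0.0
    infrastructure_cost_m: float = 0.0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def accumulate(scenario_traj: pd.DataFrame, baseline_traj: pd.DataFrame,
               start_year: float = 2012.0, end_year: float | None = None,
               infrastructure_cost_m: float = 0.0) -> CumulativeOutcomes:
    """Time-integrated scenario-minus-baseline differences (trapezoid rule)
    over [start_year, end_year]."""
    if len(scenario_traj) != len(baseline_traj) or not np.allclose(
            scenario_traj["year"].to_numpy(), baseline_traj["year"].to_numpy()):
        raise ValueError("scenario and baseline trajectories use different time grids")
    years = scenario_traj["year"].to_numpy()
    if end_year is None:
        end_year = float(years[-1])
    mask = (years >= start_year - 1e-9) & (years <= end_year + 1e-9)
    if mask.sum() < 2:
        raise ValueError("accumulation window contains fewer than two grid points")
    t = years[mask]
    out = CumulativeOutcomes(infrastructure_cost_m=infrastructure_cost_m)
    for column, attr in _OUTCOME_COLUMNS.items():
        diff = scenario_traj.loc[mask, column].to_numpy() - baseline_traj.loc[mask, column].to_numpy()
        setattr(out, attr, float(np.trapezoid(diff, t)))
    return out


def monetize(outcomes: CumulativeOutcomes, uv: UnitValues) -> dict:
    """Per-category $NZ million, preserving the savings-negative sign.

    PA deaths averted are a benefit, so they enter with a negative sign
    (a saving) when positive, valued at the fatal-injury unit value.
    """
    for f in fields(uv):
        if getattr(uv, f.name) is None:
            raise ValueError(f"missing unit value: {f.name}")
    return {
        "cyclist_fatalities": outcomes.cyclist_fatalities * uv.fatal_injury_m,
        "cyclist_serious_injuries": outcomes.cyclist_serious_injuries * uv.serious_injury_m,
        "car_occupant_fatalities": outcomes.car_occupant_fatalities * uv.car_occupant_fatality_m,
        "air_deaths": outcomes.air_deaths * uv.air_death_m,
        "air_hospitalizations": outcomes.air_hospitalizations * uv.hospitalization_m,
        "air_copd": outcomes.air_copd * uv.copd_m,
        "air_cancers": outcomes.air_cancers * uv.cancer_m,
        "restricted_activity_days": outcomes.restricted_activity_days
        * uv.restricted_activity_day_nzd / 1e6,
        "pa_deaths_averted": -outcomes.pa_deaths_averted * uv.pa_death_m,
        "ghg": outcomes.ghg_tonnes * uv.ghg_per_tonne_nzd / 1e6,
        "fuel": outcomes.fuel_cost_nzd / 1e6,
    }


def benefit_cost_ratio(monetized: dict, infra_cost_m: float) -> dict:
    """Net benefit (savings positive, $NZ million) and benefit-cost ratio."""
    net_benefit = -sum(monetized.values())
    if infra_cost_m <= 0:
        bcr = 0.0 if net_benefit == 0 else BCR_UNDEFINED
    else:
        bcr = net_benefit / infra_cost_m
    return {"net_benefit_m": net_benefit, "bcr": bcr}


def summary_table(results: dict) -> pd.DataFrame:
    """Build a summary table: rows = outcome categories (counts and
    monetized $NZm), columns = scenarios.

    ``results`` maps scenario name -> (CumulativeOutcomes, monetized dict,
    bcr dict).
    """
    rows = {}
    for name, (outcomes, monetized, bcr) in results.items():
        col = {}
        for key, value in outcomes.as_dict().items():
            col[f"count:{key}"] = value
        for key, value in monetized.items():
            col[f"nzd_m:{key}"] = value
        col["net_benefit_m"] = bcr["net_benefit_m"]
        col["bcr"] = bcr["bcr"]
        rows[name] = col
    return pd.DataFrame(rows)
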
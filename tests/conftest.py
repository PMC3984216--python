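"""Shared fixtures: configurations and session-scoped scenario runs."""

from __future__ import annotations

import pytest

from velodyn.cba import accumulate, benefit_cost_ratio, monetize
from velodyn.config import SCENARIOS, ScenarioConfig, preset
from velodyn.model import CommuteModel


@pytest.fixture()
def cfg() -> ScenarioConfig:
    return ScenarioConfig().validate()


@pytest.fixture(scope="session")
def scenario_trajectories() -> dict:
    """Deterministic full runs of all five shipped scenarios."""
    return {name: CommuteModel(preset(name)).run() for name in SCENARIOS}


@pytest.fixture(scope="session")
def baseline_trajectory(scenario_trajectories):
    return scenario_trajectories["baseline"]


@pytest.fixture(scope="session")
def scenario_cba(scenario_trajectories):
    """Cumulative outcomes, monetized values and BCR per active scenario."""
    base = scenario_trajectories["baseline"]
    out = {}
    for name in SCENARIOS:
        if name == "baseline":
            continue
        cfg = preset(name)
        cost = cfg.policy.infrastructure_cost_m[name]
        outcomes = accumulate(scenario_trajectories[name], base,
                              start_year=cfg.policy.rollout_start_year,
                              infrastructure_cost_m=cost)
        monetized = monetize(outcomes, cfg.costs)
        out[name] = (outcomes, monetized, benefit_cost_ratio(monetized, cost))
    return out


def at_year(traj, year: float, column: str) -> float:
    row = traj.loc[(traj["year"] - year).abs().idxmin()]
    return float(row[column])
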
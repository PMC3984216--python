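"""Sensitivity analysis: best/worst-case runs, seeded Monte Carlo over
uncertain parameters, and classification of effects by a hierarchy of
uncertainty (shape change > order of magnitude > within an order).

Best/worst-case runs move the policy-effect parameters to the lowest and
highest confidence limits of the underlying studies simultaneously; the
Monte Carlo set additionally samples the most uncertain structural inputs
(physical-activity relative risk and lead time, safety-in-numbers
threshold and exponent) from triangular distributions with mode at the
point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .engine import ConfigurationError
from .model import CommuteModel

__all__ = ["ParameterDistribution", "SensitivityReport", "default_distributions",
           "set_by_path", "get_by_path", "best_worst_runs", "monte_carlo",
           "classify_effect", "hierarchy_report"]


@dataclass(frozen=True)
class ParameterDistribution:
    """Triangular uncertainty description for one config parameter.

    ``favorable`` names the bound ("low"/"high") that favours cycling
    uptake and safety; best-case runs move every parameter to its
    favorable bound, worst-case to the other.
    """

    path: str
    low: float
    high: float
    mode: float
    favorable: str = "high"
    shape: str = "triangular"

    def __post_init__(self) -> None:
        if not self.low <= self.mode <= self.high:
            raise ConfigurationError(
                f"{self.path}: require low <= mode <= high, got "
                f"({self.low}, {self.mode}, {self.high})")
        if self.favorable not in ("low", "high"):
            raise ConfigurationError(f"{self.path}: favorable must be 'low' or 'high'")

    def sample(self, rng: np.random.Generator) -> float:
        if self.low == self.high:
            return self.mode
        return float(rng.triangular(self.low, self.mode, self.high))


def get_by_path(cfg: ScenarioConfig, path: str):
    obj = cfg
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def set_by_path(cfg: ScenarioConfig, path: str, value) -> None:
    parts = path.split(".")
    obj = cfg
    for part in parts[:-1]:
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        raise ConfigurationError(f"unknown parameter path: {path}")
    setattr(obj, parts[-1], value)


def default_distributions(cfg: ScenarioConfig, include_structural: bool = True
                          ) -> list[ParameterDistribution]:
    """Shipped uncertainty set.

    Policy-effect bounds reflect the spread of the underlying intervention
    studies (relative half-widths of ~25% on perception increments;
    collision RRs spanning protective to null/harmful findings). The
    structural set covers the inputs the projections are most sensitive
    to.
    """
    pol = cfg.policy
    dists = [
        ParameterDistribution("policy.on_road_lanes.collision_rr", 0.80, 1.05,
                              pol.on_road_lanes.collision_rr, favorable="low"),
        ParameterDistribution("policy.on_road_lanes.safety_per_10pct",
                              0.75 * pol.on_road_lanes.safety_per_10pct,
                              1.25 * pol.on_road_lanes.safety_per_10pct,
                              pol.on_road_lanes.safety_per_10pct),
        ParameterDistribution("policy.on_road_lanes.commute_per_10pct",
                              0.75 * pol.on_road_lanes.commute_per_10pct,
                              1.25 * pol.on_road_lanes.commute_per_10pct,
                              pol.on_road_lanes.commute_per_10pct),
        ParameterDistribution("policy.off_road_paths.safety_per_10pct",
                              0.75 * pol.off_road_paths.safety_per_10pct,
                              1.25 * pol.off_road_paths.safety_per_10pct,
                              pol.off_road_paths.safety_per_10pct),
        ParameterDistribution("policy.off_road_paths.commute_per_doubling",
                              0.75 * pol.off_road_paths.commute_per_doubling,
                              1.25 * pol.off_road_paths.commute_per_doubling,
                              pol.off_road_paths.commute_per_doubling),
        ParameterDistribution("policy.asbl.rr_midblock", 0.58, 0.90,
                              pol.asbl.rr_midblock, favorable="low"),
        ParameterDistribution("policy.asbl.rr_intersection", 0.65, 1.10,
                              pol.asbl.rr_intersection, favorable="low"),
        ParameterDistribution("policy.asbl.safety_per_10pct",
                              0.75 * pol.asbl.safety_per_10pct,
                              1.25 * pol.asbl.safety_per_10pct,
                              pol.asbl.safety_per_10pct),
        ParameterDistribution("policy.asbl.commute_per_10pct",
                              0.75 * pol.asbl.commute_per_10pct,
                              1.25 * pol.asbl.commute_per_10pct,
                              pol.asbl.commute_per_10pct),
        ParameterDistribution("policy.ser.max_speed_reduction_kmh", 10.0,
                              pol.ser.max_speed_reduction_kmh,
                              pol.ser.max_speed_reduction_kmh),
        ParameterDistribution("injury.speed_collision_base", 0.30, 0.55,
                              cfg.injury.speed_collision_base, favorable="low"),
        ParameterDistribution("policy.ser.max_volume_reduction", 0.15,
                              pol.ser.max_volume_reduction, pol.ser.max_volume_reduction),
        ParameterDistribution("policy.ser.max_safety_boost", 0.05, 0.15,
                              pol.ser.max_safety_boost),
        ParameterDistribution("policy.ser.max_commute_boost", 0.05, 0.15,
                              pol.ser.max_commute_boost),
        ParameterDistribution("policy.ser.max_lv_convenience_reduction", 0.20, 0.40,
                              pol.ser.max_lv_convenience_reduction),
    ]
    if include_structural:
        pa = cfg.physical_activity
        sin = cfg.injury.sin
        dists += [
            ParameterDistribution("physical_activity.relative_risk", 0.60, 0.88,
                                  pa.relative_risk, favorable="low"),
            ParameterDistribution("physical_activity.lead_time_years", 1.0, 5.0,
                                  pa.lead_time_years, favorable="low"),
            ParameterDistribution("injury.sin.threshold_share", 0.015, 0.040,
                                  sin.threshold_share, favorable="low"),
            ParameterDistribution("injury.sin.exponent", -0.60, -0.15,
                                  sin.exponent, favorable="low"),
        ]
    return dists


def _configured(cfg: ScenarioConfig, assignments: dict) -> ScenarioConfig:
    varied = cfg.copy()
    for path, value in assignments.items():
        set_by_path(varied, path, value)
    return varied.validate()


def best_worst_runs(cfg: ScenarioConfig, dists: list[ParameterDistribution]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic runs with every parameter simultaneously at its
    favorable (best) / unfavorable (worst) bound."""
    best = {d.path: (d.low if d.favorable == "low" else d.high) for d in dists}
    worst = {d.path: (d.high if d.favorable == "low" else d.low) for d in dists}
    best_traj = CommuteModel(_configured(cfg, best)).run()
    worst_traj = CommuteModel(_configured(cfg, worst)).run()
    return best_traj, worst_traj


def monte_carlo(cfg: ScenarioConfig, dists: list[ParameterDistribution], n: int,
                seed: int) -> list[pd.DataFrame]:
    """Ensemble of ``n`` runs with independent triangular draws per run.

    Reproducible: the same seed yields identical ensembles.
    """
    if n < 1:
        raise ConfigurationError(f"monte_carlo requires n >= 1, got {n}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        assignments = {d.path: d.sample(rng) for d in dists}
        out.append(CommuteModel(_configured(cfg, assignments)).run())
    return out


def ensemble_quantiles(ensemble: list[pd.DataFrame], column: str,
                       quantiles=(0.0, 0.05, 0.5, 0.95, 1.0)) -> pd.DataFrame:
    """Per-year quantiles of one output across an ensemble."""
    values = np.stack([traj[column].to_numpy() for traj in ensemble])
    data = {f"q{q:g}": np.quantile(values, q, axis=0) for q in quantiles}
    return pd.DataFrame({"year": ensemble[0]["year"].to_numpy(), **data})


# ---------------------------------------------------------------------------
# hierarchy-of-uncertainty classification


def _trend_class(traj: pd.DataFrame, column: str, window_years: float = 10.0,
                 flat_band: float = 0.01) -> str:
    """Sign of the least-squares trend over the terminal window:
    'growing', 'declining' or 'flat' (relative slope within +-1%/yr)."""
    years = traj["year"].to_numpy()
    mask = years >= years[-1] - window_years + 1e-9
    t = years[mask]
    y = traj.loc[mask, column].to_numpy()
    slope = np.polyfit(t, y, 1)[0]
    scale = max(abs(float(np.mean(y))), 1e-12)
    rel = slope / scale
    if abs(rel) <= flat_band:
        return "flat"
    return "growing" if rel > 0 else "declining"


def classify_effect(reference: pd.DataFrame, varied: pd.DataFrame, output: str) -> str:
    """Classify a parameter variation's effect on one output.

    ``shape_change`` if the terminal-window trend class or the overall
    direction of change over the run differs; else ``order_of_magnitude``
    if the final values differ by a factor of 10 or more; else
    ``within_order``.
    """
    if len(reference) != len(varied) or not np.allclose(
            reference["year"].to_numpy(), varied["year"].to_numpy()):
        raise ValueError("reference and varied trajectories use different grids")
    if _trend_class(reference, output) != _trend_class(varied, output):
        return "shape_change"

    def overall(traj):
        y = traj[output].to_numpy()
        delta = y[-1] - y[0]
        scale = max(abs(float(np.mean(y))), 1e-12)
        span = traj["year"].iloc[-1] - traj["year"].iloc[0]
        rel = delta / (scale * span)
        if abs(rel) <= 0.01:
            return "flat"
        return "growing" if rel > 0 else "declining"

    if overall(reference) != overall(varied):
        return "shape_change"
    ref_final = float(reference[output].iloc[-1])
    var_final = float(varied[output].iloc[-1])
    small = min(abs(ref_final), abs(var_final))
    big = max(abs(ref_final), abs(var_final))
    if big >= 10.0 * small and big > 0:
        return "order_of_magnitude"
    return "within_order"


@dataclass
class SensitivityReport:
    """One-at-a-time classification of parameter effects on outputs."""

    seed: int
    classifications: dict = field(default_factory=dict)  # (path, output) -> class

    def to_frame(self) -> pd.DataFrame:
        rows = [{"parameter": p, "output": o, "classification": c}
                for (p, o), c in sorted(self.classifications.items())]
        return pd.DataFrame(rows)


def hierarchy_report(cfg: ScenarioConfig, dists: list[ParameterDistribution],
                     outputs: list[str], seed: int = 0) -> SensitivityReport:
    """Vary each parameter one at a time to each bound and classify the
    strongest resulting effect on each output (deterministic given runs)."""
    reference = CommuteModel(cfg.copy()).run()
    rank = {"within_order": 0, "order_of_magnitude": 1, "shape_change": 2}
    report = SensitivityReport(seed=seed)
    for d in dists:
        for bound in (d.low, d.high):
            varied = CommuteModel(_configured(cfg, {d.path: bound})).run()
            for output in outputs:
                cls = classify_effect(reference, varied, output)
                key = (d.path, output)
                if key not in report.classifications or rank[cls] > rank[report.classifications[key]]:
                    report.classifications[key] = cls
    return report
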
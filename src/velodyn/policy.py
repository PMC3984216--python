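"""Policy scenarios: rollout curves and translation of infrastructure
effects into the multipliers consumed by the demand and injury sectors.

Five scenarios are supported:

* ``baseline``  — business as usual, no cycling investment;
* ``rcn``       — regional cycle network: painted on-road lanes on 46% of
                  arterials, off-road shared paths growing from 10 to
                  25 km per 100,000 population, a negligible quantity of
                  shared bus/bicycle lanes; complete by 2040;
* ``asbl``      — one-way physically segregated lanes on every arterial,
                  with intersection treatments; complete by 2050;
* ``ser``       — "self-explaining" low-speed redesign of local streets;
                  complete by 2050;
* ``asbl_ser``  — the composition of ``asbl`` and ``ser``.

All rollouts follow an S-shaped implementation curve beginning in 2012.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import PolicyConfig, ScenarioConfig
from .engine import ConfigurationError, RolloutCurve, s_curve

__all__ = ["PolicyEffects", "rollout_curve_for", "rollout_fraction",
           "network_collision_rr", "apply_policy_effects"]


@dataclass
class PolicyEffects:
    """Region-wide multipliers at one rollout fraction p.

    Identity values (no policy) are 1.0 multipliers and 0.0 deltas.
    """

    bike_commute_mult: float = 1.0     # perception of bicycle commuting
    bike_safety_mult: float = 1.0      # multiplier on perceived-safety fraction
    lv_convenience_mult: float = 1.0   # perception of light-vehicle convenience
    collision_rr: dict = field(default_factory=lambda: {"local": 1.0, "arterial": 1.0})
    local_speed_delta_kmh: float = 0.0  # reduction in mean local-road speed
    local_volume_mult: float = 1.0      # local-road vehicle volume
    cycling_local_share: float = 0.50   # fraction of cyclist distance on local roads
    infrastructure_cost_m: float = 0.0


def rollout_curve_for(pol: PolicyConfig) -> RolloutCurve | None:
    if pol.scenario == "baseline":
        return None
    completion = pol.rcn_completion_year if pol.scenario == "rcn" else pol.other_completion_year
    return RolloutCurve(start_year=pol.rollout_start_year, completion_year=completion)


def rollout_fraction(t: float, pol: PolicyConfig) -> float:
    """Fraction of the scenario's programme implemented at year ``t``."""
    curve = rollout_curve_for(pol)
    if curve is None:
        return 0.0
    if t < curve.start_year:
        return 0.0
    return s_curve(t, curve)


def network_collision_rr(p: float, coverage: float, rr_midblock: float,
                         rr_intersection: float | None = None,
                         midblock_share: float = 0.5) -> float:
    """Region-wide collision relative risk for one road class.

    The treated fraction of the class network is ``p * coverage``; treated
    segments carry the component's effective RR (midblock/intersection
    weighted where both are given), untreated segments carry RR 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"rollout fraction must be in [0, 1], got {p}")
    if rr_intersection is None:
        rr_eff = rr_midblock
    else:
        rr_eff = midblock_share * rr_midblock + (1.0 - midblock_share) * rr_intersection
    return 1.0 - p * coverage * (1.0 - rr_eff)


def _perception_increment(per_10pct: float, coverage: float, p: float) -> float:
    """Multiplier 1 + increment/10% x (treated network fraction)."""
    return 1.0 + per_10pct * 10.0 * p * coverage


def apply_policy_effects(p: float, cfg: ScenarioConfig) -> PolicyEffects:
    """Translate rollout fraction ``p`` into region-wide effect multipliers.

    Effects from distinct infrastructure components compose
    multiplicatively; the combined ``asbl_ser`` scenario is exactly the
    composition of the ``asbl`` and ``ser`` effects at every ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"rollout fraction must be in [0, 1], got {p}")
    pol = cfg.policy
    scenario = pol.scenario
    eff = PolicyEffects(cycling_local_share=cfg.injury.local_cycling_share,
                        infrastructure_cost_m=pol.infrastructure_cost_m.get(scenario, 0.0))
    if scenario == "baseline" or p == 0.0:
        if scenario == "baseline":
            eff.infrastructure_cost_m = 0.0
        return eff

    if scenario == "rcn":
        onr, offr = pol.on_road_lanes, pol.off_road_paths
        eff.collision_rr["arterial"] *= network_collision_rr(p, onr.coverage, onr.collision_rr)
        # off-road paths and bus lanes carry RR 1.0 by default: no collision term
        eff.bike_safety_mult *= _perception_increment(onr.safety_per_10pct, onr.coverage, p)
        eff.bike_safety_mult *= _perception_increment(
            offr.safety_per_10pct, offr.network_equivalent_coverage, p)
        eff.bike_commute_mult *= _perception_increment(onr.commute_per_10pct, onr.coverage, p)
        # off-road paths: "x% increase by doubling km per 100,000 population"
        km = offr.km_per_100k_start + p * (offr.km_per_100k_full - offr.km_per_100k_start)
        doublings = math.log2(km / offr.km_per_100k_start)
        eff.bike_commute_mult *= 1.0 + offr.commute_per_doubling * doublings

    if scenario in ("asbl", "asbl_ser"):
        a = pol.asbl
        eff.collision_rr["arterial"] *= network_collision_rr(
            p, a.coverage, a.rr_midblock, a.rr_intersection, pol.midblock_share)
        eff.bike_safety_mult *= _perception_increment(a.safety_per_10pct, a.coverage, p)
        eff.bike_commute_mult *= _perception_increment(a.commute_per_10pct, a.coverage, p)

    if scenario in ("ser", "asbl_ser"):
        s = pol.ser
        eff.local_speed_delta_kmh = s.max_speed_reduction_kmh * p
        eff.local_volume_mult = 1.0 - s.max_volume_reduction * p
        base_local = cfg.injury.local_cycling_share
        eff.cycling_local_share = base_local + (s.local_share_full - base_local) * p
        eff.bike_safety_mult *= 1.0 + s.max_safety_boost * p
        eff.bike_commute_mult *= 1.0 + s.max_commute_boost * p
        eff.lv_convenience_mult *= 1.0 - s.max_lv_convenience_reduction * p

    return eff
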
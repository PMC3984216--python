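"""The coupled commuter-cycling simulation.

Wires the sector models together into one deterministic stock-flow system
and integrates it over the configured grid:

* demand: commuter growth, perceptions (with 1-year preference delay),
  relative-utility mode shares, light-vehicle kilometres;
* injury: collisions, severity, safety-in-numbers, and the
  perceived-safety feedback closing the dominant balancing loop
  (more cycling -> more injuries -> lower perceived safety -> less
  cycling) together with the policy-driven reinforcing loops;
* environment: air-pollution burden, CO2eq, fuel costs;
* physical activity: mortality savings behind a 2-year lead time;
* policy: S-shaped rollout of scenario effects from 2012.

The result of :meth:`CommuteModel.run` is a tidy year-indexed DataFrame
with one row per Euler step (dt = 0.25 yr by default).
"""

from __future__ import annotations

import math

from . import demand, env_health, injury, phys_activity, policy
from .config import MODES, ScenarioConfig
from .engine import LookupFunction, TimeGrid, integrate

__all__ = ["CommuteModel", "run_scenario_trajectory"]


class CommuteModel:
    """Deterministic simulation of one scenario under one configuration."""

    def __init__(self, cfg: ScenarioConfig):
        cfg.validate()
        self.cfg = cfg
        self.grid = TimeGrid(cfg.grid.start_year, cfg.grid.end_year, cfg.grid.dt)
        self.severity = injury.SeverityModel(cfg.injury)
        self.safety_curve = LookupFunction(tuple(map(tuple, cfg.perception.safety_curve_knots)))

        t0 = self.grid.start_year
        self.commuters0 = demand.project_commuters(t0, cfg.demographics, t0)
        self.cyclists0 = cfg.perception.base_shares["bicycle"] * self.commuters0
        base_shares = dict(cfg.perception.base_shares)
        self.lv_vkt0 = demand.annual_lv_vkt(base_shares, self.commuters0, cfg.trip)
        self.pop0 = cfg.demographics.regional_population_1991

        # GHG anchor calibration against the baseline run's closed-form
        # VKT at the anchor year (baseline shares; the baseline share drift
        # over 16 years is negligible at anchor precision).
        env = cfg.environment
        anchor_year = env.ghg_anchor_year
        commuters_a = demand.project_commuters(anchor_year, cfg.demographics, t0)
        vkt_a = demand.annual_lv_vkt(base_shares, commuters_a, cfg.trip)
        pop_a = demand.regional_population(anchor_year, cfg.demographics, t0)
        scale = env_health.calibrate_co2eq_scale(env, vkt_a, pop_a, start_year=t0)
        self.fleet = env_health.FleetModel(env, start_year=t0, co2eq_scale=scale)

    # ------------------------------------------------------------------
    def initial_state(self) -> dict:
        cfg = self.cfg
        state = {f"perc_smooth_{m}": 1.0 for m in MODES}
        state["pa_lagged_cyclists"] = self.cyclists0
        # evaluate the injury chain once at baseline conditions so the
        # perception feedback starts from self-consistent counts
        aux = self._auxiliaries(self.grid.start_year, state,
                               prev_fatal=cfg.injury.fatal_count_1991
                               * cfg.injury.collision_rate_scale * cfg.injury.fatal_severity_scale,
                               prev_serious=cfg.injury.serious_adjusted_count_1991
                               * cfg.injury.collision_rate_scale)
        state.update(aux)
        return state

    # ------------------------------------------------------------------
    def _policy_at(self, t: float):
        p = policy.rollout_fraction(t, self.cfg.policy)
        return p, policy.apply_policy_effects(p, self.cfg)

    def _exogenous_pulse(self, t: float) -> float:
        pulse = self.cfg.perception.exogenous_bike_pulse
        if pulse and pulse[0] <= t < pulse[1]:
            return float(pulse[2])
        return 1.0

    def _auxiliaries(self, t: float, state: dict, prev_fatal: float | None = None,
                     prev_serious: float | None = None) -> dict:
        """Everything computable algebraically from the stocks at time t."""
        cfg = self.cfg
        t0 = self.grid.start_year
        p, eff = self._policy_at(t)

        commuters = demand.project_commuters(t, cfg.demographics, t0)
        fatal_prev = state.get("fatal", prev_fatal)
        serious_prev = state.get("serious", prev_serious)

        s_base = injury.perceived_safety_from_injuries(fatal_prev, serious_prev, self.safety_curve)
        s_eff = min(1.0, s_base * eff.bike_safety_mult)
        injury_safety_mult = (
            s_eff / cfg.perception.reference_perceived_safe
        ) ** cfg.perception.safety_elasticity

        utilities = demand.utilities_from_perceptions(
            {m: state[f"perc_smooth_{m}"] for m in MODES}, cfg.perception)
        shares = demand.mode_shares_from_perceptions(
            utilities, cfg.perception.base_shares, cfg.trip)
        cyclists = shares["bicycle"] * commuters
        lv_vkt = demand.annual_lv_vkt(shares, commuters, cfg.trip)

        # vehicle volumes: commuter VKT plus exogenous background traffic
        background = math.exp(cfg.injury.background_traffic_growth * (t - t0))
        volume_ratio = {
            "local": (lv_vkt / self.lv_vkt0) * background * eff.local_volume_mult,
            "arterial": (lv_vkt / self.lv_vkt0) * background,
        }
        sinm = injury.sin_multiplier(shares["bicycle"], cfg.injury.sin)
        speed_mult = {
            "local": injury.speed_reduction_multiplier(
                eff.local_speed_delta_kmh, cfg.injury.speed_collision_base),
            "arterial": 1.0,
        }
        class_share = {"local": eff.cycling_local_share,
                       "arterial": 1.0 - eff.cycling_local_share}
        collisions = injury.annual_collisions(
            cyclists, self.cyclists0, volume_ratio, class_share, cfg.injury,
            eff.collision_rr, speed_mult, sinm)
        outcome = injury.severity_split(collisions, cfg.injury.mean_speed_kmh, self.severity)
        rate = injury.injury_rate_per_1000(outcome, cyclists)

        pop = demand.regional_population(t, cfg.demographics, t0)
        burden = env_health.air_pollution_burden(t, lv_vkt, self.lv_vkt0, self.fleet,
                                                 pop_scale=pop / self.pop0)
        ghg = env_health.ghg_co2eq(t, lv_vkt, self.fleet, pop)
        fuel_cost = lv_vkt * self.fleet.fuel_l_per_km(t) * self.fleet.fuel_price(t)
        car_fatal = lv_vkt * cfg.injury.car_occupant_fatal_per_billion_km / 1e9

        averted = phys_activity.deaths_averted(
            t, state["pa_lagged_cyclists"] - self.cyclists0, cfg.physical_activity, t0)

        return {
            "rollout_fraction": p,
            "commuters": commuters,
            **{f"share_{m}": shares[m] for m in MODES},
            "cyclists": cyclists,
            "lv_vkt": lv_vkt,
            "perceived_safe": s_eff,
            "injury_safety_mult": injury_safety_mult,
            "collisions_local": collisions["local"],
            "collisions_arterial": collisions["arterial"],
            "fatal": outcome.fatal,
            "serious": outcome.serious,
            "injury_rate_per_1000": rate,
            "sin_multiplier": sinm,
            "air_deaths": burden["deaths"],
            "air_hospitalizations": burden["hospitalizations"],
            "air_copd": burden["copd"],
            "air_cancers": burden["cancers"],
            "air_rad": burden["restricted_activity_days"],
            "ghg_total_t": ghg["total_t"],
            "ghg_per_capita_t": ghg["per_capita_t"],
            "fuel_cost_nzd": fuel_cost,
            "car_occupant_fatalities": car_fatal,
            "deaths_averted_pa": averted,
        }

    # ------------------------------------------------------------------
    def step(self, t: float, state: dict, dt: float) -> dict:
        cfg = self.cfg
        _, eff = self._policy_at(t)

        # perception feedback uses the recorded injury counts at time t
        s_base = injury.perceived_safety_from_injuries(
            state["fatal"], state["serious"], self.safety_curve)
        s_eff = min(1.0, s_base * eff.bike_safety_mult)
        injury_safety_mult = (
            s_eff / cfg.perception.reference_perceived_safe
        ) ** cfg.perception.safety_elasticity

        policy_mults = {
            "light_vehicle": eff.lv_convenience_mult,
            "bicycle": eff.bike_commute_mult * self._exogenous_pulse(t),
            "walk": 1.0,
            "public_transport": 1.0,
        }
        perc = demand.Perceptions(
            raw={m: 1.0 for m in MODES},
            smoothed={m: state[f"perc_smooth_{m}"] for m in MODES})
        perc = demand.update_perceptions(perc, policy_mults, injury_safety_mult,
                                         cfg.perception.preference_delay_years, dt)

        new_state = dict(state)
        for m in MODES:
            new_state[f"perc_smooth_{m}"] = perc.smoothed[m]

        # 2-year first-order lead time on the cyclist count
        tau = cfg.physical_activity.lead_time_years
        new_state["pa_lagged_cyclists"] += (state["cyclists"] - state["pa_lagged_cyclists"]) * dt / tau

        new_state.update(self._auxiliaries(t + dt, new_state))
        return new_state

    # ------------------------------------------------------------------
    def run(self):
        """Integrate the model over the configured grid.

        Deterministic: identical configurations produce bit-identical
        trajectories.
        """
        return integrate(self.step, self.grid, self.initial_state())


def run_scenario_trajectory(cfg: ScenarioConfig):
    """Convenience wrapper: build and run a model for ``cfg``."""
    return CommuteModel(cfg).run()
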
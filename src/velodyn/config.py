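"""Scenario configuration: every model parameter, with defaults and validation.

The default values parameterize the business-as-usual ("baseline") run for a
car-dominated city of ~1.5M people with 400,000 commuters in 1991. Policy
effect sizes carry the published point estimates for each infrastructure
component; locally calibrated constants (collision rates, perception curves,
fleet trends, mortality strata) are declared calibration inputs and documented
in docs/methods.md.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field, is_dataclass

import yaml

from .engine import ConfigurationError

MODES = ("light_vehicle", "bicycle", "walk", "public_transport")
ROAD_CLASSES = ("local", "arterial")
SCENARIOS = ("baseline", "rcn", "asbl", "ser", "asbl_ser")


@dataclass
class GridConfig:
    start_year: float = 1991.0
    end_year: float = 2051.0
    dt: float = 0.25


@dataclass
class Demographics:
    """Commuting and regional population."""

    baseline_commuters: float = 400_000.0
    growth_total: float = 0.40  # fractional growth over the growth horizon
    growth_horizon_years: float = 60.0  # 1991-2051, independent of run length
    # Carried as a labelled constant exactly as stated in the source material;
    # it does not enter the commuter projection, which is pinned by
    # baseline_commuters and growth_total.
    noncommuting_working_fraction: float = 0.85
    regional_population_1991: float = 1_050_000.0
    regional_growth_total: float = 0.40


@dataclass
class TripConfig:
    median_lv_commute_km: float = 10.0
    lv_occupancy: float = 1.25
    annual_commute_trips: float = 400.0
    cyclable_fraction: float = 0.50  # trips <= 6 km
    walkable_fraction: float = 0.27  # trips <= 2 km


@dataclass
class PerceptionConfig:
    """Mode attractiveness structure: delays, elasticities and the
    injury-count -> perceived-safety relationship."""

    base_shares: dict = field(
        default_factory=lambda: {
            "light_vehicle": 0.85,
            "bicycle": 0.02,
            "walk": 0.055,
            "public_transport": 0.075,
        }
    )
    preference_delay_years: float = 1.0
    # Perception -> utility elasticity per mode (power transform applied when
    # building the relative-utility weights; calibrated).
    utility_elasticity: dict = field(
        default_factory=lambda: {
            "light_vehicle": 2.0,
            "bicycle": 4.0,
            "walk": 1.0,
            "public_transport": 1.0,
        }
    )
    # Fraction of the population considering cycling "always or mostly" safe,
    # as a (lookup) function of annual media-reported cyclist deaths.
    # Calibrated so that baseline-era counts map to 0.19.
    safety_curve_knots: list = field(
        default_factory=lambda: [
            [0.0, 0.30],
            [0.5, 0.234],
            [1.0, 0.211],
            [2.0, 0.190],
            [4.0, 0.171],
            [8.0, 0.154],
            [16.0, 0.139],
            [32.0, 0.125],
            [48.0, 0.120],
            [400.0, 0.120],
        ]
    )
    reference_perceived_safe: float = 0.19
    # Elasticity of bicycle attractiveness w.r.t. the perceived-safety ratio.
    safety_elasticity: float = 1.0
    # Optional exogenous perception pulse for structural testing
    # [start_year, end_year, multiplier] or None.
    exogenous_bike_pulse: list | None = None


@dataclass
class SafetyInNumbersConfig:
    threshold_share: float = 0.025
    exponent: float = -0.3  # half of the classic -0.6 per-cyclist risk power
    enabled: bool = True
    # Alternative structure for hypothesis testing: the pure no-threshold
    # power function on per-cyclist risk.
    pure_jacobsen: bool = False
    jacobsen_exponent: float = -0.6
    jacobsen_reference_share: float = 0.02
    # Alternative reading of "half the effect": halve the risk *reduction*
    # rather than the exponent.
    half_risk_reduction_variant: bool = False


@dataclass
class InjuryConfig:
    """Cyclist fatal/serious injury model: collisions, severity, feedback."""

    # Baseline (1991) fraction of cyclist distance ridden on local roads.
    local_cycling_share: float = 0.50
    local_vehicle_share: float = 0.50
    mean_speed_kmh: dict = field(default_factory=lambda: {"local": 45.0, "arterial": 55.0})
    # Baseline annual cyclist-car collisions per road class (1991 calibration).
    baseline_collisions: dict = field(default_factory=lambda: {"local": 110.0, "arterial": 110.0})
    # Power of (vehicle volume / baseline volume) in the collision model.
    volume_exponent: dict = field(default_factory=lambda: {"local": 0.5, "arterial": 1.0})
    underreporting_multiplier: float = 2.0  # serious injuries, reported -> true
    # Exogenous growth of non-commuting traffic sharing the network (per yr).
    background_traffic_growth: float = 0.007
    # 1991 calibration anchors for counts (severity scales are solved so the
    # model reproduces these exactly at the initial state).
    fatal_count_1991: float = 2.0
    serious_adjusted_count_1991: float = 32.0
    # Free multipliers on top of the calibrated structure (the parameters
    # recovered by synthetic-history fitting).
    collision_rate_scale: float = 1.0
    fatal_severity_scale: float = 1.0
    # Composite collision+severity multiplier per 10 km/h of speed reduction.
    speed_collision_base: float = 0.4
    # Conditional severity lookups: mean speed (km/h) -> probability.
    fatal_curve_knots: list = field(
        default_factory=lambda: [
            [10.0, 0.0001],
            [30.0, 0.0007],
            [40.0, 0.0018],
            [50.0, 0.0045],
            [60.0, 0.010],
            [80.0, 0.030],
        ]
    )
    serious_curve_knots: list = field(
        default_factory=lambda: [
            [10.0, 0.010],
            [30.0, 0.045],
            [40.0, 0.075],
            [50.0, 0.115],
            [60.0, 0.160],
            [80.0, 0.250],
        ]
    )
    car_occupant_fatal_per_billion_km: float = 17.0
    sin: SafetyInNumbersConfig = field(default_factory=SafetyInNumbersConfig)


@dataclass
class EnvConfig:
    """Fleet emission/fuel trends, burden-of-disease baseline, GWPs."""

    # Effective CO2eq-relevant emission factors at 1991 (g per commuter-VKT);
    # scaled jointly to the per-capita anchor below at model build time.
    ef_1991_g_per_km: dict = field(
        default_factory=lambda: {"co2": 3000.0, "co": 20.0, "ch4": 0.30, "n2o": 0.03}
    )
    # Business-as-usual technology improvement half-lives (years).
    ef_half_life_years: dict = field(
        default_factory=lambda: {"co2": 40.0, "co": 20.0, "ch4": 40.0, "n2o": 40.0}
    )
    gwp: dict = field(default_factory=lambda: {"co2": 1.0, "ch4": 25.0, "n2o": 298.0, "co": 1.9})
    # Baseline-run calibration anchor: commuting-fleet CO2eq per regional
    # capita in the anchor year (metric tons). None disables rescaling.
    ghg_anchor_year: float = 2007.0
    ghg_anchor_tonnes_per_capita: float | None = 3.1
    # PM10-proxy fleet emission index (1.0 at 1991) half-life.
    pm10_half_life_years: float = 15.0
    # Annual counts attributable to commuting at 1991.
    bod_baseline_1991: dict = field(
        default_factory=lambda: {
            "deaths": 30.0,
            "hospitalizations": 20.0,
            "copd": 30.0,
            "cancers": 5.0,
            "restricted_activity_days": 45_000.0,
        }
    )
    fuel_l_per_km_1991: float = 0.090
    fuel_efficiency_half_life_years: float = 80.0
    fuel_price_knots: dict = field(
        default_factory=lambda: {
            "petrol": [[1991.0, 1.00], [2012.0, 2.10], [2051.0, 3.50]],
            "diesel": [[1991.0, 0.70], [2012.0, 1.50], [2051.0, 2.60]],
        }
    )
    fuel_mix: dict = field(default_factory=lambda: {"petrol": 0.85, "diesel": 0.15})


@dataclass
class PhysActivityConfig:
    relative_risk: float = 0.72
    lead_time_years: float = 2.0
    dose_scaling: float = 1.0
    secular_decline_rate: float = 0.008  # per year, exponential
    # Working-age commuting population strata: share of commuters and
    # baseline (1991) all-cause mortality rate per person-year.
    strata: list = field(
        default_factory=lambda: [
            {"name": "15-34", "share": 0.40, "rate_1991": 0.0009},
            {"name": "35-54", "share": 0.37, "rate_1991": 0.0027},
            {"name": "55-69", "share": 0.23, "rate_1991": 0.0140},
        ]
    )


@dataclass
class OnRoadLanes:
    coverage: float = 0.46  # fraction of arterial network treated at full rollout
    collision_rr: float = 0.9
    safety_per_10pct: float = 0.04
    commute_per_10pct: float = 0.03


@dataclass
class OffRoadPaths:
    km_per_100k_start: float = 10.0
    km_per_100k_full: float = 25.0
    collision_rr: float = 1.0
    safety_per_10pct: float = 0.05
    network_equivalent_coverage: float = 0.15
    commute_per_doubling: float = 0.02


@dataclass
class BusLanes:
    coverage: float = 0.0004
    collision_rr: float = 1.0


@dataclass
class AsblComponent:
    coverage: float = 1.0  # whole arterial network by completion
    rr_midblock: float = 0.72
    rr_intersection: float = 0.80
    safety_per_10pct: float = 0.06
    commute_per_10pct: float = 0.04


@dataclass
class SerEffects:
    max_speed_reduction_kmh: float = 15.0
    max_volume_reduction: float = 0.25
    local_share_full: float = 0.70
    max_safety_boost: float = 0.10
    max_commute_boost: float = 0.10
    max_lv_convenience_reduction: float = 0.30


@dataclass
class PolicyConfig:
    scenario: str = "baseline"
    rollout_start_year: float = 2012.0
    rcn_completion_year: float = 2040.0
    other_completion_year: float = 2050.0
    midblock_share: float = 0.5
    on_road_lanes: OnRoadLanes = field(default_factory=OnRoadLanes)
    off_road_paths: OffRoadPaths = field(default_factory=OffRoadPaths)
    bus_lanes: BusLanes = field(default_factory=BusLanes)
    asbl: AsblComponent = field(default_factory=AsblComponent)
    ser: SerEffects = field(default_factory=SerEffects)
    infrastructure_cost_m: dict = field(
        default_factory=lambda: {
            "baseline": 0.0,
            "rcn": 45.0,
            "asbl": 250.0,
            "ser": 380.0,
            "asbl_ser": 630.0,
        }
    )


@dataclass
class UnitValues:
    """Monetization constants, $NZ million per event unless noted.

    No discounting and no inflation are applied anywhere; the discount
    rate exists as an option but defaults to zero.
    """

    fatal_injury_m: float = 3.1
    serious_injury_m: float = 0.325
    car_occupant_fatality_m: float = 3.1
    air_death_m: float = 0.75
    hospitalization_m: float = 0.003
    copd_m: float = 0.075
    cancer_m: float = 0.75
    restricted_activity_day_nzd: float = 98.0
    ghg_per_tonne_nzd: float = 40.0
    pa_death_m: float = 3.1
    discount_rate: float = 0.0


@dataclass
class SensitivityConfig:
    n_runs: int = 1000
    # Relative half-width applied to policy perception increments for the
    # best/worst-case bounds (study confidence limits).
    perception_bound_rel: float = 0.25


@dataclass
class ScenarioConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    demographics: Demographics = field(default_factory=Demographics)
    trip: TripConfig = field(default_factory=TripConfig)
    perception: PerceptionConfig = field(default_factory=PerceptionConfig)
    injury: InjuryConfig = field(default_factory=InjuryConfig)
    environment: EnvConfig = field(default_factory=EnvConfig)
    physical_activity: PhysActivityConfig = field(default_factory=PhysActivityConfig)
    policy: PolicyConfig = field(default_factory=PolicyConfig)
    costs: UnitValues = field(default_factory=UnitValues)
    sensitivity: SensitivityConfig = field(default_factory=SensitivityConfig)

    def copy(self) -> "ScenarioConfig":
        return copy.deepcopy(self)

    def validate(self) -> "ScenarioConfig":
        _validate(self)
        return self


# ---------------------------------------------------------------------------
# validation


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ConfigurationError(message)


def _validate(cfg: ScenarioConfig) -> None:
    g = cfg.grid
    _require(g.start_year < g.end_year, f"grid.start_year must precede end_year")
    _require(g.dt > 0, f"grid.dt must be > 0, got {g.dt}")

    d = cfg.demographics
    _require(d.baseline_commuters > 0, "demographics.baseline_commuters must be > 0")
    _require(d.growth_total > -1, "demographics.growth_total must exceed -1")
    _require(d.regional_population_1991 > 0, "demographics.regional_population_1991 must be > 0")

    t = cfg.trip
    for name in ("median_lv_commute_km", "lv_occupancy", "annual_commute_trips"):
        _require(getattr(t, name) > 0, f"trip.{name} must be > 0")
    for name in ("cyclable_fraction", "walkable_fraction"):
        _require(0 < getattr(t, name) < 1, f"trip.{name} must be in (0, 1)")

    p = cfg.perception
    _require(set(p.base_shares) == set(MODES), f"perception.base_shares must have keys {MODES}")
    _require(all(0 <= v <= 1 for v in p.base_shares.values()), "base shares must be in [0, 1]")
    _require(abs(sum(p.base_shares.values()) - 1.0) < 1e-9, "perception.base_shares must sum to 1")
    _require(p.preference_delay_years > 0, "perception.preference_delay_years must be > 0")
    _require(all(v > 0 for v in p.utility_elasticity.values()), "utility elasticities must be > 0")
    _require(0 < p.reference_perceived_safe <= 1, "perception.reference_perceived_safe in (0, 1]")

    inj = cfg.injury
    _require(0 <= inj.local_cycling_share <= 1, "injury.local_cycling_share must be in [0, 1]")
    _require(inj.underreporting_multiplier >= 1, "injury.underreporting_multiplier must be >= 1")
    _require(all(v >= 0 for v in inj.baseline_collisions.values()), "collision rates must be >= 0")
    _require(inj.collision_rate_scale > 0, "injury.collision_rate_scale must be > 0")
    _require(inj.fatal_severity_scale > 0, "injury.fatal_severity_scale must be > 0")
    _require(0 < inj.speed_collision_base < 1, "injury.speed_collision_base must be in (0, 1)")
    sin = inj.sin
    _require(sin.threshold_share > 0, "injury.sin.threshold_share must be > 0")
    _require(sin.exponent <= 0, "injury.sin.exponent must be <= 0")
    _require(sin.jacobsen_reference_share > 0, "injury.sin.jacobsen_reference_share must be > 0")

    env = cfg.environment
    _require(all(v >= 0 for v in env.ef_1991_g_per_km.values()), "emission factors must be >= 0")
    _require(all(v > 0 for v in env.ef_half_life_years.values()), "EF half-lives must be > 0")
    _require(env.fuel_l_per_km_1991 > 0, "environment.fuel_l_per_km_1991 must be > 0")
    _require(abs(sum(env.fuel_mix.values()) - 1.0) < 1e-9, "environment.fuel_mix must sum to 1")
    _require(all(v >= 0 for v in env.bod_baseline_1991.values()), "BoD baselines must be >= 0")

    pa = cfg.physical_activity
    _require(0 < pa.relative_risk <= 1, "physical_activity.relative_risk must be in (0, 1]")
    _require(pa.lead_time_years > 0, "physical_activity.lead_time_years must be > 0")
    _require(pa.secular_decline_rate >= 0, "physical_activity.secular_decline_rate must be >= 0")
    _require(abs(sum(s["share"] for s in pa.strata) - 1.0) < 1e-9, "strata shares must sum to 1")
    _require(all(0 < s["rate_1991"] < 1 for s in pa.strata), "strata rates must be in (0, 1)")

    pol = cfg.policy
    _require(pol.scenario in SCENARIOS, f"policy.scenario must be one of {SCENARIOS}, got {pol.scenario!r}")
    _require(pol.rcn_completion_year > pol.rollout_start_year, "RCN completion must follow rollout start")
    _require(pol.other_completion_year > pol.rollout_start_year, "completion must follow rollout start")
    _require(0 <= pol.midblock_share <= 1, "policy.midblock_share must be in [0, 1]")
    for comp in (pol.on_road_lanes, pol.asbl):
        for attr in dataclasses.fields(comp):
            v = getattr(comp, attr.name)
            _require(v >= 0, f"policy component field {attr.name} must be >= 0")
    _require(0 < pol.asbl.rr_midblock <= 1.5, "asbl.rr_midblock must be in (0, 1.5]")
    _require(0 < pol.asbl.rr_intersection <= 1.5, "asbl.rr_intersection must be in (0, 1.5]")
    _require(pol.ser.local_share_full >= cfg.injury.local_cycling_share,
             "SER local_share_full cannot be below the baseline local cycling share")

    uv = cfg.costs
    for f_ in dataclasses.fields(uv):
        if f_.name == "discount_rate":
            continue
        _require(getattr(uv, f_.name) > 0, f"costs.{f_.name} must be > 0")

    _require(cfg.sensitivity.n_runs >= 1, "sensitivity.n_runs must be >= 1")


# ---------------------------------------------------------------------------
# loading


def _merge_into(obj, data: dict, path: str = "") -> None:
    """Recursively merge a plain dict into a dataclass tree.

    Unknown keys are rejected with the full dotted path so config typos
    surface immediately.
    """
    field_names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in field_names:
            raise ConfigurationError(f"unknown config key: {where}")
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, dict):
            _merge_into(current, value, where)
        elif isinstance(current, dict) and isinstance(value, dict):
            merged = dict(current)
            merged.update(value)
            setattr(obj, key, merged)
        else:
            setattr(obj, key, value)


def config_from_dict(data: dict | None) -> ScenarioConfig:
    cfg = ScenarioConfig()
    if data:
        if not isinstance(data, dict):
            raise ConfigurationError("config root must be a mapping")
        _merge_into(cfg, data)
    return cfg.validate()


def load_config(path) -> ScenarioConfig:
    """Load a YAML scenario config; absent keys take defaults, unknown keys
    are rejected. An empty file yields the fully-defaulted baseline."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def preset_path(scenario: str):
    """Path to the shipped YAML preset for one of the five scenarios."""
    from importlib import resources

    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    return resources.files("velodyn") / "presets" / f"{scenario}.yaml"


def preset(scenario: str) -> ScenarioConfig:
    """Built-in configuration for one of the five shipped scenarios."""
    return load_config(preset_path(scenario))
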
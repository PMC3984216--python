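"""Commuter population growth and the relative-utility mode-share model.

Commuter numbers grow exponentially so that the 60-year total matches the
configured +40%. Mode shares follow a relative-utility structure: each
mode's share is proportional to its baseline share weighted by an
attractiveness index, with the bicycle and walking shares capped by the
fractions of commute trips within cycling (<= 6 km) and walking (<= 2 km)
range. Stated-preference changes reach revealed mode share through a
first-order delay of one year on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import MODES, Demographics, PerceptionConfig, TripConfig
from .engine import ConfigurationError, DelayState, delay_step

__all__ = ["Perceptions", "project_commuters", "regional_population",
           "update_perceptions", "utilities_from_perceptions",
           "mode_shares_from_perceptions", "annual_lv_vkt"]


def project_commuters(t: float, demo: Demographics, start_year: float = 1991.0) -> float:
    """Commuting population at year ``t``: constant-rate exponential growth
    pinned to the configured total growth over the growth horizon."""
    span = demo.growth_horizon_years
    return demo.baseline_commuters * (1.0 + demo.growth_total) ** ((t - start_year) / span)


def regional_population(t: float, demo: Demographics, start_year: float = 1991.0) -> float:
    span = demo.growth_horizon_years
    return demo.regional_population_1991 * (1.0 + demo.regional_growth_total) ** (
        (t - start_year) / span)


@dataclass
class Perceptions:
    """Per-mode attractiveness indices (1.0 at the 1991 baseline) and their
    smoothed copies behind the one-year preference delay."""

    raw: dict = field(default_factory=lambda: {m: 1.0 for m in MODES})
    smoothed: dict = field(default_factory=lambda: {m: 1.0 for m in MODES})

    def __post_init__(self) -> None:
        for d in (self.raw, self.smoothed):
            if any(v <= 0 for v in d.values()):
                raise ConfigurationError(f"perceptions must be strictly positive: {d}")


def update_perceptions(perc: Perceptions, policy_mults: dict, injury_safety_mult: float,
                       delay_years: float, dt: float) -> Perceptions:
    """Advance raw and smoothed attractiveness one step.

    Raw attractiveness per mode = baseline (1.0) x policy multiplier
    x injury-safety multiplier (bicycle only); the smoothed copy follows
    by first-order delay with the configured time constant.
    """
    if any(v <= 0 for v in policy_mults.values()) or injury_safety_mult <= 0:
        raise ConfigurationError("perception multipliers must be strictly positive")
    raw = {}
    for mode in MODES:
        value = policy_mults.get(mode, 1.0)
        if mode == "bicycle":
            value *= injury_safety_mult
        raw[mode] = value
    smoothed = {
        mode: delay_step(DelayState(perc.smoothed[mode], delay_years), raw[mode], dt).current_output
        for mode in MODES
    }
    return Perceptions(raw=raw, smoothed=smoothed)


def utilities_from_perceptions(smoothed: dict, perc_cfg: PerceptionConfig) -> dict:
    """Perception -> utility power transform.

    The survey-derived relationship between a stated perception index and
    the utility weight it contributes is nonlinear; it is carried here as a
    mode-specific elasticity (calibrated constant). With all elasticities
    at 1 the utilities are the perceptions themselves.
    """
    return {m: smoothed[m] ** perc_cfg.utility_elasticity[m] for m in MODES}


def mode_shares_from_perceptions(attractiveness: dict, base_shares: dict,
                                 trip: TripConfig) -> dict:
    """Relative-utility share formula with trip-distance caps.

    share_m = base_m * A_m / sum_k base_k * A_k, then the bicycle share is
    capped at the cyclable fraction and the walking share at the walkable
    fraction, with the excess renormalized over the uncapped modes.
    """
    weights = {m: base_shares[m] * attractiveness[m] for m in MODES}
    total = sum(weights.values())
    if total <= 0:
        raise ConfigurationError("all mode attractiveness indices are zero — degenerate input")
    shares = {m: w / total for m, w in weights.items()}

    caps = {"bicycle": trip.cyclable_fraction, "walk": trip.walkable_fraction}
    capped = {m for m, cap in caps.items() if shares[m] > cap}
    while capped:
        free = [m for m in MODES if m not in capped]
        remaining = 1.0 - sum(caps[m] for m in capped)
        free_total = sum(shares[m] for m in free)
        shares = {m: (caps[m] if m in capped else shares[m] * remaining / free_total)
                  for m in MODES}
        newly = {m for m, cap in caps.items() if m not in capped and shares[m] > cap + 1e-12}
        if not newly:
            break
        capped |= newly
    return shares


def annual_lv_vkt(shares: dict, commuters: float, trip: TripConfig) -> float:
    """Annual light-vehicle kilometres travelled by commuters.

    VKT = commuters x LV share / occupancy x annual trips x median trip km.
    """
    if trip.lv_occupancy <= 0:
        raise ConfigurationError(f"lv_occupancy must be > 0, got {trip.lv_occupancy}")
    return (commuters * shares["light_vehicle"] / trip.lv_occupancy
            * trip.annual_commute_trips * trip.median_lv_commute_km)
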
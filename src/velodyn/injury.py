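"""Cyclist fatal and serious injury model.

Five steps, applied per road class (local / arterial):

1. allocation of cyclist distance and vehicle volume to road classes;
2. baseline annual collision rates calibrated to 1991 counts, with an
   underreporting adjustment for serious injuries;
3. annual cyclist-car collisions scaled by cyclist exposure, a power of
   relative vehicle volume, any policy collision relative risk, the
   composite speed-reduction multiplier and the (thresholded)
   safety-in-numbers multiplier;
4. severity split into fatal and serious using speed-dependent
   conditional-probability curves, scaled at calibration;
5. a combined rate per 1,000 cyclists.

The perceived-safety feedback maps annual media-reported cyclist deaths
to the fraction of the population considering cycling "always or mostly"
safe, calibrated so that baseline-era counts map to 0.19.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .config import ROAD_CLASSES, InjuryConfig, SafetyInNumbersConfig
from .engine import ConfigurationError, LookupFunction

__all__ = ["InjuryOutcome", "SeverityModel", "sin_multiplier", "annual_collisions",
           "severity_split", "injury_rate_per_1000", "perceived_safety_from_injuries",
           "UNDEFINED_RATE"]

#: Sentinel returned by :func:`injury_rate_per_1000` when there are no cyclists.
UNDEFINED_RATE = float("nan")


@dataclass(frozen=True)
class InjuryOutcome:
    fatal: float
    serious: float

    def __post_init__(self) -> None:
        if self.fatal < 0 or self.serious < 0:
            raise ConfigurationError("injury counts must be nonnegative")

    @property
    def total(self) -> float:
        return self.fatal + self.serious


def sin_multiplier(bike_share: float, sin: SafetyInNumbersConfig) -> float:
    """Safety-in-numbers multiplier on per-cyclist collision risk.

    Thresholded variant (default): 1 at or below the threshold share, then
    (share/threshold)^exponent — continuous at the threshold. The
    ``pure_jacobsen`` variant applies (share/reference)^jacobsen_exponent
    with no threshold. The ``half_risk_reduction_variant`` halves the risk
    *reduction* of the full power function instead of its exponent.
    """
    if not 0.0 <= bike_share <= 1.0:
        raise ConfigurationError(f"bike share must be in [0, 1], got {bike_share}")
    if sin.threshold_share <= 0:
        raise ConfigurationError("safety-in-numbers threshold must be > 0")
    if not sin.enabled:
        return 1.0
    if sin.pure_jacobsen:
        if bike_share <= 0:
            return 1.0
        return (bike_share / sin.jacobsen_reference_share) ** sin.jacobsen_exponent
    if bike_share <= sin.threshold_share:
        return 1.0
    ratio = bike_share / sin.threshold_share
    if sin.half_risk_reduction_variant:
        return 1.0 - 0.5 * (1.0 - ratio ** sin.jacobsen_exponent)
    return ratio ** sin.exponent


class SeverityModel:
    """Speed-conditional severity curves with calibrated scale factors.

    The scales are solved once so the 1991 baseline state reproduces the
    configured fatal and serious counts exactly; the free multipliers
    ``collision_rate_scale`` and ``fatal_severity_scale`` then act on top
    (they are the parameters recovered by synthetic-history calibration).
    """

    def __init__(self, cfg: InjuryConfig):
        self.cfg = cfg
        self.fatal_curve = LookupFunction(tuple(map(tuple, cfg.fatal_curve_knots)))
        self.serious_curve = LookupFunction(tuple(map(tuple, cfg.serious_curve_knots)))
        # class exposure shares at baseline
        shares = {"local": cfg.local_cycling_share, "arterial": 1.0 - cfg.local_cycling_share}
        fatal_raw = sum(cfg.baseline_collisions[c] * self.fatal_curve(cfg.mean_speed_kmh[c])
                        for c in ROAD_CLASSES)
        serious_raw = sum(cfg.baseline_collisions[c] * self.serious_curve(cfg.mean_speed_kmh[c])
                          for c in ROAD_CLASSES)
        if fatal_raw <= 0 or serious_raw <= 0:
            raise ConfigurationError("baseline collisions and severity curves must yield "
                                     "positive 1991 counts for calibration")
        self._fatal_scale = cfg.fatal_count_1991 / fatal_raw
        self._serious_scale = cfg.serious_adjusted_count_1991 / serious_raw
        self._baseline_exposure = shares

    def probabilities(self, road_class: str, speed_kmh: float) -> tuple[float, float]:
        """Calibrated (P_fatal, P_serious) at a mean vehicle speed."""
        knots = self.fatal_curve.knots
        if not knots[0][0] <= speed_kmh <= knots[-1][0]:
            warnings.warn(f"mean speed {speed_kmh} km/h outside severity lookup range; clamped",
                          stacklevel=2)
        pf = self.fatal_curve(speed_kmh) * self._fatal_scale * self.cfg.fatal_severity_scale
        ps = self.serious_curve(speed_kmh) * self._serious_scale
        return pf, ps


def annual_collisions(cyclists: float, baseline_cyclists: float, vehicle_volume_ratio: dict,
                      cycling_class_share: dict, cfg: InjuryConfig, policy_rr: dict,
                      speed_mult: dict, sinm: float) -> dict:
    """Annual cyclist-car collisions per road class.

    collisions_c = baseline_c x (cyclist exposure on c / baseline exposure)
    x (vehicle volume on c / baseline)^exponent_c x policy RR_c
    x composite speed multiplier_c x safety-in-numbers multiplier.

    With every factor at its baseline value the baseline collision counts
    are returned exactly (calibration identity).
    """
    if cyclists < 0 or sinm < 0:
        raise ConfigurationError("collision inputs must be nonnegative")
    if baseline_cyclists <= 0:
        raise ConfigurationError("baseline_cyclists must be positive")
    baseline_share = {"local": cfg.local_cycling_share,
                      "arterial": 1.0 - cfg.local_cycling_share}
    out = {}
    for c in ROAD_CLASSES:
        base = cfg.baseline_collisions[c] * cfg.collision_rate_scale
        if baseline_share[c] <= 0:
            exposure = 0.0 if cycling_class_share[c] == 0 else float("inf")
        else:
            exposure = cycling_class_share[c] / baseline_share[c]
        volume = max(vehicle_volume_ratio[c], 0.0) ** cfg.volume_exponent[c]
        out[c] = (base * (cyclists / baseline_cyclists) * exposure * volume
                  * policy_rr.get(c, 1.0) * speed_mult.get(c, 1.0) * sinm)
    return out


def speed_reduction_multiplier(delta_v_kmh: float, base: float = 0.4) -> float:
    """Composite collision+severity multiplier for a mean-speed reduction.

    A 10 km/h reduction multiplies the class collision/severity product by
    ``base`` (default 0.4, i.e. a 60% reduction); intermediate reductions
    compose exponentially: base ** (delta_v / 10).
    """
    if delta_v_kmh < 0:
        raise ConfigurationError("speed reduction must be nonnegative")
    return base ** (delta_v_kmh / 10.0)


def severity_split(collisions: dict, speeds: dict, severity: SeverityModel) -> InjuryOutcome:
    """Split per-class collisions into fatal and serious annual counts.

    Serious counts are on the underreporting-adjusted ("true") scale: the
    calibration anchor itself is an adjusted count, so the adjustment is
    applied consistently on both sides.
    """
    fatal = serious = 0.0
    for c, n in collisions.items():
        if speeds[c] <= 0:
            raise ConfigurationError(f"mean speed for {c} roads must be positive")
        pf, ps = severity.probabilities(c, speeds[c])
        fatal += n * pf
        serious += n * ps
    return InjuryOutcome(fatal=fatal, serious=serious)


def injury_rate_per_1000(outcome: InjuryOutcome, cyclists: float) -> float:
    """Combined fatal+serious injuries per 1,000 cyclists; NaN when there
    are no cyclists (undefined, not a division error)."""
    if cyclists <= 0:
        return UNDEFINED_RATE
    return 1000.0 * outcome.total / cyclists


def perceived_safety_from_injuries(fatal_annual: float, serious_annual: float,
                                   curve: LookupFunction,
                                   serious_weight: float = 0.0) -> float:
    """Fraction of the population considering cycling "always or mostly" safe.

    Media-reported deaths dominate the public response; the curve maps an
    effective annual death count (fatal + serious_weight x serious) to the
    perceived-safe fraction, monotone nonincreasing in injuries.
    """
    if fatal_annual < 0 or serious_annual < 0:
        raise ConfigurationError("injury counts must be nonnegative")
    effective = fatal_annual + serious_weight * serious_annual
    return curve(effective)
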
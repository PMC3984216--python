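"""Collision, severity, safety-in-numbers and perceived-safety operations."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from velodyn.config import InjuryConfig, SafetyInNumbersConfig
from velodyn.engine import ConfigurationError, LookupFunction
from velodyn.injury import (InjuryOutcome, SeverityModel, annual_collisions,
                            injury_rate_per_1000, perceived_safety_from_injuries,
                            sin_multiplier, speed_reduction_multiplier, severity_split)

BASELINE_VOL = {"local": 1.0, "arterial": 1.0}
BASELINE_SHARE = {"local": 0.5, "arterial": 0.5}
NO_RR = {"local": 1.0, "arterial": 1.0}
NO_SPEED = {"local": 1.0, "arterial": 1.0}


class TestSafetyInNumbers:
    def test_below_and_at_threshold_is_neutral(self):
        sin = SafetyInNumbersConfig()
        assert sin_multiplier(0.02, sin) == 1.0
        assert sin_multiplier(0.025, sin) == 1.0

    def test_power_law_above_threshold(self):
        sin = SafetyInNumbersConfig()
        assert sin_multiplier(0.10, sin) == pytest.approx(4.0 ** -0.3, rel=1e-12)
        assert sin_multiplier(0.10, sin) == pytest.approx(0.660, abs=1e-3)

    def test_continuity_at_threshold(self):
        sin = SafetyInNumbersConfig()
        assert sin_multiplier(0.0250001, sin) == pytest.approx(1.0, abs=1e-4)

    def test_pure_jacobsen_has_no_threshold(self):
        sin = SafetyInNumbersConfig(pure_jacobsen=True)
        assert sin_multiplier(0.01, sin) == pytest.approx((0.01 / 0.02) ** -0.6)
        assert sin_multiplier(0.04, sin) == pytest.approx(2.0 ** -0.6)

    def test_half_risk_reduction_variant(self):
        sin = SafetyInNumbersConfig(half_risk_reduction_variant=True)
        full = (0.05 / 0.025) ** -0.6
        assert sin_multiplier(0.05, sin) == pytest.approx(1 - 0.5 * (1 - full))

    def test_disabled_and_invalid(self):
        assert sin_multiplier(0.3, SafetyInNumbersConfig(enabled=False)) == 1.0
        with pytest.raises(ConfigurationError):
            sin_multiplier(0.05, SafetyInNumbersConfig(threshold_share=0.0))
        with pytest.raises(ConfigurationError):
            sin_multiplier(1.5, SafetyInNumbersConfig())

    @given(st.floats(0.0, 0.5))
    @settings(max_examples=60, derandomize=True)
    def test_multiplier_in_unit_interval(self, share):
        assert 0.0 < sin_multiplier(share, SafetyInNumbersConfig()) <= 1.0


class TestCollisions:
    def test_zero_cyclists_zero_collisions(self, cfg):
        out = annual_collisions(0.0, 8000.0, BASELINE_VOL, BASELINE_SHARE,
                                cfg.injury, NO_RR, NO_SPEED, 1.0)
        assert out == {"local": 0.0, "arterial": 0.0}

    def test_calibration_identity(self, cfg):
        out = annual_collisions(8000.0, 8000.0, BASELINE_VOL, BASELINE_SHARE,
                                cfg.injury, NO_RR, NO_SPEED, 1.0)
        assert out["local"] == pytest.approx(cfg.injury.baseline_collisions["local"])
        assert out["arterial"] == pytest.approx(cfg.injury.baseline_collisions["arterial"])

    def test_square_root_volume_law(self, cfg):
        cfg.injury.volume_exponent = {"local": 0.5, "arterial": 0.5}
        ref = annual_collisions(8000.0, 8000.0, BASELINE_VOL, BASELINE_SHARE,
                                cfg.injury, NO_RR, NO_SPEED, 1.0)
        out = annual_collisions(8000.0, 8000.0, {"local": 4.0, "arterial": 4.0},
                                BASELINE_SHARE, cfg.injury, NO_RR, NO_SPEED, 1.0)
        for c in ref:
            assert out[c] == pytest.approx(2.0 * ref[c])


class TestSeverity:
    def test_zero_collisions_zero_injuries(self, cfg):
        sev = SeverityModel(cfg.injury)
        out = severity_split({"local": 0.0, "arterial": 0.0},
                             cfg.injury.mean_speed_kmh, sev)
        assert out.fatal == 0.0 and out.serious == 0.0

    def test_1991_calibration_anchors(self, cfg):
        sev = SeverityModel(cfg.injury)
        out = severity_split({c: cfg.injury.baseline_collisions[c] for c in BASELINE_VOL},
                             cfg.injury.mean_speed_kmh, sev)
        assert out.fatal == pytest.approx(cfg.injury.fatal_count_1991, rel=1e-9)
        assert out.serious == pytest.approx(cfg.injury.serious_adjusted_count_1991, rel=1e-9)

    def test_severity_monotone_in_speed(self, cfg):
        sev = SeverityModel(cfg.injury)
        pf30, ps30 = sev.probabilities("local", 30.0)
        pf50, ps50 = sev.probabilities("local", 50.0)
        assert pf50 >= pf30 and ps50 >= ps30

    def test_composite_speed_convention_60pct_per_10kmh(self):
        # the published speed effect is a combined collision/severity product
        assert speed_reduction_multiplier(10.0) == pytest.approx(0.4)
        assert speed_reduction_multiplier(15.0) == pytest.approx(0.4 ** 1.5)
        assert speed_reduction_multiplier(0.0) == 1.0

    def test_out_of_range_speed_clamps_with_warning(self, cfg):
        sev = SeverityModel(cfg.injury)
        with pytest.warns(UserWarning, match="clamped"):
            pf_high, _ = sev.probabilities("local", 300.0)
        assert pf_high == pytest.approx(sev.probabilities("local", 80.0)[0])


class TestRateAndPerception:
    def test_rate_arithmetic(self):
        assert injury_rate_per_1000(InjuryOutcome(8.0, 192.0), 20_000) == pytest.approx(10.0)

    def test_doubling_cyclists_halves_rate(self):
        out = InjuryOutcome(5.0, 45.0)
        assert injury_rate_per_1000(out, 10_000) == pytest.approx(
            2 * injury_rate_per_1000(out, 20_000))

    def test_zero_cyclists_gives_nan_sentinel(self):
        assert math.isnan(injury_rate_per_1000(InjuryOutcome(1.0, 1.0), 0.0))

    def test_baseline_counts_map_to_19pct(self, cfg):
        curve = LookupFunction(tuple(map(tuple, cfg.perception.safety_curve_knots)))
        s = perceived_safety_from_injuries(cfg.injury.fatal_count_1991,
                                           cfg.injury.serious_adjusted_count_1991, curve)
        assert s == pytest.approx(0.19, abs=1e-6)

    def test_zero_injuries_hits_curve_maximum(self, cfg):
        curve = LookupFunction(tuple(map(tuple, cfg.perception.safety_curve_knots)))
        top = perceived_safety_from_injuries(0.0, 0.0, curve)
        assert top == max(y for _, y in curve.knots)
        assert top <= 1.0

    def test_tenfold_injuries_strictly_lower_perception(self, cfg):
        curve = LookupFunction(tuple(map(tuple, cfg.perception.safety_curve_knots)))
        base = perceived_safety_from_injuries(2.0, 32.0, curve)
        worse = perceived_safety_from_injuries(20.0, 320.0, curve)
        assert worse < base
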
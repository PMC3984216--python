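"""Commuter growth, perceptions and the relative-utility mode-share model."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from velodyn.config import Demographics, PerceptionConfig, ScenarioConfig, TripConfig
from velodyn.demand import (Perceptions, annual_lv_vkt, mode_shares_from_perceptions,
                            project_commuters, update_perceptions,
                            utilities_from_perceptions)
from velodyn.engine import ConfigurationError

BASE = {"light_vehicle": 0.85, "bicycle": 0.02, "walk": 0.055, "public_transport": 0.075}


class TestCommuterGrowth:
    def test_baseline_and_endpoint(self):
        demo = Demographics()
        assert project_commuters(1991.0, demo) == pytest.approx(400_000.0)
        assert project_commuters(2051.0, demo) == pytest.approx(560_000.0, rel=1e-3)

    def test_midpoint_closed_form(self):
        demo = Demographics()
        assert project_commuters(2021.0, demo) == pytest.approx(400_000 * 1.4 ** 0.5, rel=1e-9)
        assert project_commuters(2021.0, demo) == pytest.approx(473_300, rel=1e-3)

    def test_growth_rate_independent_of_run_length(self):
        demo = Demographics()
        assert project_commuters(2001.0, demo, start_year=1991.0) == pytest.approx(
            400_000 * 1.4 ** (10 / 60))


class TestPerceptions:
    def test_identity_multipliers_keep_baseline(self):
        perc = Perceptions()
        out = update_perceptions(perc, {m: 1.0 for m in BASE}, 1.0, 1.0, 0.25)
        assert all(v == pytest.approx(1.0) for v in out.raw.values())
        assert all(v == pytest.approx(1.0) for v in out.smoothed.values())

    def test_step_boost_follows_first_order_delay(self):
        perc = Perceptions()
        dt = 0.01
        for _ in range(100):  # 1 year at tau = 1 yr
            perc = update_perceptions(perc, {"bicycle": 1.5}, 1.0, 1.0, dt)
        import math
        assert perc.smoothed["bicycle"] == pytest.approx(1 + 0.5 * (1 - math.exp(-1)), abs=5e-3)

    def test_lv_convenience_multiplier_passes_through(self):
        perc = Perceptions()
        out = update_perceptions(perc, {"light_vehicle": 0.7}, 1.0, 1.0, 0.25)
        assert out.raw["light_vehicle"] == pytest.approx(0.7)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ConfigurationError):
            update_perceptions(Perceptions(), {"bicycle": 0.0}, 1.0, 1.0, 0.25)

    def test_unit_elasticities_are_identity(self):
        pc = PerceptionConfig()
        pc.utility_elasticity = {m: 1.0 for m in BASE}
        smoothed = {"light_vehicle": 0.9, "bicycle": 1.2, "walk": 1.0, "public_transport": 1.1}
        assert utilities_from_perceptions(smoothed, pc) == smoothed


class TestModeShares:
    def test_identity_returns_base_shares(self):
        shares = mode_shares_from_perceptions({m: 1.0 for m in BASE}, BASE, TripConfig())
        for m in BASE:
            assert shares[m] == pytest.approx(BASE[m])

    def test_doubled_bicycle_attractiveness(self):
        a = {m: 1.0 for m in BASE}
        a["bicycle"] = 2.0
        shares = mode_shares_from_perceptions(a, BASE, TripConfig())
        assert shares["bicycle"] == pytest.approx(0.04 / 1.02, rel=1e-9)

    def test_extreme_attractiveness_binds_cyclable_cap(self):
        a = {m: 1.0 for m in BASE}
        a["bicycle"] = 1e6
        shares = mode_shares_from_perceptions(a, BASE, TripConfig())
        assert shares["bicycle"] == pytest.approx(0.50)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_attractiveness_is_degenerate(self):
        with pytest.raises(ConfigurationError):
            mode_shares_from_perceptions({m: 0.0 for m in BASE}, BASE, TripConfig())

    @given(st.lists(st.floats(0.05, 50.0), min_size=4, max_size=4))
    @settings(max_examples=80, derandomize=True)
    def test_shares_sum_to_one_and_respect_caps(self, values):
        a = dict(zip(BASE, values))
        shares = mode_shares_from_perceptions(a, BASE, TripConfig())
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)
        assert shares["bicycle"] <= 0.50 + 1e-9
        assert shares["walk"] <= 0.27 + 1e-9
        assert all(0 <= v <= 1 for v in shares.values())

    @given(st.floats(1.0, 30.0), st.floats(1.01, 3.0))
    @settings(max_examples=40, derandomize=True)
    def test_raising_bicycle_attractiveness_never_lowers_its_share(self, a_bike, factor):
        a = {m: 1.0 for m in BASE}
        a["bicycle"] = a_bike
        lo = mode_shares_from_perceptions(a, BASE, TripConfig())["bicycle"]
        a["bicycle"] = a_bike * factor
        hi = mode_shares_from_perceptions(a, BASE, TripConfig())["bicycle"]
        assert hi >= lo - 1e-12


class TestVkt:
    def test_zero_share_zero_vkt(self):
        shares = dict(BASE, light_vehicle=0.0)
        assert annual_lv_vkt(shares, 4e5, TripConfig()) == 0.0

    def test_default_parameter_arithmetic(self):
        assert annual_lv_vkt(BASE, 400_000, TripConfig()) == pytest.approx(1.088e9, rel=1e-9)

    def test_doubling_occupancy_halves_vkt(self):
        t1 = TripConfig()
        t2 = TripConfig(lv_occupancy=2 * t1.lv_occupancy)
        assert annual_lv_vkt(BASE, 4e5, t2) == pytest.approx(annual_lv_vkt(BASE, 4e5, t1) / 2)

    def test_nonpositive_occupancy_rejected(self):
        with pytest.raises(ConfigurationError):
            annual_lv_vkt(BASE, 4e5, TripConfig(lv_occupancy=0.0))
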
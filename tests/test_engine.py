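"""Stock-flow primitives: grids, lookups, delays, rollout curves, Euler."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from velodyn.engine import (ConfigurationError, DelayState, LookupFunction,
                            NumericalError, RolloutCurve, TimeGrid, delay_step,
                            integrate, s_curve)


class TestTimeGrid:
    def test_default_grid_has_240_steps(self):
        grid = TimeGrid()
        assert grid.n_steps == 240
        years = grid.years()
        assert years[0] == 1991.0 and years[-1] == 2051.0
        assert len(years) == 241

    @pytest.mark.parametrize("kwargs", [
        {"start_year": 2051, "end_year": 1991},
        {"dt": 0.0},
        {"dt": -0.5},
        {"dt": 0.7},  # non-integer number of steps
    ])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            TimeGrid(**{"start_year": 1991.0, "end_year": 2051.0, **kwargs})


class TestLookup:
    def test_linear_interpolation_and_clamping(self):
        f = LookupFunction(((0.0, 0.0), (1.0, 1.0)))
        assert f(0.5) == pytest.approx(0.5)
        assert f(-3.0) == 0.0  # clamp below
        assert f(9.0) == 1.0   # clamp above

    def test_hand_interpolated_plateau(self):
        f = LookupFunction(((0, 0), (2, 4), (4, 4)))
        assert f(3.0) == pytest.approx(4.0)
        assert f(1.0) == pytest.approx(2.0)

    def test_non_increasing_knots_rejected(self):
        with pytest.raises(ConfigurationError):
            LookupFunction(((0, 0), (0, 1)))
        with pytest.raises(ConfigurationError):
            LookupFunction(((1, 0),))

    @given(st.floats(-5, 15))
    @settings(max_examples=50, derandomize=True)
    def test_evaluation_at_knots_is_exact_and_monotone_inputs_bounded(self, x):
        f = LookupFunction(((0, 1.0), (5, 2.0), (10, 2.5)))
        assert 1.0 <= f(x) <= 2.5
        for kx, ky in f.knots:
            assert f(kx) == pytest.approx(ky, abs=1e-12)


class TestDelay:
    def test_fixed_point(self):
        d = DelayState(0.7, 1.0)
        assert delay_step(d, 0.7, 0.25).current_output == pytest.approx(0.7)

    @pytest.mark.parametrize("tau", [1.0, 2.0])
    def test_step_response_reaches_63pct_at_tau(self, tau):
        d = DelayState(0.0, tau)
        dt = 0.001
        for _ in range(int(tau / dt)):
            d = delay_step(d, 1.0, dt)
        assert d.current_output == pytest.approx(1.0 - math.exp(-1.0), abs=2e-3)

    def test_monotone_convergence_to_constant_input(self):
        d = DelayState(0.0, 1.5)
        previous = d.current_output
        for _ in range(200):
            d = delay_step(d, 1.0, 0.1)
            assert previous <= d.current_output <= 1.0
            previous = d.current_output

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            DelayState(0.0, 0.0)
        with pytest.raises(ConfigurationError):
            delay_step(DelayState(0.0, 1.0), 1.0, 0.0)


class TestSCurve:
    def test_midpoint_is_half(self):
        curve = RolloutCurve(2012.0, 2050.0)
        assert s_curve(2031.0, curve) == pytest.approx(0.5)

    def test_floor_before_start_and_ceiling_at_completion(self):
        curve = RolloutCurve(2012.0, 2050.0)
        assert s_curve(1995.0, curve) <= 0.01
        assert s_curve(2050.0, curve) >= 0.99

    def test_degenerate_window_rejected(self):
        with pytest.raises(ConfigurationError):
            RolloutCurve(2050.0, 2012.0)

    @given(st.floats(1990, 2060), st.floats(1990, 2060))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_nondecreasing(self, a, b):
        curve = RolloutCurve(2012.0, 2040.0)
        lo, hi = min(a, b), max(a, b)
        assert s_curve(lo, curve) <= s_curve(hi, curve) + 1e-12


class TestIntegrate:
    def test_zero_flows_give_constant_trajectory(self):
        grid = TimeGrid(0.0, 10.0, 0.5)
        traj = integrate(lambda t, s, dt: dict(s), grid, {"stock": 3.0})
        assert (traj["stock"] == 3.0).all()
        assert len(traj) == grid.n_steps + 1

    def test_constant_inflow_matches_closed_form(self):
        grid = TimeGrid(0.0, 10.0, 0.25)
        rate = 2.0

        def step(t, s, dt):
            return {"stock": s["stock"] + rate * dt}

        traj = integrate(step, grid, {"stock": 1.0})
        expected = 1.0 + rate * (traj["year"] - 0.0)
        assert np.allclose(traj["stock"], expected, atol=rate * grid.dt)

    def test_bit_identical_reruns(self):
        grid = TimeGrid(0.0, 5.0, 0.25)

        def step(t, s, dt):
            return {"x": s["x"] + math.sin(t) * dt, "y": s["y"] * (1 - 0.1 * dt)}

        a = integrate(step, grid, {"x": 0.1, "y": 1.0})
        b = integrate(step, grid, {"x": 0.1, "y": 1.0})
        assert a.equals(b)

    def test_nonfinite_state_reports_variable_and_step(self):
        grid = TimeGrid(0.0, 2.0, 0.5)

        def step(t, s, dt):
            return {"bad": s["bad"] / (1.0 - t) if t != 1.0 else float("inf")}

        with pytest.raises(NumericalError, match="bad"):
            integrate(step, grid, {"bad": 1.0})
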
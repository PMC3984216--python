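"""Deterministic stock-flow simulation primitives.

Fixed-step Euler integration, piecewise-linear lookup functions,
first-order exponential delays and S-shaped (logistic) rollout curves:
the standard building blocks of a system-dynamics model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "NumericalError",
    "TimeGrid",
    "LookupFunction",
    "DelayState",
    "RolloutCurve",
    "s_curve",
    "delay_step",
    "integrate",
]


class ConfigurationError(ValueError):
    """A parameter or structural setting violates its declared constraints."""


class NumericalError(ArithmeticError):
    """A state variable became non-finite during integration."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform simulation grid in calendar years.

    ``dt`` is the Euler step in years; the span must be an integer
    number of steps so both endpoints lie on the grid.
    """

    start_year: float = 1991.0
    end_year: float = 2051.0
    dt: float = 0.25

    def __post_init__(self) -> None:
        if not self.start_year < self.end_year:
            raise ConfigurationError(
                f"start_year ({self.start_year}) must precede end_year ({self.end_year})"
            )
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        span = self.end_year - self.start_year
        n = span / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"(end_year - start_year)/dt = {n} is not an integer number of steps"
            )

    @property
    def n_steps(self) -> int:
        return int(round((self.end_year - self.start_year) / self.dt))

    def years(self) -> np.ndarray:
        """Grid points, inclusive of both endpoints (n_steps + 1 values)."""
        return self.start_year + self.dt * np.arange(self.n_steps + 1)


@dataclass(frozen=True)
class LookupFunction:
    """Piecewise-linear interpolation through ordered knots.

    Evaluation outside the knot range clamps to the endpoint values;
    graphical relationships in the model are never extrapolated beyond
    their calibrated range.
    """

    knots: tuple[tuple[float, float], ...]
    clamp: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "knots", tuple((float(x), float(y)) for x, y in self.knots))
        if len(self.knots) < 2:
            raise ConfigurationError("LookupFunction needs at least 2 knots")
        xs = [x for x, _ in self.knots]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigurationError(f"lookup knot x-values must be strictly increasing: {xs}")

    def __call__(self, x: float) -> float:
        xs = np.array([k[0] for k in self.knots])
        ys = np.array([k[1] for k in self.knots])
        # np.interp clamps to endpoint values outside the range, which is
        # exactly the configured behaviour (clamp=True is the only mode
        # shipped; the flag records the contract).
        return float(np.interp(x, xs, ys))


def lookup_eval(f: LookupFunction, x: float) -> float:
    """Functional alias for ``f(x)``."""
    return f(x)


@dataclass(frozen=True)
class DelayState:
    """First-order exponential smoothing state (a 'material delay').

    ``current_output`` converges monotonically toward a constant input
    with time constant ``time_constant`` (years).
    """

    current_output: float
    time_constant: float

    def __post_init__(self) -> None:
        if self.time_constant <= 0:
            raise ConfigurationError(f"delay time_constant must be > 0, got {self.time_constant}")


def delay_step(d: DelayState, input_value: float, dt: float) -> DelayState:
    """Advance a first-order delay one Euler step: y += (u - y) * dt / tau."""
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    new = d.current_output + (input_value - d.current_output) * dt / d.time_constant
    return replace(d, current_output=new)


@dataclass(frozen=True)
class RolloutCurve:
    """S-shaped (logistic) implementation curve for a policy rollout.

    The curve is ~0 (<= 1% of range) at ``start_year`` and ~1 (>= 99%)
    at ``completion_year``, symmetric about the window midpoint.
    """

    start_year: float
    completion_year: float
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if self.completion_year <= self.start_year:
            raise ConfigurationError(
                f"completion_year ({self.completion_year}) must exceed start_year ({self.start_year})"
            )
        if not self.floor < self.ceiling:
            raise ConfigurationError("rollout floor must be below ceiling")


def s_curve(t: float, curve: RolloutCurve) -> float:
    """Evaluate a logistic rollout fraction at calendar year ``t``.

    The steepness is set so the logistic passes through 1% / 99% of its
    range at the window endpoints; values are clipped to [floor, ceiling].
    """
    mid = 0.5 * (curve.start_year + curve.completion_year)
    half_window = 0.5 * (curve.completion_year - curve.start_year)
    k = math.log(99.0) / half_window  # sigma(start) = 0.01, sigma(completion) = 0.99
    sigma = 1.0 / (1.0 + math.exp(-k * (t - mid)))
    value = curve.floor + (curve.ceiling - curve.floor) * sigma
    return min(max(value, curve.floor), curve.ceiling)


def integrate(step_fn, grid: TimeGrid, initial: dict) -> pd.DataFrame:
    """Run a fixed-step Euler simulation over ``grid``.

    ``step_fn(t, state, dt) -> state`` must return the full state dict for
    time ``t + dt``; every numeric entry of the state is recorded at every
    grid point (inclusive of both endpoints). Raises :class:`NumericalError`
    naming the offending variable and step if any entry goes non-finite.
    The result is purely deterministic given ``step_fn`` and ``initial``.
    """
    years = grid.years()
    records: list[dict] = []
    state = dict(initial)
    _check_finite(state, years[0])
    records.append(dict(state))
    for i in range(grid.n_steps):
        t = float(years[i])
        state = step_fn(t, state, grid.dt)
        _check_finite(state, float(years[i + 1]))
        records.append(dict(state))
    frame = pd.DataFrame.from_records(records)
    frame.insert(0, "year", years)
    return frame


def _check_finite(state: dict, year: float) -> None:
    for key, value in state.items():
        if isinstance(value, (int, float)) and not math.isfinite(value):
            raise NumericalError(f"state variable '{key}' is non-finite ({value}) at year {year}")
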
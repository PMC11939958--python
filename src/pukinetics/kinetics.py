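"""Numerical integration and the closed-form kinetic solutions.

The closed forms (`first_order_decay`, `linear_relaxation`) are the
analytic solutions of the two linear ODE families every model in this
package reduces to; the fixed-step RK4 integrator provides the
independent numeric route against which they are cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NumericalBlowupError


@dataclass(frozen=True)
class TimeGrid:
    """Uniform, closed time grid in hours."""

    t_start: float = 0.0
    t_end: float = 500.0
    n_points: int = 501

    def __post_init__(self) -> None:
        if not (self.t_end > self.t_start >= 0):
            raise InvalidParameterError(
                f"need t_end > t_start >= 0 (got [{self.t_start}, {self.t_end}])"
            )
        if self.n_points < 2:
            raise InvalidParameterError(f"need n_points >= 2 (got {self.n_points})")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_points)

    @property
    def step(self) -> float:
        return (self.t_end - self.t_start) / (self.n_points - 1)


#: Default grid for reproducing the four default figures: 500 h at 1 h
#: resolution shows the knee of every curve at the default constants.
DEFAULT_GRID = TimeGrid(0.0, 500.0, 501)


@dataclass
class TimeSeries:
    """A sampled scalar trajectory."""

    times: np.ndarray
    values: np.ndarray
    label: str = "value"
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and values must be 1-D and equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, self.label: self.values})

    def to_csv(self, path) -> None:
        """Write `time_h,<label>` CSV at full double precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17e")

    @classmethod
    def from_csv(cls, path, units: str = "") -> "TimeSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] != 2 or df.columns[0] != "time_h":
            raise InvalidParameterError(
                f"expected two columns starting with 'time_h', got {list(df.columns)}"
            )
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   label=df.columns[1], units=units)


def integrate_ode(
    rhs: Callable[[float, float], float],
    initial_state: float,
    grid: TimeGrid,
    method: str = "rk4_fixed",
) -> TimeSeries:
    """Integrate dy/dt = rhs(t, y) with classical fixed-step RK4.

    The step equals the grid spacing and the state is reported on every
    grid point. A non-finite state aborts with
    :class:`~pukinetics.errors.NumericalBlowupError` naming the time.
    """
    if method != "rk4_fixed":
        raise InvalidParameterError(f"unknown integration method {method!r}")
    times = grid.times
    h = grid.step
    y = float(initial_state)
    out = np.empty_like(times)
    out[0] = y
    for i in range(len(times) - 1):
        t = times[i]
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2.0, y + h / 2.0 * k1)
        k3 = rhs(t + h / 2.0, y + h / 2.0 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.isfinite(y):
            raise NumericalBlowupError(times[i + 1])
        out[i + 1] = y
    return TimeSeries(times, out, label="state")


def first_order_decay(y0: float, k: float, t: float | np.ndarray) -> float | np.ndarray:
    """Exact solution y₀·e^(−kt) of dy/dt = −k·y."""
    if not k > 0:
        raise InvalidParameterError(f"rate constant must be > 0 (got {k})")
    t = np.asarray(t, dtype=float) if np.ndim(t) else float(t)
    if np.any(np.asarray(t) < 0):
        raise InvalidParameterError("time must be >= 0")
    return y0 * np.exp(-k * t)


def linear_relaxation(
    y0: float, source: float, k: float, t: float | np.ndarray
) -> float | np.ndarray:
    """Exact solution of dy/dt = source − k·y.

    y(t) = source/k + (y₀ − source/k)·e^(−kt); relaxes monotonically to
    the steady state source/k from either side.
    """
    if not k > 0:
        raise InvalidParameterError(f"rate constant must be > 0 (got {k})")
    t = np.asarray(t, dtype=float) if np.ndim(t) else float(t)
    if np.any(np.asarray(t) < 0):
        raise InvalidParameterError("time must be >= 0")
    y_inf = source / k
    return y_inf + (y0 - y_inf) * np.exp(-k * t)
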
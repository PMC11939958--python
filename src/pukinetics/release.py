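"""Forward models for PU matrix degradation and DNA/RNA release.

Two release mechanisms are implemented: first-order kinetics
(dM/dt = −k_rel·M, exponential decay of the encapsulated mass) and the
Higuchi diffusional law, in which the released fraction grows with
√(Dt/L²) until the matrix is depleted at t* = L²/D.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .kinetics import TimeGrid, TimeSeries, first_order_decay
from .params import DegradationParams, HiguchiForm, HiguchiParams, ReleaseParams

_CONSERVATION_RTOL = 1e-9


class ReleaseModel(str, enum.Enum):
    FIRST_ORDER = "first_order"
    HIGUCHI = "higuchi"


@dataclass
class ReleaseProfile:
    """Paired remaining/released mass trajectories with mass conservation."""

    times: np.ndarray
    remaining_mass: np.ndarray
    released_mass: np.ndarray
    m0_effective: float
    model: ReleaseModel

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.remaining_mass = np.asarray(self.remaining_mass, dtype=float)
        self.released_mass = np.asarray(self.released_mass, dtype=float)
        for name in self.violations():
            raise InvalidParameterError(name)

    def violations(self) -> list[str]:
        out = []
        if np.any(self.remaining_mass < 0) or np.any(self.released_mass < 0):
            out.append("masses must be non-negative")
        total = self.remaining_mass + self.released_mass
        if not np.allclose(total, self.m0_effective, rtol=_CONSERVATION_RTOL, atol=0):
            out.append("remaining + released must equal m0_effective")
        if np.any(np.diff(self.remaining_mass) > 0):
            out.append("remaining mass must be non-increasing")
        if np.any(np.diff(self.released_mass) < 0):
            out.append("released mass must be non-decreasing")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "remaining_mg": self.remaining_mass,
                "released_mg": self.released_mass,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17e")


def _check(params) -> None:
    bad = params.violations()
    if bad:
        raise InvalidParameterError("; ".join(bad))


def simulate_degradation(params: DegradationParams, grid: TimeGrid) -> TimeSeries:
    """PU concentration C(t) = C₀·e^(−kt) on the grid, mg/mL."""
    _check(params)
    values = first_order_decay(params.c0, params.k, grid.times)
    return TimeSeries(grid.times, values, label="pu_conc_mg_per_ml", units="mg/mL")


def simulate_first_order_release(params: ReleaseParams, grid: TimeGrid) -> ReleaseProfile:
    """Exponential release: remaining M(t) = EE·M₀·e^(−k_rel·t)."""
    _check(params)
    m0 = params.m0_effective
    remaining = first_order_decay(m0, params.k_rel, grid.times)
    return ReleaseProfile(
        grid.times, remaining, m0 - remaining, m0, ReleaseModel.FIRST_ORDER
    )


def higuchi_remaining(params: HiguchiParams, t: float | np.ndarray) -> float | np.ndarray:
    """Remaining mass under the diffusional law, clamped at depletion.

    With τ = Dt/L²: remaining = M₀·(1 − √τ) for the square-root form,
    M₀·(1 − τ) for the linear form; identically 0 for t ≥ t* = L²/D
    (the law leaves the post-depletion regime undefined, so it is
    clamped rather than allowed to go negative).
    """
    _check(params)
    tau = np.asarray(t, dtype=float) * params.d_nm2_per_h / params.length_nm**2
    if params.form is HiguchiForm.SQUARE_ROOT:
        frac_released = np.sqrt(tau)
    else:
        frac_released = tau
    remaining = params.m0_effective * np.clip(1.0 - frac_released, 0.0, None)
    return float(remaining) if np.ndim(t) == 0 else remaining


def simulate_higuchi_release(params: HiguchiParams, grid: TimeGrid) -> ReleaseProfile:
    """Diffusional release profile on the grid."""
    remaining = np.asarray(higuchi_remaining(params, grid.times))
    return ReleaseProfile(
        grid.times,
        remaining,
        params.m0_effective - remaining,
        params.m0_effective,
        ReleaseModel.HIGUCHI,
    )


def time_to_fraction_released(
    params: ReleaseParams | HiguchiParams, fraction: float
) -> float:
    """Analytic inversion: hours until a given released fraction.

    first-order: t = −ln(1−f)/k_rel; Higuchi square-root: t = f²·L²/D;
    Higuchi linear: t = f·L²/D.
    """
    if not 0 < fraction < 1:
        raise InvalidParameterError(f"fraction must lie in (0, 1) (got {fraction})")
    _check(params)
    if isinstance(params, ReleaseParams):
        return -np.log(1.0 - fraction) / params.k_rel
    if isinstance(params, HiguchiParams):
        t_star = params.depletion_time_h
        if params.form is HiguchiForm.SQUARE_ROOT:
            return fraction**2 * t_star
        return fraction * t_star
    raise InvalidParameterError(f"unsupported parameter type {type(params).__name__}")
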
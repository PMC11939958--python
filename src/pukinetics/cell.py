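"""Cell-interaction models: Langmuir adsorption and endocytic uptake.

Adsorption of PU nanoparticles onto the membrane follows the Langmuir
isotherm θ = K·C/(1 + K·C); internalization then balances uptake from
the occupied sites against intracellular degradation,
dN/dt = k_uptake·θ·N_max − k_degr·N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .kinetics import TimeGrid, TimeSeries, integrate_ode, linear_relaxation
from .params import AdsorptionParams, UptakeParams


@dataclass
class IsothermCurve:
    """Membrane coverage fraction versus nanoparticle concentration."""

    concentrations_molar: np.ndarray
    concentrations_mg_per_ml: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_molar = np.asarray(self.concentrations_molar, dtype=float)
        self.concentrations_mg_per_ml = np.asarray(self.concentrations_mg_per_ml, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if np.any(self.coverage < 0) or np.any(self.coverage >= 1):
            raise InvalidParameterError("coverage must lie in [0, 1)")
        if len(self.coverage) >= 2 and np.any(np.diff(self.coverage) <= 0):
            raise InvalidParameterError("coverage must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "conc_mg_per_ml": self.concentrations_mg_per_ml,
                "conc_molar": self.concentrations_molar,
                "coverage": self.coverage,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17e")


def langmuir_coverage(concentration_molar, k_per_molar: float):
    """Equilibrium coverage θ = K·C/(1 + K·C); saturates toward 1."""
    if not k_per_molar > 0:
        raise InvalidParameterError(f"K must be > 0 (got {k_per_molar})")
    c = np.asarray(concentration_molar, dtype=float)
    if np.any(c < 0):
        raise InvalidParameterError("concentration must be >= 0")
    kc = k_per_molar * c
    theta = kc / (1.0 + kc)
    return float(theta) if np.ndim(concentration_molar) == 0 else theta


def default_isotherm_grid(params: AdsorptionParams, n_points: int = 50) -> np.ndarray:
    """Log-spaced mg/mL grid spanning 10⁻³/K to 10³/K in molar units.

    Six decades around the half-saturation concentration capture both
    the initial rise and the plateau.
    """
    c_half_molar = 1.0 / params.k_ads
    molar = np.logspace(-3, 3, n_points) * c_half_molar
    return molar * params.molar_mass  # mol/L → mg/mL (g/L)


def coverage_isotherm(
    params: AdsorptionParams, concentration_grid_mg_per_ml
) -> IsothermCurve:
    """Langmuir isotherm over a mass-concentration grid (mg/mL)."""
    bad = params.violations()
    if bad:
        raise InvalidParameterError("; ".join(bad))
    grid = np.asarray(concentration_grid_mg_per_ml, dtype=float)
    if np.any(grid < 0):
        raise InvalidParameterError("concentrations must be >= 0")
    if len(grid) >= 2 and np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("concentration grid must be strictly increasing")
    molar = grid / params.molar_mass  # 0 is allowed here; mass_to_molar guards scalars
    theta = langmuir_coverage(molar, params.k_ads)
    return IsothermCurve(molar, grid, theta)


def internalization_steady_state(params: UptakeParams) -> float:
    """Balance point of uptake and degradation, N_ss = k_uptake·θ·N_max/k_degr."""
    bad = params.violations()
    if bad:
        raise InvalidParameterError("; ".join(bad))
    return params.k_uptake * params.theta * params.n_max / params.k_degr


def internalization_closed_form(params: UptakeParams, t) -> float | np.ndarray:
    """Exact N(t) from the linear-relaxation solution."""
    bad = params.violations()
    if bad:
        raise InvalidParameterError("; ".join(bad))
    source = params.k_uptake * params.theta * params.n_max
    return linear_relaxation(params.n0, source, params.k_degr, t)


def simulate_internalization(params: UptakeParams, grid: TimeGrid) -> TimeSeries:
    """Internalized-vector count N(t) on the grid.

    Integrates dN/dt = k_uptake·θ·N_max − k_degr·N from N₀ by RK4;
    :func:`internalization_closed_form` is the analytic cross-check.
    With N₀ = 0 the trajectory rises monotonically toward the steady
    state N_ss and never exceeds it.
    """
    bad = params.violations()
    if bad:
        raise InvalidParameterError("; ".join(bad))
    source = params.k_uptake * params.theta * params.n_max

    def rhs(t: float, n: float) -> float:
        return source - params.k_degr * n

    series = integrate_ode(rhs, params.n0, grid)
    return TimeSeries(grid.times, series.values, label="internalized_count", units="count")
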
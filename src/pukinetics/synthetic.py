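"""Seeded synthetic-data generation for the PU delivery models.

Everything downstream of the forward models — the fitters, the CLI,
the test suite — is exercised on data produced here, so real
measurements are never required. Two noise families are provided:
multiplicative lognormal (default for masses and concentrations; keeps
positivity and mimics proportional assay error) and additive Gaussian
clipped at zero (default for coverage fractions). ``sigma = 0``
reproduces the forward model exactly.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cell import coverage_isotherm, default_isotherm_grid, simulate_internalization
from .errors import ConfigurationError, InvalidParameterError
from .kinetics import DEFAULT_GRID, TimeGrid, TimeSeries
from .params import (
    DiffusivityUnit,
    PuDnaSystemParams,
    convert_diffusivity,
    default_parameter_set,
)
from .release import (
    simulate_degradation,
    simulate_first_order_release,
    simulate_higuchi_release,
)


class NoiseKind(str, enum.Enum):
    MULTIPLICATIVE_LOGNORMAL = "multiplicative_lognormal"
    ADDITIVE_GAUSSIAN = "additive_gaussian"


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise description; sigma is dimensionless for the
    multiplicative kind and in data units for the additive kind."""

    kind: NoiseKind = NoiseKind.MULTIPLICATIVE_LOGNORMAL
    sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0 (got {self.sigma})")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        eps = rng.normal(0.0, self.sigma, size=values.shape)
        if self.kind is NoiseKind.MULTIPLICATIVE_LOGNORMAL:
            return values * np.exp(eps)
        return np.clip(values + eps, 0.0, None)


@dataclass(frozen=True)
class ParameterRanges:
    """Per-parameter [low, high] sampling bounds.

    Defaults are the literature ranges for the two parameters reported
    as ranges — degradation k (10⁻³–10⁻² /h) and diffusivity D
    (10⁻¹²–10⁻¹⁰ m²/s) — with every other constant held at its default
    point value. Ranges span decades, so draws are log-uniform.
    """

    k_degradation: tuple[float, float] = (1e-3, 1e-2)
    d_m2_per_s: tuple[float, float] = (1e-12, 1e-10)

    def __post_init__(self) -> None:
        for name in ("k_degradation", "d_m2_per_s"):
            low, high = getattr(self, name)
            if not 0 < low <= high:
                raise ConfigurationError(
                    f"{name}: need 0 < low <= high (got [{low}, {high}])"
                )


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    if low == high:
        return low
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def sample_parameter_set(
    ranges: ParameterRanges | None = None, seed: int = 0
) -> PuDnaSystemParams:
    """Draw a parameter set with ranged constants sampled log-uniformly.

    Identical seeds give bitwise-identical draws.
    """
    ranges = ranges or ParameterRanges()
    rng = np.random.default_rng(seed)
    params = default_parameter_set()
    params.degradation.k = _log_uniform(rng, *ranges.k_degradation)
    d_si = _log_uniform(rng, *ranges.d_m2_per_s)
    params.higuchi.d_nm2_per_h = convert_diffusivity(
        d_si, DiffusivityUnit.M2_PER_S, DiffusivityUnit.NM2_PER_H
    )
    return params


class ForwardModel(str, enum.Enum):
    DEGRADATION = "degradation"
    RELEASE_FIRST_ORDER = "release_first_order"
    RELEASE_HIGUCHI = "release_higuchi"
    INTERNALIZATION = "internalization"


def _forward(model: ForwardModel, params: PuDnaSystemParams, grid: TimeGrid) -> TimeSeries:
    if model is ForwardModel.DEGRADATION:
        return simulate_degradation(params.degradation, grid)
    if model is ForwardModel.RELEASE_FIRST_ORDER:
        profile = simulate_first_order_release(params.release, grid)
        return TimeSeries(profile.times, profile.remaining_mass,
                          label="remaining_mg", units="mg")
    if model is ForwardModel.RELEASE_HIGUCHI:
        profile = simulate_higuchi_release(params.higuchi, grid)
        return TimeSeries(profile.times, profile.remaining_mass,
                          label="remaining_mg", units="mg")
    if model is ForwardModel.INTERNALIZATION:
        return simulate_internalization(params.uptake, grid)
    raise ConfigurationError(f"unknown forward model {model!r}")


def generate_noisy_timeseries(
    model: ForwardModel | str,
    params: PuDnaSystemParams,
    grid: TimeGrid,
    noise: NoiseModel,
    seed: int,
) -> TimeSeries:
    """Forward-simulate a model, then corrupt it pointwise with noise."""
    try:
        model = ForwardModel(model)
    except ValueError as exc:
        raise ConfigurationError(f"unknown forward model: {exc}") from exc
    clean = _forward(model, params, grid)
    rng = np.random.default_rng(seed)
    noisy = noise.apply(clean.values, rng)
    return TimeSeries(clean.times, noisy, label=clean.label, units=clean.units)


def generate_default_figure_fixtures(seed: int = 0) -> dict:
    """Noiseless default-parameter trajectories of all four models.

    Returns degradation and internalization time series, the
    first-order release profile, the Langmuir isotherm, and a manifest
    recording the seed and fully resolved parameters for provenance.
    """
    params = default_parameter_set()
    fixtures = {
        "degradation": simulate_degradation(params.degradation, DEFAULT_GRID),
        "release": simulate_first_order_release(params.release, DEFAULT_GRID),
        "isotherm": coverage_isotherm(
            params.adsorption, default_isotherm_grid(params.adsorption)
        ),
        "internalization": simulate_internalization(params.uptake, DEFAULT_GRID),
        "manifest": {
            "seed": seed,
            "noise": None,
            "grid": {"t_start": DEFAULT_GRID.t_start, "t_end": DEFAULT_GRID.t_end,
                     "n_points": DEFAULT_GRID.n_points},
            "parameters": params.to_flat_dict(),
        },
    }
    return fixtures


def write_fixture_bundle(outdir: Path, seed: int = 0) -> dict[str, Path]:
    """Write the four figure fixtures plus a provenance manifest to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = generate_default_figure_fixtures(seed)
    paths = {
        "degradation": outdir / "degradation.csv",
        "release": outdir / "release.csv",
        "isotherm": outdir / "isotherm.csv",
        "internalization": outdir / "internalization.csv",
        "manifest": outdir / "manifest.json",
    }
    fx["degradation"].to_csv(paths["degradation"])
    fx["release"].to_csv(paths["release"])
    fx["isotherm"].to_csv(paths["isotherm"])
    fx["internalization"].to_csv(paths["internalization"])
    paths["manifest"].write_text(json.dumps(fx["manifest"], indent=2, sort_keys=True))
    return paths
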
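"""Scenario configuration and report generation.

A scenario selects one or more models, applies parameter overrides on
top of the defaults, and resolves a time grid, seed and optional noise
settings. ``run_scenario`` executes it and writes per-model CSVs plus
a summary JSON whose every number is recomputable from the CSVs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cell import (
    coverage_isotherm,
    default_isotherm_grid,
    internalization_steady_state,
    simulate_internalization,
)
from .errors import ConfigurationError
from .kinetics import DEFAULT_GRID, TimeGrid
from .params import PuDnaSystemParams
from .release import (
    simulate_degradation,
    simulate_first_order_release,
    simulate_higuchi_release,
    time_to_fraction_released,
)

VALID_MODELS = (
    "degradation",
    "release_first_order",
    "release_higuchi",
    "isotherm",
    "internalization",
)

_TOP_KEYS = {"models", "parameters", "grid", "output_dir", "seed", "noise", "report"}
_GRID_KEYS = {"t_start", "t_end", "n_points"}
_NOISE_KEYS = {"kind", "sigma"}
_REPORT_KEYS = {"write_csv", "write_summary"}


@dataclass
class ScenarioConfig:
    """Fully resolved run description."""

    models: list[str] = field(default_factory=lambda: list(VALID_MODELS))
    params: PuDnaSystemParams = field(default_factory=PuDnaSystemParams)
    grid: TimeGrid = DEFAULT_GRID
    output_dir: Path = Path("pukinetics-out")
    seed: int = 0
    noise: dict | None = None
    report: dict = field(default_factory=lambda: {"write_csv": True, "write_summary": True})

    def validate(self) -> None:
        unknown = [m for m in self.models if m not in VALID_MODELS]
        if unknown:
            raise ConfigurationError(
                f"unknown model(s) {unknown}; valid: {list(VALID_MODELS)}"
            )
        bad = self.params.violations()
        if bad:
            raise ConfigurationError("invalid parameters: " + "; ".join(bad))


def parse_config(path: str | Path, overrides: dict | None = None) -> ScenarioConfig:
    """Parse a YAML scenario file; ``overrides`` (e.g. from CLI flags)
    win over file values. Unknown keys are rejected by name.

    An empty file resolves to the full default scenario.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    if overrides:
        raw = _deep_merge(raw, overrides)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ScenarioConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
    cfg = ScenarioConfig()
    if "models" in raw:
        models = raw["models"]
        cfg.models = [models] if isinstance(models, str) else list(models)
    if "parameters" in raw:
        cfg.params = PuDnaSystemParams.from_dict(raw["parameters"])
    if "grid" in raw:
        g = raw["grid"]
        bad = set(g) - _GRID_KEYS
        if bad:
            raise ConfigurationError(f"unknown grid key(s): {sorted(bad)}")
        cfg.grid = TimeGrid(
            g.get("t_start", DEFAULT_GRID.t_start),
            g.get("t_end", DEFAULT_GRID.t_end),
            g.get("n_points", DEFAULT_GRID.n_points),
        )
    if "output_dir" in raw:
        cfg.output_dir = Path(raw["output_dir"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "noise" in raw and raw["noise"] is not None:
        bad = set(raw["noise"]) - _NOISE_KEYS
        if bad:
            raise ConfigurationError(f"unknown noise key(s): {sorted(bad)}")
        cfg.noise = dict(raw["noise"])
    if "report" in raw:
        bad = set(raw["report"]) - _REPORT_KEYS
        if bad:
            raise ConfigurationError(f"unknown report key(s): {sorted(bad)}")
        cfg.report.update(raw["report"])
    cfg.validate()
    return cfg


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class ReportBundle:
    """Paths of the written artifacts plus the in-memory summary."""

    csv_paths: dict[str, Path]
    summary_path: Path | None
    summary: dict


def run_scenario(config: ScenarioConfig) -> ReportBundle:
    """Execute the selected models; write CSVs and the summary JSON.

    The summary contains the analytic scalar descriptors of each curve
    (half-lives, t₅₀, depletion time, half-saturation concentration,
    steady state), each recomputable from the written trajectory.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    csv_paths: dict[str, Path] = {}
    summary: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "models": list(config.models),
            "grid": {
                "t_start": config.grid.t_start,
                "t_end": config.grid.t_end,
                "n_points": config.grid.n_points,
            },
            "parameters": p.to_flat_dict(),
        }
    }
    write_csv = config.report.get("write_csv", True)

    def _emit(name: str, obj) -> None:
        if write_csv:
            path = outdir / f"{name}.csv"
            obj.to_csv(path)
            csv_paths[name] = path

    for model in config.models:
        if model == "degradation":
            _emit("degradation", simulate_degradation(p.degradation, config.grid))
            summary["degradation"] = {
                "half_life_h": math.log(2.0) / p.degradation.k,
                "c0_mg_per_ml": p.degradation.c0,
            }
        elif model == "release_first_order":
            _emit("release_first_order", simulate_first_order_release(p.release, config.grid))
            summary["release_first_order"] = {
                "t50_h": time_to_fraction_released(p.release, 0.5),
                "m0_effective_mg": p.release.m0_effective,
            }
        elif model == "release_higuchi":
            _emit("release_higuchi", simulate_higuchi_release(p.higuchi, config.grid))
            summary["release_higuchi"] = {
                "t50_h": time_to_fraction_released(p.higuchi, 0.5),
                "depletion_time_h": p.higuchi.depletion_time_h,
                "m0_effective_mg": p.higuchi.m0_effective,
            }
        elif model == "isotherm":
            _emit("isotherm", coverage_isotherm(
                p.adsorption, default_isotherm_grid(p.adsorption)))
            summary["isotherm"] = {
                "half_saturation_molar": 1.0 / p.adsorption.k_ads,
                "half_saturation_mg_per_ml": p.adsorption.molar_mass / p.adsorption.k_ads,
            }
        elif model == "internalization":
            _emit("internalization", simulate_internalization(p.uptake, config.grid))
            summary["internalization"] = {
                "steady_state_count": internalization_steady_state(p.uptake),
                "rise_half_time_h": math.log(2.0) / p.uptake.k_degr,
            }

    summary_path = None
    if config.report.get("write_summary", True):
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return ReportBundle(csv_paths=csv_paths, summary_path=summary_path, summary=summary)
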
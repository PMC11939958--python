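"""Parameter model for polyurethane (PU) gene-delivery kinetics.

Every physical constant the simulator uses lives here, with units,
validation, and the handful of unit conversions the models need.

Canonical internal units
------------------------
time        hours
mass        mg
mass conc.  mg/mL  (== g/L)
molar conc. mol/L
length      nm
diffusivity nm²/h  (SI m²/s accepted at the boundary and converted)

Rates are per hour; equilibrium constants are per molar.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from typing import Any

from .errors import ConfigurationError, InvalidParameterError

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23

#: nm²/h per m²/s: 1 m² = 1e18 nm², 1 s = 1/3600 h.
_NM2_PER_H_PER_M2_PER_S = 1e18 * 3600.0


class HiguchiForm(str, enum.Enum):
    """Reading of the diffusional release law.

    ``square_root`` is the classical Higuchi signature, released
    fraction ∝ √(Dt/L²); ``linear`` releases ∝ Dt/L².
    """

    SQUARE_ROOT = "square_root"
    LINEAR = "linear"


class DiffusivityUnit(str, enum.Enum):
    M2_PER_S = "m2_per_s"
    NM2_PER_H = "nm2_per_h"


@dataclass
class DegradationParams:
    """First-order hydrolytic degradation of the PU matrix, C(t) = C₀e^(−kt)."""

    k: float = 1e-2  # degradation rate constant, /h
    c0: float = 1.0  # initial PU concentration, mg/mL

    def violations(self, prefix: str = "degradation.") -> list[str]:
        out = []
        if not self.k > 0:
            out.append(f"{prefix}k must be > 0 (got {self.k})")
        if not self.c0 > 0:
            out.append(f"{prefix}c0 must be > 0 (got {self.c0})")
        return out


@dataclass
class ReleaseParams:
    """First-order release of encapsulated DNA/RNA from the PU matrix."""

    k_rel: float = 1e-3  # release rate constant, /h
    m0_nominal: float = 1.0  # loaded genetic-material mass, mg
    encapsulation_efficiency: float = 0.90  # fraction actually entrapped

    @property
    def m0_effective(self) -> float:
        """Encapsulated mass actually available for release, mg."""
        return self.encapsulation_efficiency * self.m0_nominal

    def violations(self, prefix: str = "release.") -> list[str]:
        out = []
        if not self.k_rel > 0:
            out.append(f"{prefix}k_rel must be > 0 (got {self.k_rel})")
        if not self.m0_nominal > 0:
            out.append(f"{prefix}m0_nominal must be > 0 (got {self.m0_nominal})")
        if not 0 < self.encapsulation_efficiency <= 1:
            out.append(
                f"{prefix}encapsulation_efficiency must lie in (0, 1] "
                f"(got {self.encapsulation_efficiency})"
            )
        return out


@dataclass
class HiguchiParams:
    """Diffusion-controlled release through a matrix of length L.

    ``d_nm2_per_h`` is stored in the canonical unit; use
    :func:`convert_diffusivity` or :meth:`from_si` for SI input.
    """

    d_nm2_per_h: float = 1e-12 * _NM2_PER_H_PER_M2_PER_S  # diffusion coefficient
    length_nm: float = 100.0  # matrix/diffusion length, nm
    m0_effective: float = 0.90  # encapsulated mass, mg
    form: HiguchiForm = HiguchiForm.SQUARE_ROOT

    @classmethod
    def from_si(
        cls,
        d_m2_per_s: float,
        length_nm: float = 100.0,
        m0_effective: float = 0.90,
        form: HiguchiForm = HiguchiForm.SQUARE_ROOT,
    ) -> "HiguchiParams":
        d = convert_diffusivity(
            d_m2_per_s, DiffusivityUnit.M2_PER_S, DiffusivityUnit.NM2_PER_H
        )
        return cls(d, length_nm, m0_effective, form)

    @property
    def depletion_time_h(self) -> float:
        """t* = L²/D, the time at which the matrix is fully depleted (h)."""
        return self.length_nm**2 / self.d_nm2_per_h

    def violations(self, prefix: str = "higuchi.") -> list[str]:
        out = []
        if not self.d_nm2_per_h > 0:
            out.append(f"{prefix}d_nm2_per_h must be > 0 (got {self.d_nm2_per_h})")
        if not self.length_nm > 0:
            out.append(f"{prefix}length_nm must be > 0 (got {self.length_nm})")
        if not self.m0_effective > 0:
            out.append(f"{prefix}m0_effective must be > 0 (got {self.m0_effective})")
        if not isinstance(self.form, HiguchiForm):
            out.append(f"{prefix}form must be a HiguchiForm (got {self.form!r})")
        return out


@dataclass
class AdsorptionParams:
    """Langmuir adsorption of PU nanoparticles onto the cell membrane."""

    k_ads: float = 1e6  # adsorption equilibrium constant, /M
    molar_mass: float = 5000.0  # effective molar mass for mg/mL → mol/L, g/mol

    def violations(self, prefix: str = "adsorption.") -> list[str]:
        out = []
        if not self.k_ads > 0:
            out.append(f"{prefix}k_ads must be > 0 (got {self.k_ads})")
        if not self.molar_mass > 0:
            out.append(f"{prefix}molar_mass must be > 0 (got {self.molar_mass})")
        return out


@dataclass
class UptakeParams:
    """Endocytic internalization, dN/dt = k_uptake·θ·N_max − k_degr·N."""

    k_uptake: float = 1e-2  # internalization rate, /h
    k_degr: float = 1e-3  # intracellular degradation rate, /h
    n_max: float = 1000.0  # maximum membrane binding sites, count
    theta: float = 200.0 / 201.0  # membrane coverage fraction in [0, 1)
    n0: float = 0.0  # internalized count at t = 0

    def violations(self, prefix: str = "uptake.") -> list[str]:
        out = []
        if not self.k_uptake > 0:
            out.append(f"{prefix}k_uptake must be > 0 (got {self.k_uptake})")
        if not self.k_degr > 0:
            out.append(f"{prefix}k_degr must be > 0 (got {self.k_degr})")
        if not self.n_max > 0:
            out.append(f"{prefix}n_max must be > 0 (got {self.n_max})")
        if not 0 <= self.theta < 1:
            out.append(f"{prefix}theta must lie in [0, 1) (got {self.theta})")
        if not self.n0 >= 0:
            out.append(f"{prefix}n0 must be >= 0 (got {self.n0})")
        return out


@dataclass
class PuDnaSystemParams:
    """The complete constant collection for the PU–DNA delivery system.

    ``k_bind_pu_dna`` (electrostatic PU–DNA binding constant) and
    ``dna_charge_density`` are physical descriptors of the polyplex;
    they are stored and reported for provenance but drive no dynamic
    equation in any of the four models.
    """

    degradation: DegradationParams = field(default_factory=DegradationParams)
    release: ReleaseParams = field(default_factory=ReleaseParams)
    higuchi: HiguchiParams = field(default_factory=HiguchiParams)
    adsorption: AdsorptionParams = field(default_factory=AdsorptionParams)
    uptake: UptakeParams = field(default_factory=UptakeParams)
    k_bind_pu_dna: float = 1e5  # PU–DNA binding constant, /M
    dna_charge_density: float = -1.0  # charge per base pair, e/bp

    def violations(self) -> list[str]:
        out = []
        out += self.degradation.violations()
        out += self.release.violations()
        out += self.higuchi.violations()
        out += self.adsorption.violations()
        out += self.uptake.violations()
        if not self.k_bind_pu_dna > 0:
            out.append(f"k_bind_pu_dna must be > 0 (got {self.k_bind_pu_dna})")
        return out

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """Nested plain-python dict, keyed by model then field name."""
        d = dataclasses.asdict(self)
        d["higuchi"]["form"] = self.higuchi.form.value
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PuDnaSystemParams":
        base = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter section(s): {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                kwargs[f.name] = getattr(base, f.name)
                continue
            value = data[f.name]
            sub_default = getattr(base, f.name)
            if dataclasses.is_dataclass(sub_default):
                if not isinstance(value, dict):
                    raise ConfigurationError(
                        f"section {f.name!r} must be a mapping, got {type(value).__name__}"
                    )
                sub_known = {g.name for g in dataclasses.fields(sub_default)}
                sub_unknown = set(value) - sub_known
                if sub_unknown:
                    raise ConfigurationError(
                        f"unknown key(s) in section {f.name!r}: {sorted(sub_unknown)}"
                    )
                merged = {g.name: getattr(sub_default, g.name) for g in dataclasses.fields(sub_default)}
                merged.update(value)
                if f.name == "higuchi":
                    merged["form"] = HiguchiForm(merged["form"])
                kwargs[f.name] = type(sub_default)(**merged)
            else:
                kwargs[f.name] = value
        return cls(**kwargs)

    def to_flat_dict(self) -> dict[str, float]:
        """Flat `section.field` → value mapping for JSON reports."""
        flat: dict[str, Any] = {}
        for section, content in self.to_dict().items():
            if isinstance(content, dict):
                for key, value in content.items():
                    flat[f"{section}.{key}"] = value
            else:
                flat[section] = content
        return flat

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_flat_dict(), **kwargs)


def default_parameter_set() -> PuDnaSystemParams:
    """Default constants of the PU–DNA system.

    Degradation k = 10⁻² /h (upper end of the 10⁻³–10⁻² /h literature
    range, so a ~500 h horizon shows visible decay), C₀ = 1 mg/mL;
    release k_rel = 10⁻³ /h, M₀ = 1 mg with 90% encapsulation
    efficiency; diffusivity D = 10⁻¹² m²/s through L = 100 nm;
    Langmuir K_ads = 10⁶ /M with a 5 kDa plasmid; uptake
    k_uptake = 10⁻² /h against intracellular degradation
    k_degr = 10⁻³ /h from N₀ = 0 over N_max = 1000 sites.

    The membrane coverage θ is fixed once from the extracellular
    concentration C₀ via the Langmuir isotherm:
    θ = K·C/(1 + K·C) = 200/201 at C₀ = 1 mg/mL.
    """
    return PuDnaSystemParams()


def validate(params: PuDnaSystemParams) -> list[str]:
    """All invariant violations of a parameter set; empty list means valid.

    Violations are returned as data (human-readable strings naming the
    offending field), not raised.
    """
    return params.violations()


def mass_to_molar(concentration_mg_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration (mg/mL == g/L) to mol/L."""
    if not concentration_mg_per_ml > 0:
        raise InvalidParameterError(
            f"concentration must be > 0 (got {concentration_mg_per_ml})"
        )
    if not molar_mass_g_per_mol > 0:
        raise InvalidParameterError(f"molar mass must be > 0 (got {molar_mass_g_per_mol})")
    return concentration_mg_per_ml / molar_mass_g_per_mol


def molar_to_mass(concentration_mol_per_l: float, molar_mass_g_per_mol: float) -> float:
    """Convert a molar concentration (mol/L) back to mg/mL."""
    if not concentration_mol_per_l > 0:
        raise InvalidParameterError(
            f"concentration must be > 0 (got {concentration_mol_per_l})"
        )
    if not molar_mass_g_per_mol > 0:
        raise InvalidParameterError(f"molar mass must be > 0 (got {molar_mass_g_per_mol})")
    return concentration_mol_per_l * molar_mass_g_per_mol


def convert_diffusivity(
    value: float,
    from_unit: DiffusivityUnit | str,
    to_unit: DiffusivityUnit | str,
) -> float:
    """Exact factor conversion between m²/s and nm²/h.

    1 m²/s = 10¹⁸ nm²/s = 3.6 × 10²¹ nm²/h.
    """
    if not value > 0:
        raise InvalidParameterError(f"diffusivity must be > 0 (got {value})")
    try:
        from_unit = DiffusivityUnit(from_unit)
        to_unit = DiffusivityUnit(to_unit)
    except ValueError as exc:
        raise ConfigurationError(f"unknown diffusivity unit: {exc}") from exc
    if from_unit == to_unit:
        return value
    if from_unit == DiffusivityUnit.M2_PER_S:
        return value * _NM2_PER_H_PER_M2_PER_S
    return value / _NM2_PER_H_PER_M2_PER_S


def stokes_einstein_diffusivity(
    temperature_k: float,
    viscosity_pa_s: float,
    hydrodynamic_radius_m: float,
) -> float:
    """Stokes–Einstein diffusivity D = k_B·T / (6π·η·r), in m²/s.

    For nanoparticles of 5–500 nm radius in water-like media at body
    temperature this lands in the 10⁻¹³–10⁻¹¹ m²/s decade band.
    """
    for name, value in (
        ("temperature", temperature_k),
        ("viscosity", viscosity_pa_s),
        ("hydrodynamic radius", hydrodynamic_radius_m),
    ):
        if not value > 0:
            raise InvalidParameterError(f"{name} must be > 0 (got {value})")
    return BOLTZMANN_J_PER_K * temperature_k / (6.0 * math.pi * viscosity_pa_s * hydrodynamic_radius_m)
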
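"""Parameter model: defaults, validation, and unit conversions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pukinetics import (
    HiguchiForm,
    PuDnaSystemParams,
    convert_diffusivity,
    default_parameter_set,
    mass_to_molar,
    molar_to_mass,
    stokes_einstein_diffusivity,
    validate,
)
from pukinetics.errors import ConfigurationError, InvalidParameterError


class TestDefaults:
    def test_default_constants(self, params):
        assert params.degradation.k == pytest.approx(1e-2)
        assert params.degradation.c0 == 1.0
        assert params.release.k_rel == pytest.approx(1e-3)
        assert params.release.m0_nominal == 1.0
        assert params.release.encapsulation_efficiency == 0.90
        assert params.release.m0_effective == pytest.approx(0.9)
        assert params.higuchi.length_nm == 100.0
        # D = 1e-12 m²/s in canonical nm²/h
        assert params.higuchi.d_nm2_per_h == pytest.approx(3.6e9)
        assert params.adsorption.k_ads == pytest.approx(1e6)
        assert params.adsorption.molar_mass == 5000.0
        assert params.uptake.k_uptake == pytest.approx(1e-2)
        assert params.uptake.k_degr == pytest.approx(1e-3)
        assert params.uptake.n0 == 0.0
        assert params.k_bind_pu_dna == pytest.approx(1e5)
        assert params.dna_charge_density == -1.0

    def test_defaults_are_valid(self, params):
        assert validate(params) == []

    def test_default_theta_is_langmuir_at_c0(self, params):
        # θ fixed once from C₀ = 1 mg/mL via the isotherm: KC/(1+KC) = 200/201
        assert params.uptake.theta == pytest.approx(200.0 / 201.0)


class TestValidation:
    @pytest.mark.parametrize(
        "mutate, field",
        [
            (lambda p: setattr(p.degradation, "k", -1.0), "degradation.k"),
            (lambda p: setattr(p.uptake, "theta", 1.5), "uptake.theta"),
            (lambda p: setattr(p.release, "encapsulation_efficiency", 0.0),
             "release.encapsulation_efficiency"),
            (lambda p: setattr(p, "k_bind_pu_dna", 0.0), "k_bind_pu_dna"),
        ],
    )
    def test_single_violation_names_field(self, mutate, field):
        p = default_parameter_set()
        mutate(p)
        violations = validate(p)
        assert len(violations) == 1
        assert field in violations[0]


class TestConversions:
    def test_mass_to_molar_examples(self):
        assert mass_to_molar(1.0, 5000.0) == pytest.approx(2e-4)
        assert mass_to_molar(0.5, 5000.0) == pytest.approx(1e-4)

    @given(x=st.floats(1e-6, 1e3), mm=st.floats(1.0, 1e7))
    @settings(max_examples=50, derandomize=True)
    def test_molar_round_trip(self, x, mm):
        assert molar_to_mass(mass_to_molar(x, mm), mm) == pytest.approx(x, rel=1e-12)

    def test_mass_to_molar_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            mass_to_molar(0.0, 5000.0)
        with pytest.raises(InvalidParameterError):
            mass_to_molar(1.0, -5.0)

    def test_diffusivity_conversion(self):
        assert convert_diffusivity(1e-12, "m2_per_s", "nm2_per_h") == pytest.approx(3.6e9)
        assert convert_diffusivity(3.6e9, "nm2_per_h", "m2_per_s") == pytest.approx(1e-12)
        assert convert_diffusivity(7.0, "m2_per_s", "m2_per_s") == 7.0

    @given(x=st.floats(1e-15, 1e-8))
    @settings(max_examples=50, derandomize=True)
    def test_diffusivity_round_trip(self, x):
        back = convert_diffusivity(
            convert_diffusivity(x, "m2_per_s", "nm2_per_h"), "nm2_per_h", "m2_per_s"
        )
        assert back == pytest.approx(x, rel=1e-12)

    def test_diffusivity_unknown_unit(self):
        with pytest.raises(ConfigurationError):
            convert_diffusivity(1.0, "furlongs", "nm2_per_h")


class TestStokesEinstein:
    def test_reference_value(self):
        # 50 nm radius particle in water-like medium at body temperature
        d = stokes_einstein_diffusivity(310.0, 1e-3, 5e-8)
        assert d == pytest.approx(4.54e-12, rel=1e-2)

    def test_scaling_laws(self):
        d = stokes_einstein_diffusivity(310.0, 1e-3, 5e-8)
        assert stokes_einstein_diffusivity(310.0, 1e-3, 1e-7) == pytest.approx(d / 2)
        assert stokes_einstein_diffusivity(620.0, 1e-3, 5e-8) == pytest.approx(2 * d)

    @given(r_nm=st.floats(5.0, 500.0))
    @settings(max_examples=100, derandomize=True)
    def test_nanoparticle_envelope(self, r_nm):
        # nanoparticle radii at body temperature stay in the expected decade band
        d = stokes_einstein_diffusivity(310.0, 1e-3, r_nm * 1e-9)
        assert 4.5e-13 <= d <= 4.6e-11


class TestSerialization:
    def test_dict_round_trip(self, params):
        params.higuchi.form = HiguchiForm.LINEAR
        clone = PuDnaSystemParams.from_dict(params.to_dict())
        assert clone == params

    def test_partial_dict_fills_defaults(self):
        p = PuDnaSystemParams.from_dict({"release": {"k_rel": 5e-4}})
        assert p.release.k_rel == 5e-4
        assert p.release.m0_nominal == 1.0

    def test_unknown_section_rejected(self):
        with pytest.raises(ConfigurationError, match="leakage"):
            PuDnaSystemParams.from_dict({"leakage": {}})

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigurationError, match="k_relx"):
            PuDnaSystemParams.from_dict({"release": {"k_relx": 1.0}})

    def test_flat_dict_keys(self, params):
        flat = params.to_flat_dict()
        assert flat["release.k_rel"] == pytest.approx(1e-3)
        assert flat["k_bind_pu_dna"] == pytest.approx(1e5)
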
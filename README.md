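# pukinetics

Kinetic simulation and parameter estimation for polyurethane (PU)-based
gene-delivery vectors.

Biodegradable cationic PU nanoparticles are a non-viral alternative for
delivering DNA/RNA: the polymer matrix encapsulates the nucleic acid,
degrades in the biological medium, releases its cargo, adsorbs onto the
cell membrane, and is internalized by endocytosis. `pukinetics`
implements the four deterministic models that describe this pipeline,
with literature default constants, analytic solutions as oracles for
every ODE, seeded synthetic-data generation, and inverse problems that
recover the rate constants from noisy observations.

## Models

1. **Matrix degradation** — first-order kinetics,
   C(t) = C₀·e^(−kt), with k ∈ [10⁻³, 10⁻²] h⁻¹ and C₀ = 1 mg/mL.
2. **DNA/RNA release** — either first-order, dM/dt = −k_rel·M with
   k_rel = 10⁻³ h⁻¹ and M(0) = EE·M₀ = 0.9 mg (90% encapsulation of a
   1 mg load), or the Higuchi diffusional law,
   remaining = M₀·(1 − √(Dt/L²)), with D ∈ [10⁻¹², 10⁻¹⁰] m²/s and
   matrix length L = 100 nm.
3. **Membrane adsorption** — the Langmuir isotherm
   θ = K·C/(1 + K·C) with K = 10⁶ M⁻¹; at C = 1 mg/mL of a 5 kDa
   plasmid (2 × 10⁻⁴ M) the membrane is θ = 200/201 ≈ 0.995 covered.
4. **Endocytic internalization** — dN/dt = k_uptake·θ·N_max − k_degr·N
   from N(0) = 0, with k_uptake = 10⁻² h⁻¹, k_degr = 10⁻³ h⁻¹; the
   count saturates at the uptake/degradation balance
   N_ss = k_uptake·θ·N_max/k_degr.

All ODEs are linear, so every trajectory has a closed form; the
fixed-step RK4 integrator and the closed forms cross-check each other
to relative 10⁻⁶.

## Worked example

```python
import pukinetics as pk

p = pk.default_parameter_set()

# degradation half-life at k = 1e-2 /h
import math
print(math.log(2) / p.degradation.k)        # 69.31471805599453  (hours)

# membrane coverage at the default extracellular concentration
c = pk.mass_to_molar(1.0, 5000.0)            # 0.0002  (mol/L)
print(pk.langmuir_coverage(c, 1e6))          # 0.9950248756218906

# internalization steady state
print(pk.internalization_steady_state(p.uptake))   # 9950.248756218904

# recover k_rel from seeded noisy release data
ts = pk.generate_noisy_timeseries(
    "release_first_order", p, pk.TimeGrid(0, 5000, 50),
    pk.NoiseModel(sigma=0.05), seed=1,
)
print(pk.fit_first_order_rate(ts).estimates["k"])  # 0.0010024329322370145 (true 1e-3)
```

The degradation half-life of 69.3 h and release half-time of 693 h
(ln 2/k_rel) show the intended two-timescale design: the matrix erodes
an order of magnitude faster than it releases its cargo, and the
internalized count reaches half its ~9950-vector plateau at
ln 2/k_degr ≈ 693 h.

From the shell, the `default-figures` preset runs all four default
scenarios and writes one CSV per curve plus a `summary.json` with the
analytic descriptors (half-lives, t₅₀, depletion time, half-saturation
concentration, steady state):

```sh
pu-kinetics default-figures --out figures/
pu-kinetics fit figures/degradation.csv --model first_order
```

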
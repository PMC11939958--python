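# Methods

## Models and assumptions

`pukinetics` treats the PU gene-delivery pipeline as four uncoupled
deterministic models. This mirrors how the processes are usually
presented in the controlled-release literature and keeps every
sub-model analytically solvable; it also means the package makes no
claim about feedback between stages (e.g. matrix erosion accelerating
release, or extracellular depletion lowering membrane coverage).

**Degradation.** The PU concentration follows first-order kinetics,
dC/dt = −k·C, C(0) = C₀. Assumption: hydrolysis is surface- and
autocatalysis-free, so the rate is proportional to the remaining
material. Half-life ln 2/k.

**Release, first-order.** The encapsulated mass obeys dM/dt = −k_rel·M
with M(0) = EE·M₀, where the encapsulation efficiency EE discounts the
nominal load for material never entrapped. The released mass is the
complement, so remaining + released = EE·M₀ identically (conservation
is enforced as a container invariant at relative 10⁻⁹).

**Release, Higuchi diffusional.** With τ = Dt/L², the remaining
fraction is 1 − √τ (square-root form, the classical diffusion-control
signature) or 1 − τ (linear form, selectable). Both deplete the matrix
exactly at t\* = L²/D and are clamped at zero afterwards, because the
law is undefined past depletion. The square-root form is the default.

**Adsorption.** Equilibrium Langmuir isotherm θ = K·C/(1 + K·C):
a finite population of independent, identical binding sites, no
lateral interactions, adsorption fast relative to uptake. θ < 1 for
any finite concentration; half-saturation at C = 1/K.

**Internalization.** dN/dt = k_uptake·θ·N_max − k_degr·N from N₀ = 0.
The influx term is the occupied-site pool θ·N_max drained at k_uptake;
the sink is intracellular degradation. θ is computed once from the
extracellular concentration and held constant (no depletion feedback),
and N is continuous — a deterministic mean-field treatment, not a
stochastic count process. The trajectory is the linear relaxation
N(t) = N_ss·(1 − e^(−k_degr·t)) with N_ss = k_uptake·θ·N_max/k_degr.

## Default parameters

| symbol | meaning | default | unit | note |
|---|---|---|---|---|
| k | PU degradation rate | 10⁻² | h⁻¹ | upper end of the 10⁻³–10⁻² literature range, so a 500 h window shows visible decay; the range is exposed for sweeps |
| C₀ | initial PU concentration | 1 | mg/mL | typical drug-delivery loading |
| k_rel | release rate | 10⁻³ | h⁻¹ | sustained release, half-time ≈ 693 h |
| M₀ | nominal DNA/RNA load | 1 | mg | |
| EE | encapsulation efficiency | 0.90 | – | |
| D | diffusivity through the matrix | 10⁻¹² m²/s (= 3.6×10⁹ nm²/h) | | lower end of the Stokes–Einstein estimate for nanoparticle-scale species |
| L | matrix diffusion length | 100 | nm | typical PU nanoparticle size |
| K_ads | membrane adsorption constant | 10⁶ | M⁻¹ | |
| M_w | plasmid molar mass | 5000 | g/mol | converts mg/mL to molarity |
| k_uptake | internalization rate | 10⁻² | h⁻¹ | |
| k_degr | intracellular degradation rate | 10⁻³ | h⁻¹ | |
| N_max | membrane binding sites | 1000 | count | no literature value; any positive count only rescales the curve, so a round number is used |
| θ | membrane coverage | 200/201 | – | computed once from C₀, M_w and K_ads via the isotherm |
| N₀ | initial internalized count | 0 | count | |
| K_bind | PU–DNA binding constant | 10⁵ | M⁻¹ | stored for provenance; no governing equation uses it |
| σ_DNA | DNA charge density | −1 | e/bp | stored for provenance only |

Canonical internal units are hours, mg, mg/mL, mol/L and nm; SI
diffusivities are converted at the boundary (1 m²/s = 3.6×10²¹ nm²/h).
One canonical system avoids silent mixed-unit errors.

### A note on timescales

The printed diffusivity range combined with L = 100 nm implies a
Higuchi depletion time t\* = L²/D of ~10 ms — wildly faster than the
first-order release half-time of ~29 days. The two release models
therefore describe different physical limits rather than the same
experiment; the package reports t\* explicitly so users see the
implied timescale, and accepts D in either m²/s or nm²/h.

## Numerics

The integrator is classical fixed-step 4th-order Runge–Kutta with the
step equal to the grid spacing. All models here are linear and
non-stiff at the default constants, so adaptivity buys nothing; the
measured convergence order on the decay problem is ≈ 4.3 (slightly
super-quartic at coarse steps, approaching 4 asymptotically), and at
1 h steps the numeric route agrees with the closed forms to better
than relative 10⁻⁹. A non-finite state aborts integration with an
error naming the failure time. The default reporting grid is
[0, 500 h] at 1 h resolution, which shows the knee of every default
curve; quantities measured by curve-crossing in the acceptance script
use finer grids (10⁴–5×10⁴ points) purely to make interpolation error
negligible next to the analytic values.

## Estimation

All fitters minimise squared error — no likelihood is assumed beyond
that.

* **First-order rate**: ordinary least squares on log-transformed
  values (log y is linear in t). Closed-form, deterministic, exact on
  clean data. A fitted decay of less than 10⁻¹⁰ over the observation
  window is reported at the k = 0 boundary with `converged = False`.
* **Langmuir K**: nonlinear least squares, initialised from the
  reciprocal linearisation 1/θ − 1 = 1/(K·C) fitted through the
  origin. A coverage RMSE above 0.05 flags model misfit (e.g. a
  non-saturating linear response).
* **Internalization (k_uptake, k_degr)**: nonlinear least squares on
  the relaxation closed form with θ, N_max, N₀ known; initialised from
  the early-time slope (→ source term) and late-time plateau
  (→ source/k_degr). If the data window ends before 1/k̂_degr the fit
  carries an identifiability warning: without the saturation knee the
  two rates are only jointly constrained through their ratio.

Recovery tolerances quoted in the test suite were frozen after a
Monte-Carlo calibration at the synthetic-data module's default noise
levels: with 5% multiplicative noise and 50 points, the degradation
rate is recovered within 10% and both internalization rates within
15% in ≥ 95 of 100 seeds; with 0.02 additive coverage noise and 30
log-spaced concentrations, K is recovered within 15% likewise. The
internalization recovery series span [0, 3000 h] (≈ 3/k_degr) because
both rates are identifiable only when the data cover the knee.

## Synthetic data

The generator emulates proportional assay error on positive
quantities (multiplicative lognormal, default σ = 0.05 — masses,
concentrations, counts) and absolute error on fractions (additive
Gaussian clipped to ≥ 0, default σ = 0.02 — coverage). Ranged
constants (k, D) are drawn log-uniformly, since their literature
ranges span decades and uniform draws would over-weight the top
decade. Everything is seeded through `numpy.random.default_rng` and
bitwise reproducible.

What it does **not** emulate: baseline drift, detection limits,
censoring, heteroscedasticity beyond the two families above, or any
biological variability between cells. Passing recovery tests
therefore demonstrate the inverse problems are well-posed under
idealised noise — not that the constants are recoverable from a real
release assay.

## Design choices

* The typographically ambiguous diffusional release law is read as the
  square-root-of-time form by default (the signature of
  diffusion-controlled release); the linear reading stays available
  behind the `form` switch.
* The exponential-release scenario in the figure preset uses the
  first-order model: an exponential mass decrease is exactly what that
  model produces and what the square-root law cannot.
* K_bind (PU–DNA) and the DNA charge density are carried in the
  parameter set and reports but drive no dynamics — no governing
  equation exists for them here; electrostatic polyplex formation is
  out of scope.
* Degradation and release are not coupled; erosion-dependent release
  would require a model neither implemented nor parameterised here.
* CSV and JSON are the canonical outputs; plots are intentionally not
  part of the pipeline so results stay diffable and machine-checkable.

## Limitations

Deterministic, uncoupled, constant-coefficient models with constant θ;
no pH/temperature dependence of any constant; no burst release,
stimuli-responsive terms, receptor-mediated targeting, endosomal
escape, or intracellular trafficking. N_max is a free scale with no
literature value. The models are screening-level descriptions of a
delivery system's kinetics, not validated predictions of any specific
formulation.
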
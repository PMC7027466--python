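# Methods

## Model family

All discrete-time models share one update skeleton. Writing
`f_i(N) = R_i N_i / (1 + Σ_j α_ij N_j)` for the Beverton–Holt expectation
(the single-species model is the S = 1 case), the four variants are

| variant | update |
|---|---|
| deterministic | `N' = f(N)` |
| demographic | `N' ~ Poisson(f(N))` |
| environmental | `N' = f(N) + N ζ σ_t` |
| both | `N' ~ Poisson(max(f(N) + N ζ σ_t, 0))` |

with σ an AR(1) process `σ_t = a σ_{t−1} + b φ_t`, `σ_0 = 0`,
`φ_t ~ N(0,1)`, `b = (1 − a²)^0.5`. The innovation scale is tied to the
autocorrelation so the stationary variance `b²/(1 − a²)` equals 1 for every
|a| < 1 — comparisons across noise colours change only the temporal
structure of the environment, never its marginal magnitude. At a = ±1 the
series is identically zero (b = 0, σ_0 = 0).

The seed-bank annual plant replaces the skeleton by
`N_i' = N_i s_i (1 − g_{i,t}) + g_{i,t} f_i(N)` with seed survival
s_i ∈ [0,1] and germination `g_{i,t} = clip(g_i + ζ_i σ_{i,t}, 0, 1)`
(constant g_i in the deterministic variant). It supports the deterministic
and environmental variants only; the model is defined without Poisson
sampling. Competition acts on total seed abundance N_j, not on germinated
density g_j N_j; the germinated-density alternative
(`Σ_j α_ij g_{j,t} N_{j,t}`) is biologically defensible but changes the
strength of competition by roughly the mean germination fraction, and is
deliberately not implemented to keep one unambiguous convention.

An overcompensatory alternative to the Beverton–Holt map is provided as a
fixed-point-matched Ricker map `N exp(r (1 − N/K))` with `r = ln R` and
`K = (R − 1)/α`, so switching `density_form` changes the compensation type
while holding the equilibrium fixed and comparisons isolate
over- vs compensation. It is defined for S = 1 only.

## Modelling conventions

- **Extinction rule.** After every update, in every variant, any abundance
  below 1 is set to 0; zero is absorbing. The rule also applies to the
  initial state. It makes real-valued (environmental-only) and
  integer-valued (Poisson) trajectories comparable, and alpha diversity
  uses the same one-individual cutoff.
- **Noise timing.** The update from t to t+1 uses σ_t. Because σ_0 = 0,
  the first environmental update is noise-free; over the horizons used
  (T ≥ 40) this has no practical effect.
- **Negative expectations.** A strongly negative environmental term can
  push the expectation below zero; it is clamped to 0 before Poisson
  sampling (total reproductive failure) and the environmental-only variant
  floors the state at 0. Clamping is the minimal intervention preserving
  non-negativity.
- **Synchronous updates.** All species step from the time-t state; there
  is no sequential updating, so species ordering never matters.
- **Cross-species noise.** Each species has its own independent AR(1)
  stream (species respond to different underlying environmental drivers).
  An optional uniform cross-correlation ρ mixes in a shared stream as
  `√ρ · common + √(1−ρ) · own`, which preserves the AR(1) structure and
  unit variance; the default is ρ = 0.

## Random numbers

Every stream is a pure function of a root seed and a small tag path, via
`numpy.random.SeedSequence(entropy=seed, spawn_key=tags)`: tag 0·i is
species i's noise stream, tag 1 the Poisson stream, tag 2 the scenario
parameter stream. Replicate seeds are the root SeedSequence's generated
words. Consequences: re-running any scenario with the same root seed is
bitwise identical; all variants of a scenario share parameter draws and
noise histories (common random numbers), so variant contrasts are paired;
and the S = 1 community reproduces the population engine bitwise because
they are the same engine.

Scenario parameters given as distributions (e.g. `R ~ Uniform(2, 2.5)`)
are realised **once per root seed** and shared across replicates and
variants. The ensemble distribution at a snapshot then measures the spread
generated by stochastic dynamics alone, which is what the variant and
treatment contrasts isolate; redrawing parameters every replicate would
confound that spread with parameter uncertainty (measurably, it inflates
the niche arm's diversity variance enough to mask the niche-vs-neutral
contrast). The neutral community arm uses the distribution means
(R = 2.25, α = 0.0035 for all pairs including the diagonal) rather than
the realised niche means; the two coincide up to O(1/√(number of draws)).

## Predator–prey system

The transient-dynamics demonstration uses the Rosenzweig–MacArthur system
with a Holling type-II response,

```
dN/dt = r N (1 − N/K) − c N P / (h + N)
dP/dt = e c N P / (h + N) − m P,
```

chosen as the canonical consumer–resource model exhibiting the target
phenomena: damped transient cycles around a stable focus, quasi-cycles
sustained by noise, and a prey-only saddle at (K, 0) that stochastic
trajectories visit. Defaults r = 1, K = 10, c = 1, h = 2, e = 0.5,
m = 0.34 put the coexistence equilibrium at N* = 4.25, P* ≈ 3.59 with
eigenvalues −0.017 ± 0.25i: a *weakly* damped focus, selected by linear
stability analysis because quasi-cycle sustenance requires damping weak
relative to the forcing (with m = 0.35 the damping, Re λ ≈ −0.047, is
strong enough that ζ = 0.2 forcing no longer maintains half the initial
amplitude in most runs). Oscillation period ≈ 25 time units; over the
400-unit default horizon the deterministic amplitude decays by three
orders of magnitude.

Numerics: fixed-step RK4 with dt = 0.01 (halving the step changes the
trajectory by < 10⁻⁶ over 100 time units); environmental noise multiplies
the prey growth rate by (1 + ζ σ_t) with one AR(1) value per unit time
interval, frozen across the 100 RK4 substeps of that interval — the
environment varies more slowly than the integrator step. States are
floored at 0 after each substep. With ζ = 0 the stochastic code path is
bitwise identical to the deterministic one.

## Defaults and scenario sizes

- Population initial condition: the carrying capacity (R − 1)/α rounded to
  the nearest integer; community initial condition: 50 individuals per
  species. Both overridable.
- Burn-in: 0 for diversity snapshots (measured from initialization),
  100 steps for correlation and CV metrics.
- Built-in scenarios default to 200 replicates, a desk-scale ensemble that
  still resolves the documented contrasts; any replicate count is one
  argument away (`run_scenario(..., n_reps=1000)`).
- Problem sizes used by `scripts/acceptance.py`: 10⁵ steps for noise
  calibration, 10⁵ one-step draws for the conditional-mean oracle,
  500 replicates × 500 steps for the extinction contrast, 200 replicates
  for each community/seed-bank/correlation scenario, 100 seeds × 400 time
  units for the predator–prey ensemble.
- Replicates whose lag-1 correlation is undefined (extinct and therefore
  constant after the burn-in; about 10% at the white/red comparison's
  parameters) are recorded as NaN and excluded from paired comparisons and
  moments.

## What the ensembles do and do not show

The simulations are synthetic throughout: parameters are either the
documented reference values or drawn from stated distributions, and the
only data-like features emulated are Poisson demographic noise, Gaussian
AR(1) environmental forcing, and an optional observation-error overlay
(Gaussian or Poisson resampling of the recorded states). Real community
time series additionally contain features outside this family — non-Gaussian
and non-stationary environments, correlated species responses (ρ > 0 is
exposed but defaults off), size or age structure, immigration, and
interaction strengths that vary in time. Passing tests therefore certify
the internal logic and the documented qualitative orderings of this model
family, not predictions for any empirical system.

## Known limitations

- The Ricker variant is single-species; no multispecies overcompensatory
  engine is provided.
- The seed-bank model has no demographic-stochasticity variant, matching
  its definition.
- Alpha diversity is the only richness measure; evenness, beta and gamma
  diversity are out of scope.
- The predator–prey system supports environmental noise on prey growth
  only; demographic stochasticity and chaotic regimes are out of scope.
- Extinction is a hard threshold at one individual; rescue by immigration
  or fractional survival below the threshold is not modelled.
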
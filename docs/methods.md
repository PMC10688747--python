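# Methods

## The dynamical system

The pipeline treats a society's trajectory as a discrete-time system
with two endogenous variables — population level N (an SPD proxy, so a
*relative* measure on an arbitrary scale) and warfare intensity W (an
ordinal 0–6 defensive-settlement index) — forced by an exogenous
hydroclimate proxy C (lithic %, ~25–50 on the scale used here).  All
six candidate maps are multiplicative, `X_t = X_{t−1}·exp(rate)`, which
keeps states positive and makes the log growth rate the natural
regression response.  Time steps are 25 years: coarse enough to strip
high-frequency noise from SPD curves, fine enough to resolve
multi-century booms and busts.

Assumptions worth stating plainly:

* forcings act with a one-step (25-year) lag — every map uses values at
  t−1 to produce t;
* climate is exogenous (population and warfare do not feed back on C);
* the carrying capacity k is constant except for the climate/warfare
  terms inside the density-dependence bracket ("lateral
  perturbations", which shift the equilibrium rather than the maximum
  growth rate);
* observation error is multiplicative and stateless; the dynamics
  themselves are deterministic.

The warfare-mortality model is implemented with −β·W inside the
exponent (on the rate scale).  The typeset form of that model can also
be read as subtracting β·W from the whole map; because the fits work on
log rates, the rate-scale reading is the one that keeps the regression
well-defined, and the alternative is available behind the
`beta_outside` flag of `step`/`simulate_trajectory` for anyone who
wants to compare.

## Preprocessing

* **Smoothing.**  Penalized cubic smoothing splines with the penalized
  least-squares objective Σ(yᵢ−g(xᵢ))² + λ∫g″², abscissae rescaled to
  [0, 1].  The smoothing level is expressed as spar ∈ [0, 1] through
  the documented monotone map λ(spar) = 256^(3·spar−1): spar 0 is near
  interpolation, spar 1 near a linear fit.  spar is a software-specific
  convention, so cross-package numeric equality is not a goal;
  monotonicity of the residual sum of squares in spar, and exactness on
  constant/linear series, are the tested contracts.  The solver
  detrends linearly before the solve (linear functions are in the
  penalty's null space, so this changes nothing mathematically but
  keeps the system well-conditioned at large λ).  Series of exactly 4
  points use a direct natural-spline solve of the same objective;
  fewer than 4 points are rejected.
* **Warfare encoding.**  Period-coded ordinal values become an annual
  step function; a period owns its start year and excludes its end year
  (half-open), so boundary years are never double-counted.  Period
  boundaries are a user-supplied chronology table, not package
  constants.  Smoothing may overshoot the ordinal range; values are
  clipped back into [0, 6].
* **Resampling.**  Linear interpolation onto the uniform grid; the
  sources are already smoothed, so higher-order interpolation would add
  nothing testable.
* **Rates.**  log X_t − log X_{t−1}, stamped at t so the rate pairs
  with predictors at t−1.  A configurable floor ε (default 0.1) is
  added to W before any log transform, because the raw index is
  legitimately 0 in peaceful periods; the floor is logged when applied.

## Fitting

Nonlinear least squares on the rate scale.  r_N, k, λ, μ are fitted as
logarithms (soft positivity); α, β, γ, ψ are unbounded.  The optimizer
is Levenberg–Marquardt with ftol = xtol = gtol = 1e−10 and at most 10⁴
evaluations.

Every variant's rate is linear in a transformed coefficient vector
(e.g. r = a + b·N + c·C with a = r_N, b = −r_N/k, c = r_N·α), so
ordinary least squares on that design gives the *global* optimum
whenever its back-transform respects the positivity constraints.  The
multistart policy therefore runs the analytic start first and accepts
it when valid; otherwise it runs a projected version of it plus a
coarse grid spanning r_N ∈ [0.05, 1], k ∈ (0.5–2)·max(N), signed
coefficients ±{0.01, 1} and λ, μ grids scaled to the data, with a
per-start evaluation cap, a patience rule (stop after 6 consecutive
non-improving starts), and a full-tolerance polish of the winner.  The
record of starts tried and an honest convergence flag live on the
`FitResult`.

Collinear designs (e.g. a constant climate column against the
intercept) are detected by a rank check and flagged in
`FitResult.warnings`; under constant climate α is unidentifiable, which
is why the recovery benchmarks for climate-bearing variants use AR(1)
climate.

## Comparison and validation

* **BIC** = n·ln(RSS/n) + p·ln(n), Gaussian likelihood with the
  additive constant n·ln(2π)+n dropped — only differences between
  models fitted to the same response matter.  p counts the free
  dynamical parameters (the error variance is profile-maximized and
  common to all candidates).  RSS ≤ 1e−20 is a perfect fit to machine
  precision (it arises only on noise-free synthetic data); BIC then
  degenerates, is reported as −inf with a warning, and ties at −inf are
  broken by parsimony, then by σ².  The same (BIC, fewer parameters,
  higher σ²) ordering breaks exact ties everywhere.
* **R²** = 1 − RSS/TSS of the rate response.
* **σ² (coefficient of prediction)** is computed on *total
  trajectories*: the fitted map is iterated from the first observed
  value with observed exogenous covariates, never re-anchored, and the
  simulated series is scored against the observed one.  This punishes
  models whose one-step rates fit well but whose dynamics drift — the
  climate-only model on warfare-driven data scores *negative* σ²
  (worse than the mean) despite a respectable rate-scale R².  A
  diverging simulation yields σ² = −inf plus a warning flag rather than
  an exception.
* Trajectory figures can carry a 95% pointwise band from a parametric
  bootstrap: parameters perturbed multiplicatively (lognormal, relative
  sd 0.05 by default) and trajectories re-simulated.  This is a
  pragmatic uncertainty display chosen here — not a formal confidence
  procedure — and is labelled as such.

Numerical guards: rates beyond ±50 are clipped with a warning (exp
overflow under extreme trial parameters during optimization); simulated
states beyond 1e12 raise a divergence error naming the step; the
population-pressure ratio N/C refuses C at or below 1e−9.

## Synthetic data

The generator iterates a chosen population-map/warfare-map pair under a
configurable climate process (constant, linear trend, stationary AR(1),
or a regime shift emulating a multicentennial switch in mean
hydroclimate state) and applies multiplicative lognormal observation
noise to N and W.  That noise model keeps proxies positive and puts
additive Gaussian noise on the log rates, so the least-squares error
model is well-specified on synthetic data — a deliberate choice, since
the implicit error structure of real SPD/ordinal proxies is unknown.
The latent trajectories use a noise-independent substream: changing the
noise sd cannot move the truth.  Identical scenario + seed is
bit-identical.

Default study conditions: 36 steps of 25 years starting AD 50 (the
northern-area window AD 50–925); the southern-like preset uses 40 steps
(AD 250–1225).  Climate defaults to mean 35, sd 6, ρ = 0.7 on the
lithic-% scale; observation noise defaults to 1%.  Presets:

* `northern_like` — climate-driven: `pop_climate` (r_N 0.3, k 1,
  α 0.012 per lithic-%) coupled to `war_additive_climate` (λ 0.15,
  μ 0.2, ψ 0.004).  Population rides the climate-shifted equilibrium;
  warfare tracks population and climate but does not feed back.
* `southern_like` — warfare-driven: `pop_warfare` (r_N 0.3, k 4,
  β 0.35) coupled to `war_pressure` (λ 30, μ 0.22).  Density dependence
  is deliberately weak (the population peaks well below k), so the bust
  is caused by warfare — mirroring a series where warfare trends upward
  through the collapse rather than oscillating with it.
* `boom_bust` — `pop_climate_warfare` (γ −0.35) with `war_basic`
  under constant climate: a clean single-peak rise-and-fall in N with W
  rising monotonically through the decline.  Climate is constant here
  because the preset's defining property is the endogenous
  population–warfare shape; note α is unidentifiable under constant
  climate (confounded with the intercept), so recovery benchmarks for
  that variant switch the preset to AR(1) climate.

What the generator does *not* emulate: radiocarbon calibration wiggles
and measurement error, taphonomic loss, the binning/rolling-mean steps
upstream of an SPD, or spatial heterogeneity within an area.  Passing
tests therefore demonstrate that the estimation and selection machinery
is correct and well-calibrated when its assumptions hold — not that
real proxy series satisfy those assumptions.

## Benchmark problem sizes

The recovery benchmark runs 200 replicates at the 36-step study length
with 1% noise (median relative error of r_N and k ≈ 2.5%); the
selection benchmark runs 100 replicates per generating variant
(climate-driven vs warfare-driven, both selected correctly in 100% of
replicates at these settings); the consistency-in-n property is checked
at 36 vs 200 steps with 5% noise.  These sizes were chosen so the whole
suite stays interactive on a single CPU while leaving the conclusions
far from their thresholds.

## Known limitations

* SPD units are arbitrary, so k is only meaningful relative to the
  proxy's scale; no rescaling is applied before fitting.
* Smoothed series are autocorrelated; BIC and R² on the rate scale do
  not correct for that, which is precisely why total-trajectory σ² is
  carried alongside them.
* The climate sign convention is deliberately agnostic: high lithic-%
  means a wetter coast but a drier highland, and α/ψ absorb the
  direction for a given area.
* The coupled simulation mode (both N and W endogenous) exists for
  generation and exploration; validation runs each fitted model with
  *observed* covariates, the default throughout.
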
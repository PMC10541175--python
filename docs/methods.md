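# Methods

This note documents the model, the numerical choices, and what the
synthetic experiments do and do not establish.

## Network model

The expansion layer is `h = φ(J_eff x − θ)^p` with `φ(u) = max(u, 0)`
and `J_eff = J A` (M×D). Variants:

- **Dense Gaussian** — with orthonormal embedding columns and i.i.d.
  Gaussian J, the product `J A` is itself i.i.d. Gaussian, so `J_eff`
  is sampled directly as an M×D Gaussian matrix without materializing
  the M×N weight matrix. This is exact in distribution, and results for
  this variant do not depend on N or K.
- **Sparse excitatory** — each expansion unit receives exactly K
  excitatory connections at uniformly random positions, with weight 1
  (homogeneous) or |N(0,1)| (heterogeneous; a unit truncated normal,
  i.e. a standard normal conditioned on nonnegativity). Global
  feedforward inhibition subtracts the grand mean of the excitatory
  matrix from every entry, balancing excitation exactly (total weight
  sums to zero). `J_eff` is assembled as `J_E A` minus a rank-one
  correction, never densifying `J_E`.
- **Clustered input layer** — the embedding is a 0/1 block matrix
  (each input neuron encodes one task variable; D must divide N). As
  shared-threshold rectification leaves clustered codes with wildly
  uneven per-pattern activity, these networks instead pin the coding
  level per pattern by winner-take-all inhibition: the top ⌈fM⌉ units per
  pattern keep `preactivation − cutoff`, where the cutoff is the
  largest excluded preactivation (the per-pattern minimum when all
  units are selected) and ties break toward the lowest neuron index.
- **Direct-input tasks** (VOR) bypass the embedding: `J_eff = J`, an
  M×N dense Gaussian over the N = 24 mossy-fiber channels.

**Threshold calibration.** θ is the empirical (1−f) quantile of
preactivations pooled over all neurons and calibration patterns (the
training inputs). Pools beyond 2×10⁶ values are randomly subsampled;
the measured coding level on held-out patterns is within 0.01 of the
target (tested). For dense Gaussian weights and unit-norm inputs the
pooled quantile converges to Φ⁻¹(1−f), which serves as an independent
oracle in tests. Activity counts use strict positivity (h > 0),
consistent with rectification.

**Dimension.** The participation ratio (Σλ)²/Σλ² of the neuron-by-
neuron covariance is evaluated through the smaller of the two Gram
matrices of centered activity, which shares its nonzero spectrum with
the covariance; this makes M = 10⁴-unit estimates cheap. Estimates use
~1.5×10³ patterns; the suite checks the estimator against direct
eigendecomposition and its equal-eigenvalue limit.

## Tasks (the synthetic data and what it emulates)

- **Random categorization** (P associations, dimension D, noise ε):
  training inputs are i.i.d. N(0, 1/D); labels ±1 equiprobable; each
  training pattern gets exactly one test copy
  `√(1−ε²)x + ε·N(0, I/D)` with the same label. This emulates
  stimulus-discrimination learning (e.g. odor categorization); it does
  not model stimulus correlations or class imbalance.
- **Gaussian-process targets** (length scale γ): inputs uniform on the
  unit sphere (normalized Gaussians; zero vectors resampled), targets
  one joint GP draw with covariance `exp(−‖x−x′‖²/2γ²)` over the union
  of train and test points (Cholesky with diagonal jitter starting at
  1e-10, escalating ×10 at most 3 times). γ interpolates between
  quickly varying (categorization-like) and slowly varying (smooth
  motor-like) maps.
- **Two-joint arm forward model**: planar two-segment arm with inertia
  matrix M(θ) and Coriolis/friction matrix C(θ, θ̇) at the printed
  physical parameters; the coupling terms consistently use the
  lower-arm center of mass l̄₂, which makes the inertia matrix
  symmetric and conserves kinetic energy in the frictionless, unforced
  case (tested). Dynamics are integrated by fixed-step RK4 with
  dt = 1 ms over the δ = 0.2 s horizon (step-halving changes the hand
  displacement by < 1e-6 m); torques are constant over the horizon.
  Inputs are 6-D Gaussian state/torque vectors (σθ = σθ̇ = 0.1,
  σu = 1, read as standard deviations; samples are normalized to unit
  length so only the ratios matter), angles offset by π/4; the 2-D
  target is the Cartesian hand displacement. Test patterns are fresh
  draws. No gravity, muscles, or temporal basis functions.
- **VOR adaptation**: head velocities uniform on [−1, 1]; 24
  exponential mossy-fiber tuning curves `g·exp(vr) + b` (g on 6 points
  in [0.1, 1], r ∈ {−1, 1}, b ∈ {0, 1}); a battery of 25
  piecewise-linear Purkinje targets (slope pairs on a 5-point grid over
  [−2, 2], intercept 0.1, breakpoint −0.2). 100 points are sampled; a
  random 30 train, the remaining 70 test; errors average across the
  battery.

All generators are bit-reproducible from (parameters, seed) and
serialize to a CSV-per-table container with a JSON metadata block
(lossless round trip, tested to 1e-15).

## Readouts

- **Least squares**: minimum-norm solution; computed in the P×P Gram
  form when M > P (identical to the pseudo-inverse, tested to 1e-6).
- **Ridge**: penalty `M·α‖w‖²` (scaling with layer size keeps α
  comparable across widths); dual form for M > P.
- **Nonnegative with free bias**: `min_{w≥0,b} ½‖Hᵀw + b − y‖² +
  ½λ‖w‖²` with λ = 1e-2 · mean(H²) by default. The ridge is a
  robustness prior — it corresponds to penalizing sensitivity to ~10%
  relative activity noise — and is scientifically necessary here: for
  M ≫ P the ridgeless optimum is a degenerate face of interpolating
  solutions, and the fraction of silent (exactly zero) weights would
  be an artifact of solver internals (measured range 0.05–0.996 across
  compliant solvers). At the default, the solution has the rectified
  dual form `w = (Hα)₊` — a Purkinje weight distribution with a delta
  at zero — giving a silent fraction near 0.5 for smooth targets and
  higher for random categorization. Solved exactly by a semismooth
  Newton iteration on the (P+1)-dimensional dual KKT system (active
  sets are exact; KKT residuals < 1e-8, tested), with a projected
  L-BFGS-B fallback.
- **Online climbing-fiber rule**: Δw = η·c·h with error signal
  c = f(x) − ŵ·h(x), patterns shuffled every epoch, weights initialized
  at zero, no clipping or decay. At the default operating point
  (P = 30, M = 10⁴, η = 0.7/M, 2×10⁴ epochs) it reaches a test error
  within 1% of the closed-form least-squares readout (tested with a
  20% band).

Errors: fraction of sign errors for categorical targets (sign(0) → +1,
fixed), relative mean squared error `E[(f−f̂)²]/E[f²]` for continuous
targets, averaged across target dimensions for multi-output tasks.

## Kernel and spectral theory

`K(ρ) = E[(u−θ)₊^p (v−θ)₊^p]` is evaluated by conditioning on u — the
inner expectation `E[(v−θ)₊^p | u]` has a closed form via the Gaussian
truncated-power recursion — followed by composite Gauss–Legendre
quadrature over u on [θ, θ+13] (960 nodes; the integrand is smooth
there and carries a Gaussian density, so the truncated tail and the
quadrature error are both below ~1e-13, and the whole ρ-grid is
evaluated as one vectorized broadcast); ρ = 1 is fully closed-form. This is markedly more accurate near the
rectification kink than tensor Gauss–Hermite quadrature; at θ = 0 it
agrees with the closed-form arc-cosine expression to machine precision,
and a 10⁷-sample Monte-Carlo oracle validates nonzero thresholds
(tested).

Eigenvalues on the sphere use the Funk–Hecke reduction
`λ_k ∝ ∫ K(t) P_{k,D}(t) (1−t²)^{(D−3)/2} dt` with Gegenbauer
polynomials normalized to P(1) = 1 (Legendre at D = 3, Chebyshev at
D = 2 with Chebyshev–Gauss nodes for the endpoint-singular weight;
Gauss–Legendre with the weight folded into the integrand otherwise).
Node counts double until the spectrum is stable to 1e-10 (relative).
Everything is stated in the convention of harmonics orthonormal under
the uniform *probability* measure, so the trace identity reads
`Σ_k N(D,k) λ_k = K(1)` (held to < 1%, tested). Truncation defaults
(k_max = 60 at D = 3, 25 at D = 6) capture ≥ 99% of the trace;
doubling k_max moves predictions by < 1%. GP target spectra reuse the
same machinery on `C(t) = exp(−(1−t)/γ²)`; the expected squared
coefficient per mode equals the covariance eigenvalue. Empirical
target spectra use the addition theorem on off-diagonal sample pairs.

**Generalization predictor.** The error formula uses the standard
self-consistent (expected-case) spectral theory of kernel ridge
regression: κ solves `κ = ridge + κ Σ_α λ_α/(Pλ_α + κ)` by bracketed
Brent root-finding (sums are degeneracy-weighted over modes), the
variance factor is `1/(1−γ_v)` with `γ_v = Σ_α Pλ_α²/(Pλ_α+κ)²`, and
the per-mode error constants are C₂ = κ/P, C₁ = C₂²/(1−γ_v).
Ridgeless predictions use a jitter of 1e-9·K(1) (sensitivity < 1%,
tested). `γ_v ≥ 1` is reported as a divergence (interpolation-threshold
pathology) rather than silently clipped.

**Accuracy caveat (important).** The predictor was validated against a
Monte-Carlo simulation of its own idealized setting — i.i.d. Gaussian
eigenfunction designs with the same spectra — where it is accurate to a
few percent at P ∈ {10, 30, 100}. Against the *actual* model (uniform
sphere inputs at D = 3, whose eigenfunctions are spherical harmonics
with block-degenerate eigenvalues), the expected-case theory is
systematically optimistic for ridgeless interpolation: simulated errors
run ~1.5× the prediction at P = 10 and up to ~5× at P = 100 for smooth
GP targets, a genuine breakdown of the Gaussian-universality assumption
confirmed with an independent coefficient-space simulation using exact
real spherical harmonics. The theory's *comparative* statements — the
ordering of modes, the coding-level dependence of the spectrum, the
task-dependence of optima, monotone improvement with P — are all
reproduced; point-value agreement at the few-percent level is not, and
the corresponding acceptance check is left failing by design rather
than loosened.

## Experiments module

Coding-level sweeps share one network and preactivation per replicate
and move only the threshold (or the winner-take-all fraction) across
the f grid — the coding level is a thresholding knob, not a new
network — which also reduces replicate variance. The default f grid has
14 points in (0, 0.5], denser near zero where categorization optima
live; f ≤ 0.5 reflects the biologically observed regime (the theory is
symmetric under f ↔ 1−f above degree 1). Architecture sweeps hold the
synapse budget S = M·K fixed (in-degree sweeps) or scale M = ratio·N
(expansion-ratio sweeps) at fixed f = 0.3. Heavy linear algebra runs in
float32 (solves in float64); per-row seeds derive from a counter-based
SeedSequence scheme so any row is reproducible in isolation. Presets
bundle the standard parameter sets (categorization, GP at several γ,
sparse/clustered connectivity, in-degree, expansion ratio, arm,
mushroom body, VOR, theory comparison); `--scale k` divides M and the
seed count by k for quick runs.

Problem sizes used by the shipped checks (chosen to make each
scientific claim measurable with comfortable statistics): full-scale
categorization (M = 10⁴, P = 10³, 10 seeds), GP sweeps at M = 2×10⁴
(20 seeds), theory comparison at M = 2×10⁵ (50 seeds), sparse/dense
and clustered comparisons at M = 2×10⁴ (20 seeds).

## Known limitations

- No Golgi-cell dynamics, heterogeneous thresholds, spiking
  variability, or temporal filtering; inhibition enters only as the
  global weight balance and the shared threshold.
- The spectral theory assumes uniform inputs on the sphere and an
  infinite-width layer; finite-M corrections and non-uniform input
  measures are out of scope.
- The expected-case error predictor's quantitative accuracy degrades
  for low-D ridgeless interpolation (see caveat above).
- Synthetic tasks idealize real sensorimotor statistics: passing tests
  demonstrates the model's internal consistency and its qualitative
  predictions, not quantitative agreement with biological recordings.
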
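# Methods

## Model

The package implements a mean-field description of a stem-cell population:
one collective order parameter *m* (the average cell state) moving in a
Landau potential

V(m, ξ) = −(1−ξ)/2·m² + α/3·m³ + β/4·m⁴ + γ/6·m⁶,

where the control parameter ξ ≥ 0 is the population's intrinsic
gene-expression noise, playing temperature's role in the classical theory of
disorder–order transitions. Pluripotency is the symmetric state m = 0
(all fates accessible); differentiation is the occupation of an asymmetric
minimum m ≠ 0. Two extensions turn this static picture into the dynamical
system of interest:

1. **Self-regulation.** ξ is not swept externally but obeys the negative
   feedback dξ/dt = G(m² − M²). The population lowers its own noise while
   undifferentiated (|m| < M), steering itself through the critical point
   ξc = 1 where the symmetric state destabilizes; overshooting |m| > M
   raises the noise again. G is the feedback gain, M the set-point.
2. **Finite-size noise.** An additive stochastic forcing σ dW on *m*
   represents fluctuations of a finite population of N cells. σ is
   specified directly; a convenience map σ = c/N^q is provided with
   configurable exponent q (1/2 by central-limit scaling, 1 for strict
   inverse proportionality — both conventions appear in the mean-field
   literature). The reference value used throughout the ensembles is
   σ = 10⁻⁴, with 2×10⁻⁴ for the switching scenarios.

Model assumptions worth keeping in view: a single scalar order parameter
(no multi-lineage competition), spatially well-mixed populations (no
signaling geometry), white additive noise on *m* only, and a deterministic
noise-feedback law.

## Coefficient presets and validity

Arbitrary real (α, β, γ) are accepted subject to boundedness below
(γ > 0, or γ = 0 with β > 0); the three presets (0,1,0), (0,−1,1), (−1,1,0)
pin the standard second-order, first-order/hysteresis, and asymmetric
scenarios. Admissible set-points are bounded by the requirement that the
equilibrium noise ξ*(±M) = 1 ∓ αM − βM² − γM⁴ stay non-negative: M < 1,
M < √((1+√5)/2) ≈ 1.27202 and M < (√5−1)/2 ≈ 0.61803 for the three presets
respectively, computed as the smallest positive root of ξ*(M).

## Analysis layer (exact where possible)

* **Fixed-noise branches.** Equilibria of the one-dimensional gradient flow
  are roots of the drift polynomial; presets use the closed forms
  (±√(1−ξ); ±√(0.5±√(1.25−ξ)); 0.5±√(1.25−ξ)), custom coefficient sets use
  `numpy.roots`, and the two routes are cross-checked in the tests to 1e−9.
  Stability is the sign of ∂(drift)/∂m.
* **Critical noise values.** The pluripotent state destabilizes at ξc = 1
  (the linearization at m = 0 is (1−ξ)m for every coefficient set). The
  saddle-node point solves the double-root condition drift = ∂drift/∂m = 0
  at m ≠ 0 (ξ = 5/4 for both presets 2 and 3). The phase-transition point
  solves the degenerate-minimum condition V = ∂V/∂m = 0 at m ≠ 0 by
  analytic elimination — substituting the stationarity condition reduces it
  to α/6 + βm/4 + γm³/3 = 0 — giving ξ = 19/16 (m² = 3/4) and ξ = 11/9
  (m = 2/3) for presets 2 and 3. When no nonzero degenerate point exists
  the ground-state shift is continuous and the transition is second order
  at ξc. Exact fractions are the reference; the two-decimal values 1.18 and
  1.22 are their roundings.
* **Stability of the coupled system.** The Jacobian at a state (m, ξ) is
  [[∂f/∂m, −m], [2Gm, 0]]; at E± its trace is −αm − 2βm² − 4γm⁴ and its
  determinant 2GM² > 0. Eigenvalues come from the standard quadratic
  formula λ = [T ± √(T²−4Δ)]/2, and classification follows the
  trace–determinant (Poincaré) diagram with a sign tolerance of 1e−10;
  boundary cases return the degenerate label (e.g. `stable_degenerate_node`
  exactly on G = M²/2 for preset 1) rather than an arbitrary side.
* **Hopf points.** Candidates are positive roots of T(M) = 0 inside the
  admissible range with Δ > 0 and T′(Mc) ≠ 0 (transversality): Mc = √2/2
  for preset 2, Mc = 1/2 on the m > 0 branch of preset 3, none for preset 1.
  Whether the bifurcation is supercritical is decided numerically — a
  deterministic run at Mc − 0.02 must settle on a small stable orbit while
  Mc + 0.02 converges — rather than by computing the first Lyapunov
  coefficient; the normal-form calculation is outside scope and the
  simulation check tests the same prediction directly.

## Simulation layer

Euler–Maruyama with dt = 10⁻³ (the protocol step used for every reported
ensemble): m ← m + f·dt + σ√dt·z, ξ ← ξ + G(m²−M²)·dt, z ~ N(0,1). σ = 0
reduces to forward Euler on the deterministic flow; first-order convergence
in dt and agreement with an adaptive RK45 reference to 1e−4 at t = 10 are
tested. Recording keeps every 100th step (0.1 time units) so
1000-trajectory ensembles stay small in memory. The inner loops are
numba-compiled scalar recurrences.

Reproducibility: trajectory *i* of an ensemble draws from
`SeedSequence(master_seed, spawn_key=(i,))`, a counter-based split, so each
path is bit-identical regardless of ensemble size or execution order, and
repeated runs with the same master seed write byte-identical files.

Degenerate-input choices: the line m = 0 is invariant under the
deterministic flow, so deterministic runs default to m(0) = 10⁻³ to break
it (stochastic runs may start at exactly 0); ξ may go negative under policy
`none` (the drift stays well defined; a warning is logged) or be floored at
0 under `clamp`, since ξ is physically a noise strength. A non-finite state
aborts with the step index (reachable only with absurd steps — the valid
potentials are confining).

## Observables

* **P(m, t)**: per-time-node histogram across trajectories, 201 uniform
  bins on [−1.5, 1.5] by default, normalized so ∑P·Δm = 1 at every node.
* **Quasi-potential** Φ = −ln P on occupied bins; empty bins are masked
  (NaN), never imputed — imputation would fabricate landscape features.
* **Fate fractions**: share of trajectories within a radius (default 0.1)
  of each equilibrium's m at an evaluation time, plus an `undecided` rest.
* **Limit cycles**: after discarding a transient (default the first half),
  a cycle requires amplitude > 10⁻³ in m, regular peak spacing (period CV
  < 5%), and a stationary (non-decaying) amplitude — the last test is what
  separates a genuine orbit from a slowly converging spiral, which also
  rings at a regular period. Orientation is the sign of the signed area of
  the (m, ξ) loop; period is the mean peak spacing; fewer than five peaks
  returns `undetermined`.
* **Switching**: basin labels are assigned hysteretically (a label changes
  only on entering a different labeled interval), which suppresses chatter
  at boundaries; dwell times are the run lengths of constant labels. Basin
  intervals are a declared convention (default half-width 0.3 × attractor
  spacing), not derived from the model.

## Problem sizes and test design

The analytic layer is exact and instantaneous; every simulation-backed test
picks the smallest size that cleanly exhibits the effect. Ensembles use
60–200 trajectories at t = 100 for the symmetry-breaking scenario (the
even split is tested against three binomial standard deviations of 1/2,
so it holds for any seed at ~99.7% confidence); deterministic phase
portraits run to t = 2500, long enough for the slowest spiral considered
(decay rate ≈ 0.004) to fall below the cycle-detection threshold; the
Hopf-scaling study fits amplitude against offsets 5×10⁻⁴–4×10⁻³ below Mc
at t = 6000. That window is a deliberate choice: the square-root law
amplitude ∝ √(Mc−M) is the *onset* asymptotics of a supercritical Hopf
bifurcation, and measured cycles obey it there (slope 0.50–0.54,
amp/√offset ≈ 1.21); farther from Mc (offsets ≳ 0.01) the orbit turns
relaxational — its period roughly doubles by offset 0.05 — and the
apparent log-log slope steepens to ≈ 0.74, which is a property of the full
nonlinear cycle, not a failure of the normal-form prediction.

## What the synthetic ensembles do and do not show

All inputs are model-generated; there is no external data. The ensembles
emulate the published protocol (start (m, ξ) = (0, 1.5), σ = 10⁻⁴,
dt = 10⁻³) at 60–200 trajectories instead of 1000, which widens binomial
error bars but changes no expectation values. Passing tests show the
*model's* phenomenology — spontaneous symmetry breaking, valley splitting
of the reconstructed landscape, oscillatory fates, hybrid states,
hysteresis — not that real stem-cell populations follow a scalar Landau
potential. In particular the quasi-potential is an empirical −ln P of a
simulated density, and dwell/switching statistics depend on the declared
basin convention.

## Known limitations

* Noise-induced transitions between mirror-image limit cycles are
  exponentially suppressed once the orbit's closest approach to m = 0
  exceeds the stationary noise scale; at σ = 2×10⁻⁴ single paths commit to
  one side and stay (the three-state hybrid at M = 0.5 is an
  ensemble-level statement here). Quantitative escape rates (Kramers
  theory) are out of scope.
* The Hopf character check is a two-point simulation probe, not a proof of
  genericity; degenerate (non-generic) custom coefficient sets could fool
  it and report `undetermined`.
* Euler–Maruyama is first order; no higher-order or adaptive stochastic
  schemes are provided.
* The hysteresis sweep relaxes by damped gradient flow with a small
  symmetric-breaking kick (10⁻⁶); exactly at degenerate points (e.g. the
  pitchfork at ξ = 1) convergence is algebraic and the settled value is
  accurate only to ~10⁻³ there.
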
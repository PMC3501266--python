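# Methods

## Model

The package studies the scalar neural field

    du = [ -u + (w * F(u)) + I(x - v t) ] dt + ε^{1/2} g(u) dW(x, t)

on the real line, time measured in membrane time constants.  The
connectivity kernel is the offset difference of exponentials

    w(x) = a_e e^{-σ_e |x - x0|} - a_i e^{-σ_i |x - x0|}

with `a_e > a_i > 0` and `σ_e > σ_i > 0` (validated at construction): a
Mexican hat whose peak is displaced by `x0`.  The displacement breaks
reflection symmetry and is the mechanism of interest — it lets the network
propagate pulses in the direction of the offset with no adaptation
variable, a recurrent substrate for direction selectivity.  All analytic
constructions take the high-gain limit `F(u) = H(u - κ)`; the sigmoid
`F(u) = 1/(1 + e^{-γ(u-κ)})` is supported by the simulator only.

Canonical parameters used throughout the presets, examples and tests:
`a_e = 5, a_i = 1, σ_e = 0.42, σ_i = 0.1, x0 = 3, κ = 4`, stimulus width
`d = 5`, noise `ε = 0.005, g(U) = U, C(0) = 10` on a lattice with
`Δx = 0.1, Δt = 0.01`.

## Closed-form core

Every construction reduces to the half-line transform of the kernel,

    G(z; γ) = ∫_z^∞ e^{-γ (y - z)} w(y) dy,       Re γ > 0,

which has an exact piecewise-exponential antiderivative.  The pulse
profile is the window integral of `G`:

    U(ξ) = (1/c) ∫_{d1}^{d2} G(ξ - s; Γ) ds,

free pulses using the window `(0, d)` with `Γ = 1/c`, stimulus-locked
pulses the window `(d1, d2)` with `Γ = 1/v` plus an explicit stimulus
response term, and noise-modified pulses the shifted decay
`Γ(ε) = (1 - ε C(0) g0²)/c_ε`.  Leftward waves (`v < 0`) evaluate the
mirrored transform via the kernel's symmetry about `x0`.  The same
primitive with complex decay `(λ+1)/c` yields the Evans function, and with
`b(z) = G(z; Γ)/c` the adjoint mode of the wandering theory.  The
piecewise `M_n`/`N_n` building blocks of the branch-wise profile listing
are exposed as `exp_weighted_window` and tested to agree with the unified
route; quadrature appears only as a test oracle.  Degenerate decays
(`γ` equal to a kernel rate) use the analytic limit formulas.

## Existence solvers

The threshold conditions are transcendental with multiple roots, so both
solvers are multi-start damped root finders (scipy `hybr`):

* free pulses: log-space in `(c, d)` over a 10x10 geometric seed grid on
  `c ∈ [0.05, 20], d ∈ [0.1, 50]`; converged roots with residual < 1e-9
  are deduplicated at 1e-6 relative tolerance;
* locked pulses: variables `(d1, log(d2 - d1))`, seeded from the free
  pulses shifted across ±2 widths plus 40 uniform random seeds (up to four
  coexisting solutions occur inside overlapping tongues); enumeration caps
  at 8 roots per parameter point.

Every root must pass a hard validity filter: the profile sampled at ≥1000
points per width (extended several inhibitory decay lengths each side)
must be superthreshold exactly on the interval between its crossings.
Roots failing it are reported separately — their loss with increasing
stimulus amplitude traces the solid boundaries of the locking diagram.
`branch_scan` continues branches over a threshold grid with warm starts
and records terminations (the two branches approach each other and meet at
a fold near κ ≈ 5.2 for the canonical kernel; the residual Jacobian
condition number grows accordingly).

## Spectral machinery

Stability is decided by the zeros of the Evans determinant right of the
essential spectrum (the vertical line `Re λ = -1`).  The search samples the
determinant on a rectangular grid (default `Re λ ∈ (-0.95, 3]`,
`|Im λ| ≤ max(2π|speed|/width, 2)`, 90x61 points), seeds a complex Newton
polish wherever the zero contours of the real and imaginary parts cross a
cell, and adds a dense bracketed sweep of the real axis.  Classification
additionally sweeps the real axis out to `Re λ = 200`: narrow locked
pulses whose crossing sits near the stimulus plateau have linearization
coefficients `1/|κ - W(d_n) - I(d_n)|` that are large, pushing real
unstable eigenvalues far right of any fixed box (an instance at the
canonical parameters sits at λ ≈ 4.6).  `E(λ) → 1` as `|λ| → ∞`, so roots
cannot escape to infinity.  An eigenvalue counts as the translation zero
if `|λ| < 1e-6`; verdicts require all other roots to satisfy
`Re λ < -1e-6`, else `unknown`.

As an instance-by-instance cross-check, `linearized_operator_matrix`
builds a dense central-difference discretization of the linearized
operator with the point evaluations at the crossings spread over the two
neighboring nodes (second order).  On a domain padded ±60 beyond the
crossings with `Δx = 0.05`, its eigenvalues right of `Re λ = -0.75` match
the Evans zeros to ~1e-4; the truncated essential spectrum shows up as
spurious arcs that retreat toward `Re λ = -1` as the domain grows, which
is why the comparison window stays right of -0.75.

## Stochastic integrator

`integrate_langevin` steps the Itô-equivalent form: drift
`-u + ε C(0) g'(u) g(u) + (w * F(u)) + I`, plus per-site independent
Gaussian increments of variance `2 C(0) Δt` scaled by `ε^{1/2} g(u)`.
Writing the Stratonovich (Novikov) correction as explicit drift makes it
testable in isolation; the test suite verifies both the increment variance
law and the midpoint identity `ε^{1/2}⟨g(U_mid) dW⟩ = ε C(0) g'g Δt` at a
frozen field.  For lattice white noise the construction requires
`C(0) = 1/Δx` and the integrator rejects inconsistent combinations.

The convolution samples the kernel where `|w| > 1e-8 (a_e - a_i)` and is
evaluated by FFT on a zero-padded domain (the padding realizes the
clamped-zero exterior; a periodic variant exists for co-moving windows).
The kernel transform is precomputed and the product carried out in single
precision — relative error ~1e-6 against O(Δt) drift increments — which
triples throughput.  All trials march in lockstep as one `(n_trials, nx)`
block drawing from a single seeded PCG64 stream; runs are bit-reproducible
given the seed, and a blow-up guard plus a boundary-proximity warning
(superthreshold activity within `min(5/σ_i, L/10, 10)` of the domain ends)
police the domain choice.

At the canonical lattice (`Δx = 0.1, Δt = 0.01`) the deterministic
integrator transports the analytic pulse about 4% fast — a first-order
lattice-pinning bias that shrinks under refinement (verified by a
Richardson-style test).  Notably the bias largely disappears under noise:
measured noisy ensemble speeds match the analytic noise-modified `c_ε` to
~0.2%, because the noise dithers the Heaviside across the lattice.

## Wandering theory

Splitting the field into a displaced mean profile plus O(ε^{1/2}) shape
fluctuations and projecting the fluctuation equation onto the adjoint mode
V gives a scalar SDE for the displacement Δ(t).

* Free pulse: V is the exact null vector of the adjoint linearized
  operator, `V(ξ) = b(Δ) H(ξ) e^{-Γξ} - b(-Δ) H(ξ-Δ) e^{-Γ(ξ-Δ)}`; the 2x2
  self-consistency system at the crossings is singular identically and the
  construction certifies `|det| ≤ 1e-8` relative to its norm.  Δ(t) is
  unbiased Brownian motion with `⟨Δ²⟩ = 2 D(ε) t`.
* Locked pulse: translation symmetry is broken, the linearization
  annihilates nothing (`L U0' = -I' ≠ 0`), and a λ = 0 adjoint null vector
  does not exist.  The projection mode implemented is the adjoint
  eigenfunction of the slowest discrete mode λ1 — the same two-exponential
  ansatz with decay `(λ1 + 1 - εC(0)g0²)/v`, where λ1 is the largest real
  root of the self-consistency determinant (the noise-aware Evans
  function).  With that choice the restoring rate obeys
  `A = ∫V I' / ∫V U0' = -λ1` *exactly* (from `⟨V, L U0'⟩ = λ1⟨V, U0'⟩`),
  and the code verifies the identity to 1e-6.  Δ(t) is an OU process with
  variance `(D/A)(1 - e^{-2At})`, saturating at D/A.  Only `v > 0` is
  implemented; leftward locked pulses would need the mirrored ansatz.

The D(ε) integrals are evaluated by adaptive quadrature split at the
profile kinks, with an exponential tail cut at 60 decay lengths.  D is
exactly linear in ε for linear gain, and ε = 0 short-circuits to D = 0.

The theory treats the width as rigid.  In simulation the width does
fluctuate: it inflates the trailing-edge variance by a fast-saturating
offset (the transient the mean-position fits must skip), and for locked
pulses the trailing edge saturates an order of magnitude above the leading
edge — so the rigid-displacement D describes the bulk displacement, not
either edge's variance level, once a stimulus pins the leading edge.

## Measurement protocol

Wave position is read as the linearly interpolated crossing of a level
`a ∈ {0.6κ, 0.8κ, κ}` per edge; in noisy frames the crossing nearest the
previous frame's position is kept (temporal continuity), falling back to
the widest superthreshold component on the first frame.  The mean path
averages over levels then trials; the variance averages each level's
across-trial variance (per-level demeaning, so constant level offsets
x_a(0) cancel and the estimator targets ⟨Δ(t)²⟩).  Fits discard the first
25% of the record as transient by default.  Brownian parameters come from
least-squares lines through the mean and variance; OU parameters from
either the saturating-curve fit (unbiased but noisy at a few hundred
trials) or, preferably, `fit_ou_acf`, which fits the stationary
autocovariance `(D/A) e^{-Aτ}` over lags — using every time pair — and
recovers (D, A) within ~5% from 512 synthetic trials.  Synthetic
Brownian/OU track generators (exact transition densities, optional
per-level observation jitter) provide the estimator oracles.

## Problem sizes

The shipped tests and the reproduction script run on one CPU: free-pulse
wandering ensembles use 512 trials to t = 20 at three thresholds (theory
vs empirical D agrees within ~10% there, asserted at 25% to cover
Monte-Carlo spread), the stimulus-locked ensemble 200 trials to t = 48 for
saturation checks and to t = 24 for the drift-slope reproduction, and the
matrix-oracle comparisons a ±60 domain at Δx = 0.05.  Monte-Carlo
comparisons against the perturbation theory use 25% tolerances throughout:
Δ(t) is itself only defined up to O(ε^{1/2}) corrections, and desk-scale
trial counts add sampling error of the same order.

## Known limitations

* Spatially correlated noise (finite correlation length) is an extension
  point: only the lattice white-noise limit `C(0) = 1/Δx` is implemented.
* Stationary stimuli (v = 0) are out of scope; the locked machinery
  requires a moving frame.
* The sigmoid firing rate has no closed-form pulse; it is simulator-only.
* The locked adjoint mode assumes a real slowest eigenvalue and `v > 0`.
* Width fluctuations are measured (width_stats) but not modeled; the
  theory's Δ(t) is a rigid displacement.
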
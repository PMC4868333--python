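# Methods

## Model

Degradation is modeled as a continuous-time Markov chain with two
biochemical states and an absorbing degraded state: a molecule is born in
state 1, exits it at rate λ₁ = κ₁₀ + κ₁₂ (to degradation with branching
probability P₁₀ = κ₁₀/λ₁, to state 2 with P₁₂ = κ₁₂/λ₁), and leaves state 2
by degradation at rate λ₂ = κ₂₀.  The lifetime is the absorption time — a
phase-type distribution: a mixture of an Exp(λ₁) (direct path) and a
hypoexponential Exp(λ₁)+Exp(λ₂) (two-step path).  Its survival function,
density, and hazard are two-exponential expressions in λ₁, λ₂; the hazard
starts at κ₁₀ and tends monotonically to min(λ₁, λ₂), so molecules
*stabilize with age* when κ₂₀ < λ₁.

Key assumptions: constant synthesis rate ω during labeling, a homogeneous
and stationary cell population, and measured abundances reflecting only
synthesis and degradation.  Dilution by cell division is **not** modeled;
experiments must be short relative to the doubling time, or κ₁₀/κ₂₀ are
read as effective rates that include dilution.  Two states are the
practical identifiability limit for a single decay pattern; larger chains
are out of scope.

### Decay and accumulation curves

With a pulse of length t_p, the labeled cohort at chase start carries a
mixture of ages; the chase pattern is the window integral of survival,
normalized to C(0) = 1:

    C(Δt) = ∫_{Δt}^{t_p+Δt} S(u) du / ∫_0^{t_p} S(u) du
          = [A_c e^{−λ₁Δt} + B_c e^{−λ₂Δt}] / (A_c + B_c)

with A_c = (κ₁₀−κ₂₀)/λ₁·(1−e^{−λ₁t_p}) and B_c = κ₁₂/κ₂₀·(1−e^{−κ₂₀t_p}).
t_p → ∞ (synthesis shutoff) sets both bracketed factors to 1; t_p → 0
recovers the bare survival function; κ₁₂ → 0 collapses everything to
e^{−κ₁₀Δt} independent of pulse length.  A_c may be negative (κ₂₀ > κ₁₀):
the curve is still a valid decreasing pattern and no sign constraint is
imposed.

Pulse-only measurements accumulate toward steady state:
P(Δt) = N(Δt)/N^(st) = I(Δt)/T̄ where I(t) = ∫₀ᵗ S and T̄ = 1/λ₁ +
κ₁₂/(λ₁κ₂₀) is the mean lifetime.  This equals the explicit two-term form
with weights A_p = κ₂₀(κ₁₀−κ₂₀), B_p = κ₁₂λ₁ (exposed as `pulse_weights`
and verified by a dual-route test); the integral form is used for
evaluation because A_p + B_p → 0 at eigenvalue degeneracy.  Normalization
by a finite reference time is computed as the abundance ratio
N(Δt)/N(t_norm) rather than a separate closed form — identical by
construction, fewer formula branches.

Derived quantities: occupancies π₁ = κ₂₀/(κ₁₂+κ₂₀), π₂ = 1−π₁; steady
state N^(st) = ωT̄; the true half-time solves C_∞(t_½) = ½ on the
infinite-pulse curve, while finite-pulse crossings are *apparent*
half-times that grow with t_p whenever κ₁₂ > 0.

## Numerics

Every two-exponential form carries a 1/(λ₁−λ₂) factor and becomes 0/0 at
the degeneracy κ₂₀ = κ₁₀+κ₁₂ (e.g. A_c → −B_c), with catastrophic
cancellation in a wide band around it.  Instead of switching to a special
branch only at exact degeneracy, all curves are evaluated through
divided-difference primitives built on `expm1`
(`exp_dd(λ₁,λ₂,t) = (e^{−λ₂t}−e^{−λ₁t})/(λ₁−λ₂)` and its integrals), which
are accurate for any eigenvalue gap and reduce exactly to the
`t·e^{−λt}` secular terms in the degenerate limit.  A direct-difference
fallback is used when |gap·t| > 50, where the series form could overflow
and the naive form is already safe.  The closed forms agree with adaptive
quadrature of the defining integrals to better than 1e-12 in tests,
including gaps down to 1e-14 relative.  The hazard is evaluated with
numerator and denominator rescaled by e^{min(λ₁,λ₂)·t} so it never
underflows to 0/0 at large ages.  Half-times are found by geometric bracket
expansion from T̄ followed by Brent root finding at 1e-12 relative
tolerance.  `RateSet` flags eigenvalue degeneracy below a relative gap of
1e-12.

## Fitting

The objective is the squared-log error M = Σⱼ [ln C(Δⱼ) − ln C̃(Δⱼ)]²
(lognormal measurement error); pooling m experiments sums their objectives,
each evaluated with its own pulse length, design, and time grid.  Pulse-only
patterns may contain the point (t = 0, value 0), which is excluded from the
log objective.  Public objective functions use exactly-rounded summation
(`math.fsum`) so the value is invariant under point and pattern order.

Minimization: multistart bounded local least squares.  Start points are
drawn log-uniformly over the calibration box [1e-6, 1]³ min⁻¹ (the rates
span four decades) with a seeded generator; each start is polished by
scipy's trust-region-reflective `least_squares` in log10-parameter space
with box bounds.  Defaults follow the reference protocol: 1000 starts for
chase calibration, 100 for the small pulse-only designs (unit tests use
fewer for speed).  All minima within 1e-6 relative objective of the best
are reported as `alternates`; per-start final objectives are kept for
identifiability diagnostics.  Identical seed and inputs give bit-identical
results.

Model selection fits the nested one-stage model (C = e^{−κt}, pulse-length
independent; P = 1−e^{−κt}) and compares AIC = n·ln(RSS/n) + 2k with k = 1
or 3, RSS on log residuals (floored at 1e-300 since noiseless fits reach
RSS = 0).  An optional chi-squared goodness-of-fit report (RSS/σ², n−k
d.o.f.) is available when the user supplies a residual variance; it is
disabled by default because σ² is rarely known.

## Synthetic data

`fabricate_pattern` evaluates the closed forms on a default chase grid of
0, 40, …, 480 min (13 points), chosen to straddle the fast (1/λ₁ ≈ 34 min
at the reference rates) and slow (1/κ₂₀ = 5000 min) timescales at a
realistic number of time points; the reference pulse-length family is
{1, 5, 30, 120, 1200} min.  The reference rates used throughout tests and
examples are κ₁₀ = 0.0109, κ₁₂ = 0.0189, κ₂₀ = 0.0002 min⁻¹ — a
slowly degrading HeLa-protein-like calibration whose mean lifetime is
53.4 h (κ₂₀ is sometimes quoted as 0.002 alongside these values; only
0.0002 is consistent with that mean lifetime, and it is used everywhere
here).

`add_noise` multiplies each value at t > 0 by exp(ε·ζ) with ζ ~ U[0, 1)
independent per point (default ε = 0.01); the t = 0 anchor is untouched.
This noise is deliberately **one-sided** (factor ≥ 1), kept exactly as
defined rather than symmetrized.  Consequence worth knowing: relative to
the fixed C(0) = 1 anchor, the uniform upward shift of all later points
mimics a small fast-decaying component of negative amplitude, so on truly
exponential data AIC tends to prefer the two-stage model under this noise.
The model-selection test therefore uses zero-mean log-noise, which is the
meaningful version of the "AIC recognizes an exponential" property.

`simulate_single_molecules` is an independent Monte-Carlo oracle: n
molecules are born uniformly over the pulse window (conditioning on the
birth count instead of simulating Poisson arrivals — the normalized pattern
is identical in distribution and the variance bookkeeping simpler), draw
phase-type lifetimes by explicit dwell sampling, and are censused at the
requested times.  Chase censuses are normalized by the count surviving at
pulse end — conditionally on that count, each later census is exactly
binomial with success probability C(Δt), which the 3-standard-error test
bounds exploit.  What passing these tests shows: the closed forms and the
stochastic single-molecule picture agree, and the fitting pipeline is
self-consistent.  What they do not show: anything about un-modeled features
of real data — labeling toxicity, cell division, age-dependent synthesis,
or instrument-specific error structure.

## Sensitivities

Local sensitivities v_κ(t) = dP(t)/dκ of the pulse-only output are
implemented in closed form by chain-rule differentiation of the
(A_p, B_p, λ₁, λ₂) parameterization, derived symbolically once and
hard-coded; they are validated against central finite differences
(relative step 1e-6, balancing truncation against rounding over the
1e-6..1 rate range) to 1e-4 relative error on a 20×20 (κ, t) grid per
parameter.  The closed form is refused within a relative eigenvalue gap of
1e-9 of the degeneracy (the finite-difference route remains available
there).  Only local, pointwise derivatives are computed — no global
sensitivity indices.  The profiles quantify the design guidance built into
the package: sensitivities vanish once P saturates, so pulse-only sampling
beyond ~20–40 min (at the reference rates) adds no information, and the
output responds only to small values of κ₁₀ and κ₁₂.

## Limitations

* Two-stage chains only; no three-state models, no cell-division dilution,
  no age-dependent synthesis.
* The chi-squared report requires an externally supplied residual variance.
* Closed-form sensitivities are unavailable at near-degenerate eigenvalues.
* Long single-pulse patterns are intrinsically weakly identifying (state 2
  dominates the cohort): with noise, fitted rates can wander far at a flat
  objective.  The package reports per-start diagnostics and near-tie
  alternates to surface this, and pooling several pulse lengths is the
  recommended remedy.
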
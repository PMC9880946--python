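# Methods

## Models

All four models describe an SIR epidemic with per-link transmission rate
τ (1/day), recovery rate γ (1/day) and population size N on a network of
mean degree n. Time is measured in days throughout.

**Compartmental SIR.** Ṡ = −τnIS/N, İ = τnIS/N − γI. The disease-free
state (N, 0) has leading eigenvalue λ = τn − γ, and the final attack
fraction r<sub>∞</sub> solves τn·r<sub>∞</sub> + γ·ln(1−r<sub>∞</sub>) = 0.

**Pairwise model.** Node counts [S], [I] and (doubly counted) pair counts
[SS], [SI] evolve under the triple closure [ASB] = κ[AS][SB]/[S], with
κ = (n−1)/n (exact for binomial degree distributions in the large-network
limit) or κ = 1 (Poisson). The disease-free state is (N, 0, nN, 0);
its infection block ([I], [SI]) has dominant eigenvalue τ(n−2) − γ for
κ = (n−1)/n and τ(n−1) − γ for κ = 1. The final size solves
τ(s − s^{2/n}) + γ(s^{1/n} − s^{2/n}) = 0 (κ = (n−1)/n, disease-free
initialisation); for κ = 1 the conserved-quantity reduction gives a
relation identical to the EBCM one.

**Edge-based compartmental model.** A single ODE for θ, the probability
that a random neighbour of an initially susceptible test node has not yet
transmitted:
θ̇ = −τθ + τφ_S(0)e^{n(θ−1)} + γ(1−θ) + τφ_R(0),
with S(t) = Nψ(θ(t)) and ψ the Poisson PGF. λ = τ(n−1) − γ;
θ<sub>∞</sub> solves (τ+γ)θ − γ − τφ_S(0)e^{n(θ−1)} = 0 and
s<sub>∞</sub> = e^{n(θ∞−1)}.

## The inverse problem

Observing (λ, s<sub>∞</sub>) with γ known yields two curves in the
(n, τ) plane: τ = (λ+γ)/l(n) and the τ that makes the final-size
equation hold at (n, γ). Their intersection is found by bracketing
root-finding (Brent, xtol 1e-12) on the sign change of the curve
difference. If the difference never changes sign the observation is
inconsistent with the model and a `NoIntersectionError` carries the
minimal gap; if the curves agree to roundoff everywhere (the SIR case,
where both equations pin down only τn) a
`StructurallyUnidentifiableError` is raised instead of a spurious point
estimate. Multiple sign changes (not expected; the reduced functions are
monotone on their domains) are all reported and flagged.

At fixed n the two equations are *linear* in (τ, γ);
`solve_tau_gamma_given_n` solves the 2×2 system directly and raises when
the determinant vanishes relative to the matrix scale (the degenerate
s<sub>∞</sub> → 1 limit; for admissible interior observations the
determinant works out strictly one-signed for all four models).

## The reduced function and the ε-band

Eliminating τ gives f(n) = f(n\*) with the f's listed in the README.
Numerical care: the pairwise f suffers catastrophic cancellation both as
n → 2 (denominator s^{2/n} − s → 0) and as s → 1; both factors are
rewritten via `expm1`, which keeps direct evaluation within 1e-6 of the
closed-form limits at n = 2 + 1e-8 and n = 1e8. The limits themselves
(f₂, f<sub>∞</sub>, and their value 1 at s = 1) are always computed from
the closed forms, never by numerical limiting.

The monotonicity of the pairwise f holds only for s<sub>∞</sub> above a
threshold; rather than reproducing the analytic proof apparatus, the
package characterises the threshold empirically: `scan_monotonicity`
tests strict increase on a 2000-point logarithmic n-grid over (2, 10³]
for a dense grid of s values and reports the largest failing s (0.025
with the default grids, comfortably below 0.1). The verdicts are stable
under doubling the n-grid.

The ε-band set {n : |f(n) − f(n\*)| < ε} is computed by monotone
inversion of f — numerically (bracketed Brent) for the pairwise f,
in closed form n = (yq−1)/(y−1) for the EBCM f. Because f is bounded,
the band reaches the upper end of the domain as soon as
ε > f_limit − f(n\*), and the set is reported as a half-line with
`measure = math.inf` and an explicit `infinite` flag — never a large
float, since the definition is measure-theoretic.

## Integration and summaries

Trajectories are integrated with DOP853 (rtol 1e-8, atol 1e-10·N; for
the EBCM θ uses atol 1e-14), tight enough that trajectory-derived final
sizes agree with the implicit-equation roots to better than 1e-4 across
threshold ratios τl(n)/γ in [1.2, 4]. When no horizon is given,
integration stops once prevalence falls below 1e-8·N, capped at 500/γ
days. Cumulative incidence is accumulated as part of the state
(Ċ = τnIS/N, τ[SI], or N(1−ψ(θ)) bookkeeping) and daily new cases are
first differences of C on integer-day bins, matching how case counts are
reported.

Adaptive trial steps in burnt-out pairwise epidemics can undershoot
[S] = 0 or push pair counts slightly negative, where the closure is
undefined; the integrator wrapper evaluates the closure at the nearest
admissible state (S floored at 1e-12·N, pair counts at 0). The strict
`rhs_pairwise` API still rejects [S] ≤ 0, as user code should.

The pairwise pair-level initial conditions are not canonical anywhere;
the package uses the random-placement convention
[SI](0) = n·I0·(N−I0)/N, [SS](0) = n(N−I0)²/N, consistent with
[SS] = nN at the disease-free state. The EBCM is seeded by perturbing
φ_S(0) = 1 − I0/N at θ(0) = 1. Both are documented package choices.

## Synthetic observations

`generate_observation` returns the analytic pair (closed-form λ,
final-size root); `estimate_growth_rate` and `estimate_final_size`
provide the trajectory-derived counterparts. The growth-rate window
defaults to the days where prevalence lies in [10, 0.01·N] *before* the
prevalence peak — below that band the signal is dominated by the seeding
transient, above it by saturation. The least-squares slope of
log(daily cases) recovers λ to within a few percent for day-scale rates.

The noise model is deliberately minimal: λ is perturbed multiplicatively
by a zero-mean Gaussian (default sd 2%), s<sub>∞</sub> additively
(default sd 0.01, clipped into (0, 1)); these scales are chosen as
plausible surveillance accuracy and already produce the characteristic
error amplification (a 1% final-size error moves the recovered degree by
several percent, and noisy draws regularly land outside the consistent
region altogether). All randomness flows through one seeded
`numpy.random.Generator`. What the generator does **not** emulate:
demographic stochasticity, reporting delay and underascertainment, or
any real contact-network structure beyond the mean degree — so passing
tests establish the behaviour of the deterministic mean-field theory,
not robustness on real surveillance data.

## Experiment problem sizes

The distance surface is evaluated on a 60×60 grid over
n ∈ [2.2, 12], τ ∈ [0.02, 1.2] with a 300-day horizon and the distance
‖Δ(daily cases)‖₂/N; these bounds bracket all three trajectory-pair
parameter sets and resolve the valley at roughly one cell width. Local
minima are strict 8-neighbour minima after masking failed cells. The
surface is fully deterministic: repeated evaluation is bitwise
identical. The monotonicity scan uses a 0.005-step s-grid on (0.01,
0.99) × 2000 log-spaced n values. Unit tests run scaled-down variants
(7×8 surface grid, 150-day horizon); the full-size experiment lives in
the end-to-end suite.

## Known limitations

* Only the Poisson PGF is built in for the EBCM; the `ModelSpec.psi`
  hook is the extension point.
* The general-S₀ pairwise final size is the literal root of the implicit
  relation; away from near-disease-free initial conditions its agreement
  with the ODE is not claimed.
* No stochastic (Gillespie) network simulation, no SEIR dynamics, no
  profile-likelihood or Bayesian identifiability diagnostics.
* The intersection logic assumes the single-crossing geometry of the
  monotone reduced functions; exotic observations outside the scanned
  regimes are flagged rather than resolved.
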
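# Methods

## The model

A cell is represented by n focal adhesions (FAs) in the plane, each either
attached or detached, and a centroid c. Attached FAs act as identical
linear springs, so force balance puts the centroid at the mean of the
attached positions: Σᵢ αᵢ ψᵢ (vᵢ − c) = 0 with ψᵢ ∈ {0, 1}. Time is
replaced by a count of binding events. At each event, with k FAs attached,
one uniform draw decides the event type: attachment with probability
(n−k) r p, detachment with probability k p, where p = 1/(k + (n−k)r) and
r > 0 is the ratio of a detached FA's switching propensity to an attached
one's. An attaching FA (chosen uniformly among the detached ones) is placed
at c + η with the outreach η ~ ν; a detaching FA (uniform among the
attached) simply flips state, its position retained until reattachment.
After every event the centroid jumps to the new attached mean; if all FAs
are detached the centroid does not move, and the next event is an
attachment with probability one.

The attachment count is a birth–death chain with stationary law

- π₀ = 1/(2(1+r)^(n−1)),
- πₖ = r^(k−1) C(n−1, k−1) [k + (n−k)r] / (2(1+r)^(n−1) k), 1 ≤ k ≤ n.

Two exact identities anchor the implementation and are asserted in rational
arithmetic (`fractions.Fraction` flows through `switch_probability` and
`stationary_distribution` unchanged): the law sums to one and satisfies
detailed balance, and the aggregate stationary detach probability
Σₖ πₖ k pₖ equals 1/2 exactly for every n and r.

Note that the count chain is *periodic*: every event flips the parity of
k. π is its stationary (time-average) law but not a fixed-lag limit from a
deterministic start; see "Ensemble averages" below.

## Outreach distribution

ν is specified by a length law on [0, L_max] and an angle law in degrees
counter-clockwise from the positive x-axis (the reference axis is a
convention; it affects only the direction of the drift, never E[|η|²]).
Uniform and degenerate (point-mass) laws are supported with closed-form
moments; anything else raises `UnsupportedLawError` rather than silently
quadrating. Defaults: length U(0, 10) (length units), angle U(−30°, 30°),
giving E[η] = (15/π, 0) ≈ (4.7746, 0) and E[|η|²] = 100/3. The first
moment uses E[η] = E[L]·(E[cos θ], E[sin θ]); for a uniform angle on
[θ₁, θ₂] (radians) E[cos θ] = (sin θ₂ − sin θ₁)/(θ₂ − θ₁) and
E[sin θ] = (cos θ₁ − cos θ₂)/(θ₂ − θ₁).

## Displacement algebra and the AMSD

An attach event taking the count from k−1 to k displaces the centroid by
η/k, for any configuration. Detach displacements depend on the whole
configuration; they are closed-form for *sequential configurations*, built
by attaching FAs one at a time at outreaches η₂ … η_k from successively
updated centroids (FA 1 sits at the first centroid). If creation-story FA
ℓ+1 detaches, Δc = (1/(k−1)) [Σ_{m=ℓ+2}^{k} η_m/m − ℓ η_{ℓ+1}/(ℓ+1)], and
−η_k/k for the last FA; equivalently (c_k − v_d)/(k−1), which the test
suite verifies geometrically to 10⁻¹² by rebuilding the state and
re-averaging.

The expected squared detach displacement, summed over the k possibilities,
is Σᵢ i E[|η|²]/(i+1) / (k−1)² (i = 1..k−1). This drops the cross terms
E[ηᵢ]·E[ηⱼ], which vanish for a mean-zero (isotropic) ν; the Monte Carlo
oracle for this quantity therefore uses an isotropic angle law. The AMSD
assembles attach terms πₖ·rpₖ·(n−k)·E[|η|²]/(k+1)² (exact) and detach
terms πₖ·pₖ·(detach sum) — sequential values carried with *full*
state-space probabilities:

AMSD(1) = E[|η|²]/(2(1+r)^(n−1)) · [1 + Σ_{k=1}^{n−1} C(n−1,k) rᵏ
(1/(k+1)² + (1/((k+1)k²)) Σ_{i=1}^{k} i/(i+1))].

For n = 1 this is E[|η|²]/2 and for n = 2 it coincides identically with the
exactly enumerable MSD E[|η|²](1 + r/2)/(2(1+r)) — an algebraic identity the
tests check over a grid of r.

Accuracy for n > 2: the AMSD carries a positive bias that grows with n and
peaks at intermediate r, because real (non-sequential) configurations are
more spread out than sequential ones and because of the dropped cross terms
under the biased default ν. Measured against the simulator (which is exact
by construction, and validated to Monte Carlo error against the closed-form
n = 1, 2 MSD): at 10⁶ events the relative error stays below ~4% for
r = 0.25 up to n = 10, but reaches ~5–10% for r = 1 at n ≥ 5 and ~7–9% for
r = 10 at n ≥ 3. Passing the r = 0.25 comparisons therefore shows the
assembly is right, not that the approximation is uniformly tight; the
bounds below are what hold unconditionally.

## Bounds

Lower bound: keep the attach part, credit detach displacements only when
the history literally follows a sequential creation story — probability
Pₖᵈ(r) = π₀ k rᵏ p₀p₁…pₖ n!/(n−k)! — and replace every other detach
displacement by zero: LB = attach part + Σ_{k≥2} (Pₖᵈ/k)·(detach sum).
LB ≤ AMSD term by term. Limits: P₁ᵈ → 1/2 and Pₖ≥₂ᵈ → 0 as r → 0; all
Pₖᵈ → 0 as r → ∞.

Upper bound: in the worst case one FA stays attached while the others chain
outward at maximal outreach η_max; the far-FA positions follow
x_t = (x_{t−1}+…+x_{t−n+2})/(n−1) + η_max, whose unique fixed point
η_max(n−1) is attracting because all roots of
(n−1)λ^(n−2) = λ^(n−3)+…+1 lie strictly inside the unit circle (there is
exactly one positive real root; `numpy.roots` on the companion
coefficients, with a 10⁻⁹ imaginary-part cut for realness). The limiting
detach displacement is η_max(n−1)/n, and with k attached the bound is
η_max(n−1)/k. The MSD upper bound charges non-sequential detach events —
probability mass k πₖ pₖ − Pₖᵈ, clamped at ≥ 0 against floating-point
rounding at extreme r — that worst-case displacement squared. It is loose
by construction (order-of-magnitude above the MSD for mid-size n) but
finite and ordered: LB ≤ AMSD ≤ UB everywhere tested, and simulated
TAMSD₂(1) falls inside [LB, UB] on the whole comparison grid.

## MSD as a function of lag

The process is space- and time-homogeneous but its jumps are not
independent, so the i.i.d. decomposition
MSD(τ) = τ·Var + τ²·|drift|² is an approximation for τ > 1:
msd_of_tau = τ(AMSD − |m|²) + τ²|m|² with m = `mean_jump` (the closed-form
first moment). At τ = 1 it reduces to the AMSD exactly; for isotropic ν it
is linear in τ. The curve flattens as n or r grows — more adhesion, less
displacement — which the tests assert as strict monotonicity at τ = 50.

## Simulation and estimators

The simulator uses a single seeded numpy generator with a documented draw
order per event (event-type uniform; FA-selection uniform over the eligible
ids in increasing order, index = ⌊u·m⌋; then, for attaches, one draw per
non-degenerate law, length before angle), making trajectories
bit-reproducible; degenerate laws consume no draws. The default
initialization places the n FAs equally spaced on a circle of radius
U(0, 10) with all FAs attached; `burn_in` (default 10,000) events are
discarded before recording so that occupancy and spatial configuration
reach stationarity for n ≤ 10 and r ∈ [0.25, 100] (total-variation
distance of occupancy from π measured < 0.01 at 10⁶ events). The centroid
is recomputed as an exact mean after every event rather than updated
incrementally, avoiding drift over long runs; recorded positions include
the post-burn-in centroid, so a trajectory of E events yields E
displacements.

TAMSD with overlapping and disjoint windows and the ensemble EAMSD follow
the standard definitions; the estimators are translation invariant, agree
at lag 1, and give exactly k²|v|² on deterministic linear motion. The
theory targets lag 1 (disjoint = overlapping), which is how simulated MSDs
are compared to the AMSD throughout.

**Ensemble averages and parity.** Because k flips parity every event, an
ensemble started from a fixed count (e.g. all attached) and burned in for a
fixed number of events has its parity locked, and EAMSD at a fixed lag is
then biased. The `steady_state_count` initialization draws the initial
count from π; since π is invariant under a single step, the ensemble count
law is exactly π at every subsequent event index, and EAMSD(1) matches the
exact MSD (verified for n = 2).

## Problem sizes and numerical choices

Simulation-based checks run at 10⁶ events per parameter point (the
comparison grid n = 2..10 × r ∈ {0.25, 1, 10}), with 10,000-event burn-in;
ensemble checks use 2,500 replicates. Monte Carlo assertions use 4 standard
errors, computed by batch means (1,000 blocks) because successive jumps are
correlated and an i.i.d. standard error would be anticonservative.
Combinatorial sums use exact integer binomials (`math.comb`) with floating
division last; n up to ~30 is safe in float64, and the stationary-law and
normalization identities are checked exactly with rational arithmetic up to
n = 12. Equal spring weights are required by all analytic routines
(`UnequalWeightsError` otherwise): the displacement algebra relies on plain
averages. The simulator's CSV output stores coordinates at 17 significant
digits and is re-read with round-trip float parsing, so persistence is
lossless.

## Limitations

- The detach algebra, AMSD, LB and UB describe the planar, equal-weight,
  i.i.d.-outreach model only; no 3-D motion, correlated outreach or
  heterogeneous substrate.
- The AMSD bias quantified above means downstream uses needing better than
  ~10% accuracy at intermediate r should use simulation, for which the
  bounds provide a sanity bracket.
- MSD(τ) for τ > 1 has no exact closed form here; the quadratic
  approximation inherits the jump correlations it ignores.
- The synthetic trajectories emulate the idealized jump process, not
  experimental cell tracks: no localization noise, no frame-rate
  discretization of a continuous path, and event-indexed rather than
  time-indexed sampling. Agreement of estimators with theory on these
  trajectories validates the implementation, not the model's fit to data.
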
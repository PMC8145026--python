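# Methods

## The clustering family

The package fits mixtures by minimizing a generalized energy built from a
survival function S (decreasing, S(0) = 1, convex for the Pareto and
exponential families):

    L_S(μ) = (1/τ) Σᵢ S⁻¹( (1/K) Σₖ S(τ‖xᵢ − μₖ‖²) ).

The inner mean is a Kolmogorov–Nagumo average: S maps each squared distance
to a "membership probability", the probabilities are averaged across
clusters, and S⁻¹ maps the average back to the energy scale.  Convexity of S
does two jobs: it extends the domain of S⁻¹ beyond [0, 1] (needed once
component covariances enter through |Σ|^(−1/2) factors), and it yields the
Jensen-gap minorization that the estimation algorithm exploits.

With the generalized Pareto survival S(t) = (1 + βt)^(−1/β), covariances and
proportions enter through the component weight
w(x, μ, Σ) = |Σ|^(−1/2)(1 + τβ‖x − μ‖²_{Σ⁻¹})^(−1/β), giving

    L_{τ,β}(θ) = (1/τβ) Σᵢ [ (Σₖ πₖ wᵢₖ)^(−β) − 1 ].

τ sharpens the average (τ → ∞ drives it toward hard assignment), β controls
the tail weight of the implied components (β → 0 is the Gaussian case).
The classical objectives are boundary members: β → 0 gives maximum-entropy
clustering, and at τ = 1/2 the energy is an affine image of the
Gaussian-mixture negative log-likelihood, τ·L = NLL − n·log((2π)^{d/2});
τ → ∞ gives fuzzy c-means with fuzzifier m = 1 + β; τ → ∞, β → 0 gives
k-means.  β = 0 and τ = ∞ are implemented as separate analytic branches —
floating-point τ cannot reach the fuzzy/k-means regime reliably, and the
β = 0 formulas avoid the 0/0 forms — with the numeric limits exercised only
in tests.

## Estimation

One sweep updates, in this order,

1. responsibilities qₖ(xᵢ) = πₖwᵢₖ / Σₗ πₗwᵢₗ (log-space, max-shifted);
2. centers μₖ = Σᵢ qₖ^{1+β}xᵢ / Σᵢ qₖ^{1+β} (q^{1+β} computed from log q);
3. covariances Σₖ = τ(2 − dβ) · q^{1+β}-weighted scatter about the *new*
   centers;
4. proportions πₖ ∝ (Σᵢ qₖ^{1+β} wᵢₖ^{−β})^{1/(1+β)} with the new centers
   and covariances.

This order makes each step an exact minimizer of the convexity surrogate, so
the energy is non-increasing; the suite verifies descent over a hundred
random datasets and initializations.  Convergence is declared when the
energy changes by less than `rel_tol` (default 1e−8) relatively, with a
`max_iter` cap of 500.

**Covariance scale and its degeneracy.** The update scale τ(2 − dβ) is
positive only for dβ < 2; at the package's own default β = 1 this already
fails in the plane.  The fitter refuses covariance estimation outside the
guard (`DegenerateScaleError`) rather than guessing a workaround; callers
either lower β or fix Σₖ = I.

**Ridge.** Every covariance update is blended as αΣ + (1 − α)σ̂²I with σ̂²
the largest diagonal entry of the raw update (default α = 0.95, α = 1
disables it).  The ridge is a regularization outside the MM derivation: it
perturbs the exact surrogate minimizer and can raise the energy by ~1e−3 on
early sweeps.  Exact monotonicity therefore holds for α = 1 (or whenever Σ
is not estimated), which is the configuration the descent tests assert; the
default keeps the ridge because it guarantees positive-definite updates.

**Initialization.** A Ward-linkage agglomeration cut at K groups supplies
centers, covariances and proportions (the mclust tradition).  The linkage
excludes the 1% of points farthest from the coordinate-wise median
(`trim=0.01`, `trim=0` restores the plain cut): the family's target
densities have polynomial tails — radial exponent 2(1 + β)/β per component —
and a handful of extreme draws otherwise hijack an entire agglomerative
branch, seeding a component on outliers instead of a mode.  In exploratory
runs on the packaged scenario this single change moved center recovery from
roughly half the replicates to all of them.

**Empty clusters.** A component whose q^{1+β} mass underflows (possible in
the exponential branch, where weights decay as exp(−τd²)) is re-seeded at
the point the current mixture explains worst; two consecutive re-seeds of
the same component abort with `ConvergenceError`.  Hard-assignment ties go
to the lowest cluster index, deterministically.

## The synthetic-data generator

`mh_sample` draws from the unnormalized density
p_{τ,β}(x) ∝ (Σₖ πₖ* w(x, μₖ*, Σₖ*))^{1+β}, the law under which the
estimator is consistent.  Integrability requires 2(1 + β)/β > d, which the
module enforces.  The default scenario is a three-component planar mixture —
centers (0,0), (5,5), (−5,−5); proportions (0.5, 0.2, 0.3); one correlated
covariance [[2, −0.5], [−0.5, 1]] and two identity covariances; τ = 0.5,
β = 1; n = 3000 — whose β = 0 member is an exact Gaussian mixture (the
regime used to calibrate the sampler against closed-form marginals).

The kernel mixes, with probability 1/2 each, a local isotropic Gaussian
random walk (scale 1.0) and an independence proposal from a Student-t
mixture (df = 2, scale 1.5·Σₖ*) centred at the true components.  Each move
type satisfies detailed balance on its own — the independence moves use the
exact t-mixture density in the acceptance ratio — so the mixture kernel
targets p_{τ,β} exactly.  A pure local walk was rejected at the design
stage: the default scenario's modes sit ~7σ apart in the β = 0 regime and a
scale-1 walk crosses between them only every few thousand steps, far too
rarely for a 5000-draw sample to represent the mixing proportions.  The t
tails (r^−(df+d) = r^−4 in the plane) match or dominate the target's
component tails for every admissible β, keeping the jumps effective far
out.  Defaults: burn-in 5000, thinning 5, one chain, everything derived
from a single integer seed.  What the generator does *not* emulate: i.i.d.
sampling (draws are a thinned Markov chain with small residual
autocorrelation), model misspecification, noise dimensions, or label noise —
passing recovery tests show the estimator recovers its own generating law,
not robustness to data that violate it.

`simulate_study` runs the center-recovery experiment: for each generating
(τ, β) it samples, fits each requested method with the true K, and scores
center MSE.  The "pareto" method is fitted as the centers-only model
(Σₖ = I, πₖ = 1/K fixed, τ = 0.5, β = 0.5): at the generating default β = 1
the covariance scale degenerates in d = 2, and in exploratory runs the
Σ-estimating variant chased the polynomial tails (mean MSE ~2×10³) while
the fixed-Σ fit recovered the centers (mean MSE ~0.2, vs ~18 for the
Gaussian mixture).  The study sizes used by the tests and the acceptance
script (20 replicates of n = 3000) are a deliberately scaled-down version
of a 100-replicate design, keeping the qualitative ordering testable in
minutes.

## Metrics

Purity weights the best per-cluster precision by cluster size; the F-value
weights the best per-class harmonic mean of precision and recall by class
size (the sum runs over reference classes).  The Centroid Index counts
reference centers that are nearest targets of no estimated center, in both
directions, and reports the maximum — an integer cluster-level error.
Center MSE pairs fitted with reference centers by minimum-cost bipartite
matching before averaging squared distances: fitted components arrive in
arbitrary order, and matching is the only label-invariant pairing (the
alternative, index-order pairing, is not well defined for a fitted model).
Nearest-center ties break toward the lowest index; empty clusters are
dropped from Purity/F-value with a logged warning.

## Numerical choices

- All mixture sums, responsibilities and q^{1+β} weights go through
  log-space with max-shift stabilization; naive evaluation overflows once
  τ‖x − μ‖² is large.
- Pareto S, S⁻¹ and the β → 0 branch use log1p/expm1 identities; β = 0 is
  an exact analytic alias of the exponential family, not a small-β
  evaluation.
- Exact point-center coincidences in the τ = ∞ branch take the analytic
  limit: the coincident center receives the full membership (k-means/FCM
  convention).
- The Fréchet density at t = 0 is the analytic limit 0 for every γ < 0 (the
  essential singularity exp(−t^γ) dominates all powers).
- Convergence tolerance 1e−8 (relative), ridge α = 0.95, trim 1%, MH scale
  1.0 / burn-in 5000 / thinning 5 — all configurable; defaults chosen once
  as described above.

## Known limitations and open points

- **Fréchet τ → 0 limit.** The Fréchet-family energy (S = 1 − exp(−t^γ),
  γ < 0) is sometimes described as reducing to k-means as τ → 0.  Its
  actual limit, verified analytically and numerically here, is
  Σᵢ maxₖ‖xᵢ − μₖ‖² — the sharpened inner average acts on (d²)^γ with γ < 0,
  which inverts the ordering of the distances, and the outer 1/γ power does
  not restore it.  The corresponding estimating-equation weight
  concentrates, for small τ, on each point's *farthest* center.  The energy
  and weights are implemented as defined (the weight is derived as the exact
  gradient of the energy and verified against numerical differentiation);
  the τ → ∞ limit (fuzzy c-means with γ = 1/(1 − m)) is correct and tested.
  One acceptance test records the k-means claim and fails against this
  implementation by construction.
- No Fréchet-family *fitting* is provided (only the energy and weights); no
  automatic selection of K, no multi-start or global search, no
  cross-validation for (τ, β).
- The exponential-branch component weights underflow for centers stranded
  hundreds of scale units from all data; the re-seeding policy recovers the
  common cases but pathological inputs (e.g. exactly duplicated data with
  K > 1) abort with an explicit error rather than returning a degenerate
  fit.
- Covariance estimation is limited to dβ < 2 by the model itself; in high
  dimension this forces β ≪ 1.
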
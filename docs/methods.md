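# Methods

## Generative model

The package models the allocation of `Y` indivisible tokens to `N` spatial
units. Individuals are exchangeable within a unit, so the per-person
assignment process aggregates exactly to one city-level multinomial draw
`y ~ Multinomial(Y, p)` with

    p_i = x_i A_i^(β−1) / Z(β),   A_i = Σ_i' x_i' a(d_ii'; α),
    Z(β) = Σ_i x_i A_i^(β−1).

`A_i` is the effective number of interactions available to an individual in
unit `i`; it depends only on populations and distances, never on the
counts, so it is computed once per kernel scale and cached. The own-unit
term enters with full weight `a(0) = 1` (`A_i ≥ x_i` always); this is the
large-population aggregation of the individual-level sum, and the package
makes no claim about units with only a handful of inhabitants. Kernel
normalisation is irrelevant: rescaling `a(0)` cancels in `p_i`.

Assumptions worth keeping in mind: token assignments are independent given
the parameters (the multinomial has no overdispersion, while real data
overdisperse), individuals are identical, and distance is the only spatial
covariate. The framework compares models; it does not claim any of them is
"true".

## Parameters

| parameter | meaning | support / default |
|-----------|---------|-------------------|
| `β` | scaling exponent (dimensionless) | flat prior on [0, 2] |
| `α` | kernel half-decay scale, km | flat prior on [0, 6371] (Earth radius) |
| family | P, C, G, E | flat model prior 1/4 each |

`a(α; α) = 1/2` calibrates `α` identically across the G and E families, so
their fitted scales are directly comparable. `α = 0` passed to G/E is
mapped exactly to the C kernel (their pointwise limit when all off-diagonal
distances are positive), which also makes the nested chain
C ← (α→0) G,E → (α→∞, β→1) P explicit in code.

## Estimation

With flat priors, MAP estimation is likelihood maximisation on the support.
At fixed `α` the log-likelihood is a linear function of `β` minus
`Y·logsumexp` of linear functions, hence strictly concave in `β` whenever
attractiveness varies across units: a bounded Brent search (tolerance 1e−4)
finds the unique maximiser, and endpoint values are checked explicitly so
boundary maxima are returned as exactly 0 or 2 with a flag. If the profile
is numerically flat (spread < 1e−9, e.g. `α` far beyond the system
diameter), `β̂ = 1` is returned with an `unidentified` flag rather than an
optimizer artefact.

The `α` search scans `{0} ∪ 60` log-spaced points in [0.1 km, 6371 km] —
log spacing because plausible interaction ranges (tens of km) sit four
decades below the prior ceiling — then refines around the best grid point
with a bounded search in `log α` to 1% relative tolerance. On data with no
spatial signal the profile is flat below the smallest inter-unit distance;
any `α̂` in that plateau is equivalent to the city model and the fitted
log-likelihood, not the raw `α̂`, is the meaningful quantity there.

All probability arithmetic is in log space (log-sum-exp): populations span
many orders of magnitude and `β` reaches 2, so naive powers overflow.
Non-integer counts (GDP, road miles) are accepted; the multinomial
coefficient uses the log-gamma extension, is model-independent, and cancels
from every comparison. Zero counts contribute zero to the likelihood —
no unit is ever discarded, unlike in log-log OLS.

## Model selection

The joint evidence `P(M, D) = ∫ P(D|M,θ) P(θ|M) P(M) dθ` is integrated by
trapezoid quadrature accumulated with log-sum-exp. The `β` grid joins a
coarse scan of [0, 2] with a dense window of ±10 posterior standard
deviations around the conditional maximiser (located from the concave fit
plus a finite-difference curvature); the `α` grid joins `{0}`, a log-spaced
scan to the prior ceiling, and a dense window around the MAP. Grids are
refined (node counts doubled) until the implied description length moves by
less than 0.1 byte — well below the few-byte margins that typically
separate competing families — with a warning attached if 6 refinements do
not converge. Reported description length is `D = −ln P(M, D)/(8 ln 2)`
bytes; `ΔD` is taken against the per-capita family and is exactly free of
the shared multinomial coefficient.

A Laplace (Gaussian) approximation of the evidence is available as a
cross-check for interior MAPs. It is refused, by design, when the MAP sits
on the support boundary — above all `α = 0`, where the prior is
discontinuous and the quadratic expansion does not integrate to a Gaussian.

## Uncertainty

`σ_β` is a parametric bootstrap: B = 100 (default) replicate count vectors
drawn from `Multinomial(Y, p̂)` at the MAP, `β` re-fitted on each with `α`
held at `α̂`, and the sample standard deviation reported. Holding `α` fixed
matches reporting `σ_β` alone; the choice of a parametric (rather than
case-resampling) scheme is the package's own, made because the generative
model defines it unambiguously. Non-integer totals are rounded for
resampling with a warning.

## Synthetic data

The generator emulates the shape of national municipal datasets: unit
centroids uniform on a bounding box (default lat ∈ [−18, 0],
lon ∈ [−54, −36], roughly a 2000 × 2000 km continental window), populations
i.i.d. Pareto ("zipf-like") with tail exponent 2, minimum 1000 and cap 1e7
inhabitants (megacity scale; the cap prevents a single unit from swallowing
the synthetic country), and counts drawn from the chosen allocation model.
Default scenarios use N = 200 units and 1e6–1e7 tokens with α* of 10–100 km
— token totals large enough that multinomial noise is small against the
spatial signal, matching the data regimes the method targets.

What the generator does **not** emulate: spatial clustering of cities
(placement is uniform, whereas real systems form metropolitan belts —
identifiability of small α in sparse uniform systems relies on the handful
of close pairs), population–location correlation, measurement error, and
overdispersion relative to the multinomial. Passing recovery tests on this
generator therefore demonstrates correctness of the inference machinery
under the model's own assumptions, not robustness to real-data violations
of them.

## Problem sizes in the test suite

The shipped tests run the full pipeline at N = 50–200 units and up to 1e7
tokens, and model-selection consistency over 20 seeded replicates at
N = 100, Y = 1e5 — sizes chosen so the entire suite completes in about a
minute while every statistical check retains comfortable power. Country
scale runs (thousands of units) use the same code paths; the dominant cost
is the O(N²) attractiveness per α node of the evidence quadrature.

## Known limitations

- Distances are spherical (haversine, radius 6371 km); no ellipsoid.
  Sub-km differences from ellipsoidal geodesics are possible.
- The gravitational kernel's exponent is fixed at 2; no generalised decay
  power.
- Evidence quadrature assumes the likelihood is smooth in `α`; pathological
  multi-peaked α-profiles would need a denser base grid
  (`selection.log_evidence(level=...)` forces one).
- Absolute description lengths for continuous observables depend on the
  chosen token unit (the CLI `--token-unit` flag); `ΔD` comparisons between
  families on the same data do not.
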
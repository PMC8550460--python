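# Methods

## Model

Each of `n` individuals is observed `m` times under a common regime:
`y_ij = f(x_j)' b_i + e_ij`, with `E b_i = beta`, `Cov b_i = sigma² D`
(`D` known, symmetric PSD, possibly singular: zero rows/columns mark
non-random coefficients), and homoscedastic uncorrelated errors. The
regression basis supports polynomials, fractional polynomials (powers
restricted by default to {−2, −1, −0.5, 0, 0.5, 1, 2, 3}; power 0 means
`ln x`, a repeated power multiplies the previous term by `ln x`; arbitrary
real powers behind `allow_any_power=True`), and multi-factor bases with
product interactions. `sigma²` defaults to 1: every criterion scales
monotonically in it, so it never affects which design is optimal.

All design-space geometry is an axis-aligned box; weights of an
approximate design are idealized replication fractions, converted to
integer run counts by largest-remainder apportionment (plain per-point
rounding cannot guarantee the total), ties broken by larger weight then
lower point index.

## Criteria

With `M(xi) = Σ w_l f(x_l) f(x_l)'`, `Delta = m D`, and
`N(xi, Delta) = Delta − Delta (M⁻¹ + Delta)⁻¹ Delta` (the Delta-form is
used throughout because it stays valid for singular `D`; for nonsingular
`D` it equals `(M + Delta⁻¹)⁻¹`):

* prediction variance `phi(x, xi) = f' M⁻¹ f + (n−1) f' N f`; the
  G-criterion is its maximum over the space, bounded below by
  `p + (n−1) tr{(M⁻¹ + Delta)⁻¹ Delta}` for every design;
* the MSE matrix of the stacked predictors is
  `(sigma²/m)[(1/n) J_n ⊗ M⁻¹ + (I − J_n/n) ⊗ N]`, whose spectrum is the
  union of the spectra of the two blocks (the N-block with multiplicity
  `n−1`) — a tested identity;
* the prediction D-criterion is
  `(1/m)[ln det M⁻¹ + (n−1) ln Π_{l≤q} λ_l(N)]`, `q = rank D` computed
  with a relative eigenvalue threshold of 1e-10. **Scale convention:** the
  per-observation `1/m` factor is this package's convention; it leaves the
  optimizer invariant (a positive monotone rescaling for fixed `m`) and
  matches the scale on which the quadratic-basis case-study values are
  quoted. Efficiency ratios use the unscaled value:
  D-efficiency = `exp{[psi(ref) − psi(xi)] / ((n−1)q + p)}` on the raw
  log-eigenvalue criterion; G-efficiency is the plain criterion ratio.
  Both are package conventions for mixed models, where no standard
  efficiency definition exists.

The BLUE of `beta` is the least-squares fit to the average response; each
individual BLUP shrinks the individual least-squares estimate toward it
with matrix weight `D (A + D)⁻¹`, `A = (F'F)⁻¹`.

## Equivalence certificate

A design is G-optimal iff some probability measure `mu*` on its answering
set `A(xi)` (the maximizers of `phi`) makes
`phi_G(x) − tr{M_A M⁻¹ + (n−1) M N M_A N} ≤ 0` on the whole space, with
`phi_G = f' M⁻¹ M_A M⁻¹ f + (n−1) f' N M_A N f` and
`M_A = Σ mu_a f(a) f(a)'`. The certificate machinery:

1. **Answering set.** One-factor spaces: every local maximum of `phi` on a
   dense grid is polished and kept if within a relative `eps` of the
   global maximum. Higher dimensions: the box is split into sub-boxes per
   axis, `phi` maximized on each, splitting doubled until the set size is
   stable for two rounds. The membership default is `eps = 1e-4`;
   `verify_g_optimality` widens it to `tol / phi_bar` because a design
   reported to finite precision keeps near-maximizers spread over that
   tolerance band — with the tight eps the answering set of any rounded
   design collapses and no measure can exist.
2. **Measure search.** The loss is the design-weighted squared sensitivity
   at the design's own support (which must be roots at the optimum),
   optionally plus the squared supremum term. A swarm (64 particles,
   social factor 0.05, up to 1200 iterations) minimizes the support-residual
   loss first; a simplex refinement then minimizes the full loss. A loss
   above 1e-5 is flagged on the report, never hidden.
3. **Verdict.** PASS iff the sensitivity supremum over the space and its
   absolute value at every support point are below the tolerance, default
   `0.02 × phi_bar` — matched to designs reported to three decimals, which
   cannot pass at machine precision. The report carries a G-efficiency
   floor (criterion lower bound over achieved criterion) and serializes to
   text plus a plottable CSV grid of `phi` and the sensitivity.

The fixed-effects D-sensitivity `f' M⁻¹ f − p` and the Atwood-type
D-efficiency floor `p / max-sensitivity` are provided for the classical
checks; the reference invoked for that bound does not print a formula, so
the Atwood form is the package's choice.

## Competitive swarm optimizer

Velocity update for the loser of each random pairing:
`v ← R1∘v + R2∘(x_win − x) + gamma·R3∘(x̄ − x)`, position `x ← x + v`,
with fresh U(0,1) vectors each update. Conventions where the method
description is silent: velocities initialize at zero (uniform-random
available by flag) for reproducibility; positions clip to the box with the
violating velocity component zeroed; weights are parameterized as
nonnegative raw coordinates normalized to the simplex (an all-zero vector
maps to uniform weights). Convergence: successive best values within 1e-6
for 20 consecutive iterations (a single stalled iteration is not
convergence, since only pair losers are re-evaluated). Defaults: 128
particles, `gamma = 0`, 350 iterations (200 for the outer G-search; 32
particles / 128 iterations for inner maximizations in three or more
factors), 5 independent seeded restarts with best-of selection.

During the search the information-type matrix carries a `1e-7` diagonal
ridge for stability. On badly conditioned bases (fractional polynomials)
the ridge biases criterion values by up to ~0.5%, so the final
simplex polish and all reported values run unregularized; the polish
restarts from the canonicalized (sorted, normalized) design until it stops
improving, which escapes the flat-objective stalls typical of min-max
criteria. Inner maximization of `phi` is a deterministic dense grid (2001
points for one factor, 201 per axis for two) plus L-BFGS-B polish from the
best grid cells; three or more factors use a seeded inner swarm. Default
support slots `k = p + 1`, with near-duplicates merged (1e-4 of the factor
range) and weights below 1e-4 pruned afterwards.

## Poisson mixed models

Counts have log intensity `f(x)' b_i` with `b_i ~ (beta, D)`. Under
normal random effects the marginal moments are explicit: mean
`mu(x) = exp(f' beta + f' D f / 2)`, variance `mu + mu²(e^{f'Df} − 1)`,
within-individual covariance `mu_j mu_k (e^{f_j' D f_k} − 1)`. The
quasi-information of an approximate design treats the weights as the
within-individual allocation: `M = G' V⁻¹ G` with `G = diag(w mu) F` and
`V = diag(w mu) + (w w') ∘ S`. When `D = 0` this is exactly the Poisson
GLM information `Σ w λ f f'`. The criterion is `log |M|`; its sensitivity
is defined as `p` plus the directional derivative of `log |M|` toward a
one-point design, computed by a second-order forward difference because
the weight dependence is nonlinear; at `D = 0` it reduces to
`λ f' M⁻¹ f`. The linear predictor is capped at ±50 before
exponentiation, with an error naming the offending point. Large nominal
coefficients make `V` severely ill-conditioned (intensities of order
`e^{15}` and beyond); criterion values in that regime are reported as
computed but should be read with caution.

## Validation strategy and what it does (not) show

Closed forms anchor the numerics: the random-slope design weight
`w* = [sqrt(δ²n² + 4δ + 4) + nδ − 2] / [2δ(n+1)]` (δ = m·d; δ = 0 handled
as the limit 1/2 since the printed expressions are 0/0 there), its
explicit variance and sensitivity functions, and the design-independent
random-intercept value `p + (n−1)δ/(1+δ)` attained by the fixed-effects
D-optimal design. The swarm search is further checked against exhaustive
(support × simplex) grid search on small one-factor problems and against
brute-force weight grids for the `D = 0` Poisson case. The random
model-specification generator draws `D = AA'` (optionally with zeroed
rows/columns to exercise singular dispersion) with polynomial bases up to
degree 3, n ≤ 20, m ≤ 8 on random sub-unit-length intervals — sizes at
which properties (criterion floor, trace identity, eigenvalue structure)
are cheap to test in the hundreds; it emulates the *structure* of real
design problems, not any data-generating process, so passing tests attest
to the correctness of the formulas and the optimizer, not to robustness
against model misspecification in real studies.

Problem sizes in the shipped tests and acceptance script are the
case-study sizes themselves (3–4 support points, p ≤ 4, and the 12-point
four- and five-factor Poisson designs); the exhaustive oracle runs at
support resolution 0.02 and weight resolution 0.005 on a two-parameter
model, chosen as the finest grid whose full enumeration stays interactive.

## Known limitations

* Non-box design regions, exact-design optimization beyond rounding and
  multivariate responses are out of scope.
* The equivalence certificate is numerical (grid + polish + swarm); it is
  not a symbolic proof, and for three or more factors the sensitivity
  supremum relies on the seeded swarm finding the global peak.
* Whether prediction D- and G-optimal designs coincide beyond the
  random-intercept case is open; the package reports cross-efficiencies
  (typically ≥ 0.99 on the case studies) but makes no equivalence claim.
* The Poisson quasi-information follows the construction above; published
  criterion values for the four- and five-factor case studies are not all
  reproducible under it (nor under any variant examined), so those
  comparisons are reported as computed rather than matched.
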
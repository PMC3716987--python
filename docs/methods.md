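# Methods

## Model and notation

A matched-pairs study observes two binary events (A, B) on each of N
independent pairs. Joint cell probabilities p₁₁, p₁₂, p₂₁, p₂₂ (rows =
A, columns = B, success before failure) give marginal success
probabilities p₁₊ = p₁₁ + p₁₂ and p₊₁ = p₁₁ + p₂₁. This is a marginal
(population-averaged) model; the null hypothesis is marginal
homogeneity, p₁₊ = p₊₁, which is equivalent to equality of the
discordant cells, p₁₂ = p₂₁.

## The five tests

**Asymptotic.** z = (n₁₂ − n₂₁)/√(n₁₂ + n₂₁) is the score statistic
for marginal homogeneity; two-sided p = 2(1 − Φ(|z|)). The chi-squared
form z² on 1 df gives identical two-sided p-values (asserted in the
test suite).

**Asymptotic with continuity correction.** The numerator is replaced
by |n₁₂ − n₂₁| − 1, clamped at zero: a correction must never increase
the apparent evidence, and clamping makes the tie case n₁₂ = n₂₁
return p = 1 rather than a p-value that decreases with n. (statsmodels
squares the −1 at ties instead; the test suite cross-checks against
statsmodels everywhere except at ties for exactly this reason.)

**Exact conditional.** Conditionally on n = n₁₂ + n₂₁,
n₁₂ ~ Binomial(n, ½) under H₀. One-sided p = lower tail at
min(n₁₂, n₂₁); two-sided = doubled, capped at 1; exactly 1.0 at a tie.

**Mid-p.** The exact two-sided p minus the point probability f(n₁₂|n);
at a tie, 1 − f(n₁₂|n)/2. Quasi-exact: the nominal level is not
guaranteed, but the evaluation machinery here shows it is respected in
every scenario of the built-in grid.

**Exact unconditional.** Uses all N pairs. For observed z_obs ≥ 0 the
one-sided region is C = {(x₁₂, n): x₁₂ ≥ h(n)}, h(n) = (z_obs√n + n)/2;
membership is decided by the direct inequality z(x) ≥ z_obs − 1e−12
(inclusive at the boundary — when h(n) is an exact integer the
boundary outcome carries the same evidence as the observed one and
belongs in the region; the guard of 1e−12 absorbs floating-point ties).
An equivalent cumulative-binomial indexed form of the region
coefficients is kept as an internal cross-check away from integer
boundaries. Under H₀ the triplet (x₁₂, x₂₁, N − n) is trinomial with
probabilities (p/2, p/2, 1 − p); regrouping by n gives the attained
level P(p) = Σₙ C(N, n) pⁿ(1 − p)^(N−n) cₙ with cₙ the Binomial(n, ½)
mass of the region at discordant total n. The one-sided p-value is
sup₍₀<p<1₎ P(p); two-sided = doubled, capped at 1. A negative z_obs is
handled by swapping n₁₂ and n₂₁ (reversing the region inequality).

### Locating the supremum

P(p) is a Bernstein polynomial in p with coefficients cₙ ∈ [0, 1] and
can be multimodal. The search evaluates P on a uniform grid of 2000
interior points (vectorized in log space, so N in the hundreds never
underflows), refines the five largest local grid values with bounded
scalar maximization (absolute tolerance 1e−8), and finally compares
the two boundary limits P(0⁺) = c₀ and P(1⁻) = c_N exactly. The
boundary step matters: the supremum over the *open* interval equals
the maximum over the closure, and for small |z_obs| the attained level
increases monotonically toward p = 1 (for a tie, toward 1 as p → 0,
where the mass concentrates on the empty-discordant outcome, which
lies in the region). Without it any grid undershoots the supremum by
~5e−4; with it the search agrees with a full-enumeration brute-force
oracle to better than 1e−6 across all tables with N ≤ 12 and random
tables up to N = 30. Both `grid_size` and `refine_tol` are exposed
(CLI flags and function arguments); the defaults reproduce all
reference values.

## Degenerate tables

When n₁₂ = n₂₁ = 0 the asymptotic statistics are undefined; both
asymptotic tests return p = 1 with a `degenerate` flag. The exact
conditional test returns 1.0 (tie rule), the mid-p test returns
1 − f(0|0)/2 = 0.5, and the unconditional test has z_obs = 0, hence a
one-sided supremum ≥ ½ and a two-sided p-value of 1. These conventions
let every outcome of the enumeration receive a p-value.

## Scenario model

A scenario is (N, p₁₊, p₊₁, θ) with θ = p₁₁p₂₂/(p₁₂p₂₁). Solving the
θ definition for p₁₁ yields a quadratic; the root inside the Fréchet
bounds is, with s = p₁₊ + p₊₁,

    p₁₁ = [1 + (θ−1)s − √((1 + (θ−1)s)² − 4θ(θ−1)p₁₊p₊₁)] / (2(θ−1)),

with p₁₁ = p₁₊p₊₁ at θ = 1, and boundary solutions when a margin is 0
or 1 (where θ is formally 0/0; the boundary solution is the natural
limit, and such scenarios put all mass on the empty-discordant
outcome, handled by the degenerate conventions above). A 500-triple
round-trip property test confirms margins and θ are recovered to
1e−10.

No implemented statistic depends on the split of concordant pairs, so
the outcome space is reduced to the (N+1)(N+2)/2 discordant pairs
(x₁₂, x₂₁), trinomially distributed with cells (p₁₂, p₂₁, 1 − p₁₂ − p₂₁).

## Exact evaluation

Type I error rates and power are computed by complete enumeration:
per N and method, a table of two-sided p-values over the outcome space
is built once (memoized; for the unconditional test, one supremum
search per distinct |z_obs|); a scenario's exact rejection probability
is the trinomial mass of {p ≤ α}. The rejection rule is p ≤ α rather
than p < α; on the grids used here the boundary carries no mass (exact
and mid-p p-values are dyadic rationals, never exactly 0.05, and the
asymptotic p-values are continuous), so the choice is immaterial.
Masses are computed in log space with 0·log 0 handled explicitly, so
margin probabilities of exactly 0 or 1 are exact, not NaN.

The built-in grids mirror the evaluation study: 19 N values
(10…100 step 5) × 5 θ values (1, 2, 3, 5, 10) × 101 marginal values
(i/100, generated as rationals over 100 to avoid accumulated 0.01
drift) = 9595 null scenarios, the 2525-scenario subset with N ≤ 30,
and a power grid with N = 1…100, p₁₊ ∈ {0.1, 0.35, 0.6} and
Δ = p₊₁ − p₁₊ ∈ {0.10, …, 0.35}. The full conditional-test evaluation
runs in seconds on one core; the unconditional test is the slow path
and is evaluated on demand (its per-N p-value tables make the
small-sample subregion cheap).

## Sample size

"N to reach power" is defined as the smallest N ≤ Nmax with exact
power ≥ target. Discrete power curves sawtooth in N, so when the
target is not reached by Nmax the returned N is extrapolated from a
least-squares line through the last 10 points (which smooths the
parity sawtooth), rounded up, and flagged. Tabulated summaries average
the per-combination minimal N over the 15 (θ, p₁₊) combinations and
round half away from zero; the averaging convention of published
summary tables of this kind is not fully determined, and reproduction
is asserted to ±1 pair.

## Reporting conventions

P-values are computed and stored at full double precision; display and
table comparisons round half away from zero to 4 decimals (the
precision reference tables print). Proportions of scenarios are
compared at 3 decimals.

## Limitations

- The package evaluates N up to a few hundred comfortably; no special
  large-N path exists for the unconditional test (its cost grows with
  the number of distinct |z_obs| values, roughly N²/4 supremum
  searches per p-value table).
- One-sided p-values are internal/diagnostic; the user-facing result
  is two-sided throughout.
- Confidence intervals for paired differences/ratios, likelihood-ratio
  statistics, and Berger–Boos restriction of the nuisance parameter
  are out of scope.
- The scenario model is the marginal (population-averaged) one; pair-
  specific random-effect structure beyond what θ captures is not
  modeled. Enumeration is exact for the model, which is precisely why
  passing tests certify operating characteristics under the model, not
  robustness to features real paired data may have (clustering beyond
  the pair, time effects, misclassification).
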
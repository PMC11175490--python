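# Methods

## Setting and model

A finite population U of N units is partitioned into H strata U₁,…,U_H with
sizes Nᵢ and stratum-level auxiliary scores xᵢ used for ordering, pairing,
and kernel smoothing. One SRSWOR sample of size nᵢ ∈ {1, 2} is drawn
independently in each stratum (π_k = nᵢ/Nᵢ), and the total t = Σᵢ tᵢ is
estimated by the Horvitz–Thompson total t̂ = Σᵢ t̂ᵢ. All moments in this
package are *design* moments: expectations over repeated sampling from the
fixed finite population. Strata are always held in (x, id) order; file order
is never trusted.

The true design variance is var(t̂) = Σᵢ Vᵢ with
Vᵢ = Nᵢ²(1 − nᵢ/Nᵢ)Sᵢ²/nᵢ under SRSWOR (for nᵢ = 1 this is evaluated
directly from the HT double sum with vanishing joint inclusion
probabilities; the two forms agree algebraically and are cross-checked
against exact enumeration in the tests). With one PSU per stratum no
unbiased variance estimator exists, which is the problem the three
estimators address; their definitions are in the README and module
docstrings.

## Exact moment results used by the oracle checks

* **Collapsed estimator.** For size-2 groups, E[V̂_col] − var(t̂)
  = ½ Σᵢ (tᵢ − Σⱼ c_j(i)tⱼ)² exactly. For a size-3 group (odd H) the
  estimator's variance part over-counts: each group of strata {i,j,k}
  contributes (3/2)(Vᵢ+Vⱼ+V_k) to the expectation rather than the Vᵢ+Vⱼ+V_k
  appearing in var(t̂), so the closed-form bias identity is exact only for
  pure pairings. The identity tests therefore use even H.
* **Kernel estimator.** Expanding E[(t̂ᵢ − Σⱼ d_j(i)t̂ⱼ)²] under independent
  strata gives the exact expectation

      E[V̂_ker] = c_d⁻¹ { Σᵢ [Vᵢ(1 − 2d_i(i)) + Σⱼ d_j(i)² Vⱼ]
                          + Σᵢ (Σⱼ d_j(i)(tᵢ − tⱼ))² }.

  Note the Σⱼ d_j(i)²Vⱼ term: a commonly quoted display factors Vᵢ out of
  that inner sum, which is valid only when the Vᵢ are constant across strata
  (or the weight matrix is symmetric — row normalization breaks symmetry at
  the boundaries). The package implements the exact form;
  `kernel_expectation_exact` matches brute-force enumeration to 1e-10 on
  heteroscedastic toy populations, and reduces to the constant-variance
  display when Vᵢ ≡ V. The reported bias term is the squared-mean part,
  which is the exact bias in the constant-variance case.
* **Normalizing constants.** Per row, 1 − 2d_i(i) + Σⱼ d_j(i)² ≥ (1 −
  d_i(i))² ≥ 0, so c_d ≥ 0 with equality only for the identity matrix
  (bandwidth below the stratum spacing) — that case raises a degenerate-
  bandwidth error rather than dividing by zero. Likewise c_b = 1 − 2Σw/J +
  Σw² ≥ ((Σw − 1)² + J − 1)/J, so with J ≥ 2 pseudo-strata c_b is strictly
  positive for *any* weight vector; a nonpositive c_b can only be supplied
  via the explicit override, and a negative override is honored with a
  warning and the estimate's sign preserved rather than silently
  absolute-valued.

## Bootstrap construction

Singleton strata are merged with the not-yet-merged stratum of smallest
sample size (ties: nearest x, then smallest id); a leftover singleton joins
the nearest pseudo-stratum. With all strata singletons and H even this
reproduces adjacent pairing in x-order. Within pseudo-stratum j, replicate
totals are t̂*_bj = (m_j/n*) Σ of n* with-replacement draws from the m_j HT
contributions, making resampling exactly unbiased for t̂ⱼ (the m_j/n*
rescale is a package choice, exposed as `replicate_scale="raw_sum"` for the
unscaled alternative). The corrector is â_j = 2t̂ⱼ − mean_b(t̂*_bj); fed the
*enumerated* replicate law instead of Monte-Carlo draws its bias component
is exactly zero, and at finite B it is unbiased with O(B^(-1/2))
Monte-Carlo noise. The default `sum_to_one` mode normalizes â to unit sum
before it enters the weight slot of the quadratic form (the correctors have
the units of totals, while the slot expects unit-sum weights); `raw` mode
uses them verbatim.

### Behavior on trending populations — an honest caveat

Because the corrector weights form a single *global* weight vector (one
weighted mean Σⱼ wⱼt̂ⱼ shared by every residual), V̂_boot's quadratic form
measures the dispersion of the stratum totals around that weighted mean.
When the mean function trends across strata (e.g. the linear population),
this dispersion is a fixed-population quantity of order Σᵢ(tᵢ − t̄)² that
dwarfs the sampling variance: on the reference linear configuration
(H = 100, σ = 0.25, n = 2) V̂_boot averages ≈ 46,000 against a true
var(t̂) ≈ 2,650, while the collapsed and kernel estimators' biases are two
orders of magnitude smaller. Its CV across replicates is the smallest of the
three — the estimate is very stable — but stability around the wrong level.
Localizing the corrector weights to pseudo-stratum pairs reduces the form to
(a reweighted version of) the collapsed estimator and recovers its bias, not
less. The estimator is therefore provided as specified, with its diagnostics
(c_b, weights, merge log) exposed, and the simulation harness is the tool
for judging when it is usable: populations whose stratum totals are nearly
exchangeable (flat mean functions, strong prior matching) are the favorable
case; trending totals are not.

## Synthetic-data generator

The generator reproduces the comparison-study conditions: N = 3000 units in
H ∈ {50, 100, 200} evenly sized strata, stratum scores xᵢ = i/H, and unit
values y_k = μ*(xᵢ) + σe_k with e_k iid N(0,1), σ ∈ {0, 0.25, 0.5}. Seven
mean shapes (linear, quadratic, bump, jump, exponential, one- and four-cycle
sinusoids) are affinely rescaled so min = 0 and max = 2 on [0,1], with
extrema located on a 10⁵+1-point grid. The jump function is
(1 + 2(x − 0.5))·1{x ≤ 0.65} + 0.65·1{x > 0.65} — a level drop at 0.65.
Units additionally carry individual auxiliary scores uniform within their
stratum cell ((i−1)/H, i/H] (marginally uniform on (0,1)); without them the
sample mean x̄ would be constant under fixed per-stratum sample sizes and
the conditional study would be vacuous. The population is generated once per
scenario and held fixed across replicates.

What the generator does *not* emulate: unequal stratum sizes, within-stratum
dependence of y on the unit-level score (y depends on x only through the
stratum score), nonresponse, measurement error, or multi-stage clustering.
Passing tests on these populations show correctness of the design
arithmetic and the estimators' relative behavior under clean conditions,
not robustness to those real-data features.

## Simulation harness

Unconditional study: R replicate SRSWOR samples from the fixed population;
per estimator, bias = mean(V̂) − var(t̂), RMSE = √mean((V̂ − var(t̂))²), CV =
sd/mean (sd with divisor R−1). Estimator failures are recorded per replicate
and excluded from summaries, never fatal to a run. Conditional study: the
same replicates sorted by x̄ and cut into n_groups equal consecutive groups
(50 × 20 when R = 1000), reporting per-group mean x̄, conditional bias, and
CRMSE; equally weighted pooling of group biases reproduces the unconditional
bias by construction (asserted to 1e-10).

Seed discipline: one root SeedSequence per run spawns (population stream,
replicate parent); each replicate child spawns (sampling, bootstrap)
streams. Extending R leaves earlier replicates bit-identical, and every run
logs version, configuration, and the root seed.

The option `n_collapsed` restricts pairwise collapsing to the first
n_collapsed strata in x-order (the remaining strata, which must hold nᵢ ≥ 2
units, contribute the standard within-stratum SRSWOR estimate). The default
collapses all strata.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| h (bandwidth) | 0.015 for H = 100 | kept in (1/H, 2/H), the smallest nonempty window on the xᵢ = i/H grid; outside that range a warning (not an error) is raised |
| B (resamples) | 1000 | corrector Monte-Carlo noise is O(B^(-1/2)); B = 200 already makes it negligible next to design noise |
| n* | 2 | resample size per pseudo-stratum, matching the two-PSU design |
| corrector mode | sum_to_one | `raw` implements the unnormalized form verbatim |
| R (replicates) | 1000 | 50 × 20 grouping in the conditional study |
| σ | 0.25 | unit-level noise sd; 0 makes var(t̂) = 0 under nᵢ = 2 so empirical biases equal the closed forms exactly |

The test suite and acceptance script run reduced problem sizes chosen so the
Monte-Carlo assertions are still sharp: R = 200/B = 200 for the directional
comparison, R = 1000/B = 20 (N = 1000, H = 50) for the conditional-structure
checks, B = 10⁵ for the corrector-vs-exact-law comparison, and enumeration
capped at 10⁶ outcomes with exact `fractions.Fraction` probabilities (floats
are binary rationals, so rational moments of float-valued statistics are
exact).

## Numerical choices and degenerate inputs

* Enumeration probabilities exact by default; float fallback at 1e-12.
* c_d = 0 / identity weight matrix → degenerate-bandwidth error; corrector
  sum = 0 → degenerate-corrector error; single pseudo-stratum (c_b = 0) →
  degenerate-normalizer error. Nothing is silently clamped.
* Constant mean functions have no [0,2] rescale → explicit error.
* N not divisible by H, R not divisible by n_groups, nᵢ > Nᵢ → config
  errors before any computation.
* CSV readers name the missing column, the inconsistent stratum, or the
  offending row in their error messages; round-tripping a sample preserves
  every field.

## Known limitations

* Single-stage, equal-probability-within-stratum designs only; no πps,
  multi-stage, nonresponse, or calibration machinery.
* The kernel weights use no boundary correction; boundary rows are
  asymmetric and contribute most of the kernel estimator's bias.
* The collapsed-bias closed form is exact only for pure pairings (see
  above); odd H introduces a size-3 group with an over-counted variance
  part.
* The bootstrap-corrected estimator's global-weight form is faithful to its
  specification but, as documented above, tracks between-stratum spread on
  trending populations; treat its output as a diagnostic alongside the
  collapsed and kernel estimates rather than a drop-in replacement.
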
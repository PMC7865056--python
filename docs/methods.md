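# Methods

## Model

Ages at death are modelled as a three-component mixture density on `x ≥ 0`:

```
f(x; θ) = η·f_I(x) + (1−η)·[ α·f_m(x; ξ_m, ω_m, λ_m) + (1−α)·f_M(x; ξ_M, ω_M, λ_M) ]
```

with `f_I` the unit-scale half normal and `f_m`, `f_M` Azzalini skew
normals. The half normal's scale is pinned at 1: it fixes the infant mode at
age 0, makes the infant-component variance a function of `η` alone
(`Var = η²(1−2/π)`), and removes an identifiability problem between the
infant scale and the left tail of the young component. Assumptions baked
into the model: deaths are independent across individuals; the period
schedule is a single density (no cohort structure); the age pattern has at
most one young hump and one adult hump.

Counts on single-age bins are multinomial: bin `x` covers `[x, x+1)`, the
last bin is open-ended (the HMD "110+" convention), and
`p_x(θ) = F(x+1) − F(x)` with the mixture cdf `F`. The log-likelihood is
`Σ_x D_x log p_x`, with the multinomial coefficient dropped (constant in θ)
and probabilities floored at 1e−300 before the log.

### Mass below age zero

The skew components place a small amount of mass at negative ages (about
7e−5 for the reference scenario). We deliberately do **not** renormalize:
renormalization would silently invalidate the closed-form `e0`
decomposition. Instead the bin probabilities sum to the in-range mass
`1 − F(0)`, the decomposition warns when that mass drops below 0.999, and
the synthetic-count generator refuses parameter vectors with more than 1%
out-of-range mass. The one exception is the noise-free recovery study (see
below), where cell probabilities are renormalized so that the generating
vector is an exact stationary point of the objective.

## Parametrizations

The likelihood is fitted in **centered coordinates** per skew component —
mean `μ`, standard deviation `σ`, standardized skewness `γ` — because the
direct coordinates `(ξ, ω, λ)` produce a ridged surface on which local
optimizers routinely stall. The maps are closed-form both ways; the inverse
recovers `δ = λ/√(1+λ²)` from `γ` via the cube-root inversion of
`γ(δ) = ((4−π)/2)·(δ√(2/π))³/(1−2δ²/π)^{3/2}`. Skewness is constrained to
`|γ| < 0.99527`, the supremum attainable by the family; values at or beyond
it are rejected rather than clipped.

`σ_m`, `σ_M` are standard deviations in years throughout. (Some descriptions
of this model family call them "variances", but their magnitudes — 10–20 on
the age scale — are only coherent as SDs; we expose SDs and note the
terminology discrepancy here.)

## Estimation

1. **Global stage** — differential evolution over the 8-dimensional box
   (defaults: `η ∈ [0, 0.5]`, `α ∈ [0, 0.9]`, `μ_m ∈ [5, 75]`,
   `σ_m ∈ [1, 40]`, `μ_M ∈ [40, 105]`, `σ_M ∈ [2, 30]`,
   `|γ| ≤ 0.95`), population 10×dim initialized uniformly in the box,
   crossover 0.9, differential weight dithered in [0.5, 1.0], 1000
   generations. Early stopping is disabled by default: the likelihood's
   magnitude grows with the death count, so relative population-spread
   criteria fire long before convergence.
2. **Local stage** — bounded L-BFGS-B refinement of the DE winner.
3. **Restart policy** — if the refiner improves the log-likelihood by more
   than 1 unit, or the solution sits on a bound, DE is rerun with doubled
   population and generations (up to 2 restarts). A weight (`η`, `α`)
   resting on its *lower* bound 0 is a demographically meaningful estimate
   (absent component) and does not trigger a restart. Non-convergence is
   reported via a warning and `converged=False`, never silently.
4. **Label guard** — the likelihood is invariant to swapping the two skew
   components; estimates are relabelled (swap components, `α → 1−α`) so the
   young component always has the smaller mean.

The objective is vectorized over candidate vectors (one Owen's-T-based
skew-normal cdf call per component per generation), which keeps a full
global+local fit of a 111-bin count vector to a few seconds on one CPU.
All stochastic steps take an explicit seed; an unseeded fit draws a seed
from entropy and logs it.

Default bounds are engineering choices: generous demographic ranges that
exclude most label swaps. They are overridable per coordinate (CLI:
`--bounds file.json`).

## Uncertainty

**Bootstrap.** B multinomial resamples of the observed total from the
empirical age distribution (nonparametric; a parametric variant resamples
from the fitted probabilities), each refitted by a warm-started local
refinement at the point estimate. A full global search per replicate is
available behind `refit="full"` but is rarely warranted: when the resample's
likelihood is unimodal the warm-started refit finds the same optimum, and
the expensive alternative changes the spread estimates only through the
small fraction of genuinely bimodal resamples. Replicates that fail to
refit are dropped and counted; results are flagged when more than 5% of
replicates fail or sit on a bound. SEs are per-coordinate standard
deviations across draws; 2.5/97.5 percentile intervals are also reported.

A caveat the package makes visible rather than hiding: when the premature
component is weak (small `α`), the bootstrap distribution of its
coordinates can be **bimodal** — a minority of resamples place their global
MLE in a second likelihood basin. The SD then mixes within-basin spread
with the between-basin separation and becomes sensitive to the
minority-basin fraction, so SE estimates for `μ_m`, `σ_m`, `γ_m` stabilize
only slowly in B. The well-identified coordinates (`η`, `μ_M`, `σ_M`,
`γ_M`) do not show this.

**Recovery study.** From a known vector θ\*, the exact binned death
distribution is computed (no sampling noise; sampled counts are an option),
and the *local* refiner alone is launched from `n_starts` vectors drawn
uniformly in the bounds box. The rescaled bias `RE = (θ* − θ̂)/θ*` is
summarized per coordinate by its quartiles; coordinates whose true value is
0 are excluded from RE and summarized by absolute bias instead. Local-only
refinement is the point of the design — it exposes which coordinates are
identifiable from a bad start. On the reference scenario the premature
skewness `γ_m` is by far the worst-identified coordinate (median |RE| about
0.13 and an interquartile range of several units, against ~1e−5 for `μ_M`).

## Synthetic data

`simulate_death_counts` draws one multinomial sample of N deaths from the
binned mixture probabilities (renormalized over the in-range mass). The
reference scenario is a low-mortality male population: `η = 0.02`,
`α = 0.08`, young component `(μ, σ, γ) = (45, 15, 0.10)`, adult component
`(80, 10, −0.30)` — 2% infant deaths, a flat premature component, and a
left-skewed adult hump with modal age ≈ 81.6. This generator reproduces
exactly the statistical structure the estimator assumes (multinomial counts
from a mixture). Real death counts additionally carry age heaping,
migration-driven exposure errors, cohort effects and overdispersion, none of
which are emulated — so passing recovery tests here demonstrates correctness
of the estimator, not robustness of the model to real-data artefacts.

## Life tables

The HMD reader handles the `Deaths_1x1`/`Exposures_1x1` plain-text dialect
("110+" open age, "." for missing). Life tables use the standard
single-decrement recursions: `m_x = D_x/E_x`, `q_x = m_x/(1+(1−a_x)m_x)`,
`a_x = 0.5` for ages 1+, open age `q = 1`, `e_Ω = 1/m_Ω`. For `a_0` the
default is the Andreev–Kingkade piecewise-linear rule in `m_0`
(sex-specific; the mean of the male and female rules for combined-sex
data), with the classic `0.07 + 1.7·m_0` available via `a0_rule="classic"`.
The normalized `d_x` column is the distribution the mixture fits; fitting
fractional `d_x` weights instead of integer counts changes only the
curvature, not the location, of the likelihood.

## Problem sizes and tolerances

Simulation-based checks in the test suite use one million deaths for the
headline recovery run (asymptotic-accuracy thresholds: `η` ±0.005, `μ_M`
and `σ_M` ±0.3 years, `α` ±0.02, L1 fit error < 0.01), 200 random starts
for the recovery study, and B = 200 bootstrap replicates on 1e5-death
samples — sizes at which each check is informative while the full suite
stays desk-scale. Quadrature oracles (scipy adaptive quadrature) verify
densities, cdfs and moments to 1e−7–1e−10; the coordinate maps round-trip
to 1e−8; the skew-normal mode is found by bounded scalar minimization on
`[ξ−5ω, ξ+5ω]` (unimodality guarantees correctness) to better than 1e−6.

## Known limitations

* The closed-form `e0` uses untruncated component means; the error is the
  (asserted tiny) mass outside `[0, Ω]` and is not corrected.
* With a weak premature component the likelihood can be multimodal in the
  m-coordinates; global search mitigates but cannot abolish this, and
  bootstrap SEs for those coordinates inherit the instability described
  above.
* No cohort tables, no abridged (5-year) tables, no rate smoothing, no
  covariates, and no Hessian-based standard errors (bootstrap only).
* The multinomial treats counts as independent given θ; overdispersed real
  data will yield anti-conservative bootstrap SEs.
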
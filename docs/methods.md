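# Methods

`behavmeta` re-implements, as a tested pipeline, a longitudinal analysis of
behavioral correlations in a wild passerine population: yearly phenotypic
correlations treated as study-level effect sizes in a random-effects
meta-analysis, moderated by year-level socio-ecological covariates, with the
correlations further partitioned into within- and between-individual
components from repeated assays. This note records the models, the
parameter choices, and the places where the design was genuinely open.

## Data model

One row per behavioral assay of a male during courtship: season (year),
individual identity (missing when the bird was never captured and ringed),
assay order and day-of-season, and three behaviors — novelty avoidance
(latency difference with vs. without a novel object, s), aggression
(latency to attack a decoy male, s, recorded as 301 s when no attack
occurred within the 5-minute assay), and risk-taking (flight initiation
distance, m). All three are stored so that a **smaller value means a bolder
bird**; a positive correlation between any two stored traits therefore
always reads "bold in one context, bold in the other".

## Effect sizes

For each year and trait pair, the Spearman correlation (midranks for ties;
censored 301-s records form tie blocks and stay in the data) of
**first assays only**, on pairwise-complete cases. Non-captured, anonymous
males contribute: excluding them would import the trappability bias (shy
birds are harder to trap) straight into the correlations. Effects enter
the meta-analysis as Fisher-Z values `z = atanh(r)` with sampling variance
`1/(n − 3)` (the plain normal-theory variance, not the 1.06/(n−3) Spearman
variant). `|r|` is clamped at 0.9999 before `atanh` so a degenerate
correlation keeps a finite weight. Years with fewer than five
pairwise-complete males are dropped (configurable via `min_n`).

## Random-effects meta-analysis

DerSimonian–Laird: fixed-effect weights `w_i = 1/v_i` give
`Q = Σ w_i (z_i − z̄_FE)²` on `k − 1` df; the moment estimator
`τ̂² = max(0, (Q − df) / (Σw − Σw²/Σw))` feeds random-effect weights
`1/(v_i + τ̂²)`. CIs and p-values are normal-theory on the Z scale,
reported back on the correlation scale via `tanh`.
`I² = 100·τ̂²/(τ̂² + s̃²)` with the typical within-year variance
`s̃² = (k−1)Σw/((Σw)² − Σw²)` — the convention of the standard
meta-analysis tooling (our `dl_pool` matches R's `metafor::rma(method
= "DL")` to 10 decimals in the test suite; `metafor` is used there only as
an independent oracle).

Meta-regression uses the method-of-moments residual τ² generalized to a
design matrix (`τ̂² = max(0, (Q_E − (k − p)) / tr(P))` with
`P = W − WX(X'WX)⁻¹X'W`), then WLS with weights `1/(v_i + τ̂²)` and a Wald
omnibus `Q_M` on the non-intercept coefficients. Moderators are only
examined for pairs whose effects are actually heterogeneous (default gate:
`p_Q < 0.05` or `I² > 25%`) — testing moderators of a homogeneous set is
meaningless. Known behavior documented by the tests: with τ² estimated at
k = 8 the normal-theory Wald test is mildly conservative (≈3.8% rejections
at the nominal 5%), and the normal-theory DL interval undercovers slightly
under real heterogeneity (≈92.5% instead of 95% at k = 8, τ = 0.15) —
the classic motivation for Knapp–Hartung adjustments, which we deliberately
do not apply to stay consistent with the printed CI arithmetic.

Two pooled correlations are compared with
`z = (atanh r₂ − atanh r₁)/√(1/(n₁−3) + 1/(n₂−3))`, and a two-sided p can
be reconstructed from a published estimate with its CI by reading the SE
off the symmetric-on-Z interval.

## Variance partitioning

Random-intercept LMMs, `y = Xβ + b_ind + e` with the assay date as the
fixed covariate, fitted by a fully conjugate Gibbs sampler written for this
package: normal full conditionals for `β` (flat prior) and the individual
effects, inverse-gamma for univariate variances, inverse-Wishart (sampled
via the Bartlett decomposition) for the 2×2 matrices of bivariate fits.
Derived per draw: repeatability `R = V_ind/(V_ind + V_e)` per trait and,
from the bivariate fits, the between-individual correlation `r_ind` and
within-individual correlation `r_e`. Summaries are posterior means with
central 95% credible intervals. Only identified (captured) birds enter
these fits — exactly the subsample the field protocol can re-assay.

**Prior.** Weakly informative inverse-gamma(0.001, 0.001) on each variance.
For 2×2 covariances the matching inverse-Wishart is `IW(0.002·I, ν₀ =
1.002)`: the marginal of each diagonal of `IW_p(Ψ, ν)` is
`IG((ν−p+1)/2, ψ_ii/2)`, so `ν₀ = 1.002`, `ψ_ii = 0.002` reproduces
IG(0.001, 0.001) at p = 2. A side effect worth knowing: the implied
marginal prior on a correlation, `∝ (1−r²)^((ν−3)/2)`, is U-shaped at this
ν, so when a trait's between-individual variance is essentially zero the
posterior of `r_ind` piles near ±1 and mixes poorly. We do not hide this:
such fits are reported with their PSRF and flagged as weakly identified.
They barely affect downstream reconstruction because their weight there is
`√(R_x R_y) ≈ 0`.

**Schedules.** Defaults are desk-scale: 3 chains × 20,000 iterations,
burn-in 5,000, thinning 10 — for these model sizes (tens to hundreds of
individuals) this gives Monte-Carlo errors far below the reported
precision; heavier schedules (e.g. 1.3M/300k/1000) are plain configuration.
The many small per-year fits in the analysis scripts and the reproduction
script use 2 chains × 6,000/2,000/5, chosen once as sufficient for
posterior means of these low-dimensional models. Convergence is monitored
with the Gelman–Rubin PSRF across chains (gate < 1.1).

**Between-year repeatability** uses the first assay per (individual, year)
of birds seen in ≥ 2 years. The synthetic generator deliberately does not
model survival across years, so on simulated data this model is reported
as unidentified rather than silently fitted.

## Decomposition and reconstruction

The expected phenotypic correlation from components is

    r_P = r_ind·√(R_x·R_y) + r_e·√((1−R_x)(1−R_y))

the standard two-term decomposition for random-intercept models. Two
audits tie it down: (i) applied to the generator's ground truth it matches
the empirical single-observation correlation within 0.03 at n = 5000; (ii)
end-to-end, expected values built from posterior-mean components on the
captured subsample correlate strongly (r > 0.7 required, ≈0.99 observed at
n = 300/year) with the phenotypic correlations observed in full samples
across 15 year × pair cells. Posterior means (not modes) of components are
used.

## Weighted inference across years

Year-level statistics are compared with t-tests whose weights are the
year-specific numbers of individuals: weighted mean `Σwv/Σw`,
frequency-weighted variance rescaled by `n/(n−1)` (n = number of years),
`t = (mean − μ₀)/√(var/n)` on `n − 1` df, two-sided. Paired comparisons
apply the one-sample test to per-year differences, each year weighted by
the **pairwise minimum** of the two traits' sample sizes — the convention
is our reconstruction (it reproduces the published t statistics to ±0.02
from the rounded table inputs; alternatives such as reliability weights do
not), flagged as such rather than asserted. Independent p-values are
combined with Fisher's method, `−2Σln p ~ χ²(2k)`.

## Moderators

Four year-level covariates: mean daily spring temperature (pass-through;
its derivation from station data is out of scope), previous-year nest
predation rate (predation happens after the assays, so it acts with a
one-year lag; the first study year consequently drops out of designs using
it), a per-day competition index, and the proportion of juveniles among
assayed males. The competition index is (breeding efforts / available
boxes) / (length in days of the **shortest** window containing ≥ 90% of
breeding-initiation dates); the phrasing "interval containing 90% of
efforts" is ambiguous, so the central 5th–95th-percentile alternative is
exposed behind `window="central"`. Proportion-scale covariates are
square-root transformed before modeling. A collinearity screen flags
moderator pairs with `|r|` above 0.8 for exclusion from the joint model.

## Synthetic-data generator

The generator is the testing ground for every stage. Per year,
`y_ij = μ + date_slopes·date_ij + b_i + e_ij` with `b_i ~ MVN(0, Σ_ind[year])`
and `e_ij ~ MVN(0, Σ_e[year])`, then: aggression latency censored at 301 s
(flagged), the novelty-avoidance difference clamped at ±301 s, flight
distance floored at 0.5 m and aggression at 1 s (a bounded latency cannot
be negative; at the default scales the floor collects the "attacked
immediately" birds as a tie block). Capture is Bernoulli with
`logit p = intercept + slopes·z-scores` of the first-assay behaviors;
non-captured birds lose their identity and are never re-assayed. Captured
birds in repeat seasons draw their assay count from a distribution on 1..6
whose conditional mean given ≥ 2 is 2.74. Each year has an independent RNG
substream (spawned in year order), so appending a season never perturbs
earlier draws, and identical configuration + seed yields byte-identical
CSV output.

The study-like default (`study_like_config`) emulates the published
design: 8 seasons with the published per-year sample sizes (17–56 males),
repeat effort in five seasons, trait means/SDs matched to the published
yearly summaries, repeatabilities (0.22, 0.16, 0.45) with risk-taking most
repeatable, the strongest between-individual correlation on the
aggression/risk-taking pair (0.65), and a year-varying (sign-flipping)
novelty-avoidance/aggression correlation acting on both components so that
this pair — and only this pair — shows detectable heterogeneity, as in the
study. The simulated moderators are *not* causally coupled to the
correlation structure, so null meta-regression results on simulated data
are correct behavior, not a defect.

What the generator does **not** emulate: skewed latency distributions
(traits are conditionally Gaussian), survival and re-occurrence of males
across years, territory/spatial structure, and the two-stage latency assay
itself (novelty avoidance is simulated directly as the difference, with
censoring approximated by clamping the difference — the analysis only ever
sees the difference). Passing tests therefore validate the statistical
machinery under the stated model, not the field protocol.

## Numerical choices and degenerate inputs

- Ties: midranks everywhere; a constant vector raises an explicit error
  rather than returning NaN.
- `k = 1` meta-analysis: passthrough with τ² = Q = I² = 0.
- Rank-deficient moderator designs raise an error naming the collinear
  columns; years with missing moderators are dropped with a warning.
- Non-PSD truth covariances are rejected up front (eigenvalue ≥ −1e−10)
  naming the offending matrix; numerically non-PD inverse-Wishart draws are
  resampled with a diagnostic counter (in practice zero).
- Weighted t with an exactly zero numerator returns t = 0 even when the
  weighted variance is also zero.
- All stochastic stages take explicit seeds; pipeline reports are
  byte-reproducible given the seed.

## Problem sizes used in validation

Chosen once, as informative-but-quick study conditions: DL coverage at the
study's own k = 8 / year sizes with true mean Z = 0.33 and τ = 0.15
(20,000 replicates, Monte-Carlo se ≈ 0.2 points); heterogeneity type-I
error at τ = 0 (5,000 replicates); Gibbs recovery at n = 200 × 4 repeats
(R = 0.5, r_ind = 0.6, r_e = 0.1); decomposition consistency at n = 5,000
single observations; reconstruction across 5 years × 3 pairs at n = 300
males/year with capture bias and censoring active.

## Known limitations

- DL normal-theory intervals undercover modestly under heterogeneity at
  small k (documented above); REML/Knapp–Hartung variants are standard
  remedies but are out of scope here by design.
- `r_ind` is weakly identified whenever a trait's repeatability is near
  zero or the number of re-assayed birds is small (16–28 in the emulated
  design); the package reports this honestly via PSRF flags and wide
  credible intervals instead of suppressing the fits.
- The paired-weight convention (pairwise minimum N) and the exact prior
  parameterization for 2×2 covariances are reconstructions of
  under-specified published choices; both are pinned by tests against the
  published statistics and by prior-sensitivity reasoning recorded above.
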
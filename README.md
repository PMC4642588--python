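# behavmeta

Meta-analytic and mixed-model pipeline for **among-year variation in
behavioral correlations** in longitudinal field studies of animal
personality.

Behavioral syndromes are between-individual correlations of functionally
distinct behaviors. A correlation measured in one breeding season need not
exist in the next: phenotypic correlations mix between-individual
(`r_ind`) and within-individual (`r_e`) components, and either can track
the environment. This package implements the analysis chain needed to ask
that question with repeated field assays — here modeled on courtship
assays of male collared flycatchers (*Ficedula albicollis*): novelty
avoidance and aggression (latencies, censored at the 301-s assay ceiling)
and risk-taking (flight initiation distance), all oriented so smaller =
bolder.

The chain:

1. **Effect sizes** — per year and trait pair, Spearman correlations
   (midranks for censoring ties) of first assays, as Fisher-Z effects with
   variance `1/(n − 3)`.
2. **Random-effects meta-analysis** — DerSimonian–Laird pooling across
   years, heterogeneity (`Q`, `τ²`, `I²`), z-comparison of pooled effects,
   and method-of-moments **meta-regression** on year-level socio-ecological
   moderators (temperature, lagged predation, per-day competition index,
   age structure), gated on detected heterogeneity.
3. **Variance partitioning** — univariate and bivariate random-intercept
   mixed models fitted by a conjugate Gibbs sampler (inverse-gamma /
   inverse-Wishart priors, Gelman–Rubin PSRF gate < 1.1), yielding
   repeatabilities `R = V_ind/(V_ind + V_e)`, `r_ind`, and `r_e` with 95%
   credible intervals.
4. **Reconstruction** — expected phenotypic correlation
   `r_P = r_ind·√(R_x R_y) + r_e·√((1−R_x)(1−R_y))`, validated against the
   observed correlations.
5. **Weighted inference** — t-tests across years weighted by year sample
   sizes, and Fisher's combined probability.
6. **Synthetic data** — a generator with known ground truth (hierarchical
   MVN with date effects, censoring, behavior-dependent capture
   probability, within-season repeats) that makes every stage testable
   without any field data.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

```python
from behavmeta import (
    study_like_config, simulate_multiyear, year_effect_table, dl_pool,
)

table = simulate_multiyear(study_like_config(seed=1))
effects = year_effect_table(table)          # first assays, all males
for pair in ("NA-AG", "NA-RT", "AG-RT"):
    res = dl_pool([e for e in effects if e.pair == pair])
    print(f"{pair}: pooled r = {res.pooled_r:.3f} "
          f"({res.ci95_r[0]:.3f}/{res.ci95_r[1]:.3f}), "
          f"Q = {res.Q:.2f}, P_Q = {res.p_Q:.3f}, I2 = {res.I2:.1f}%")
```

prints

```
NA-AG: pooled r = 0.174 (-0.088/0.414), Q = 36.72, P_Q = 0.000, I2 = 80.9%
NA-RT: pooled r = 0.218 (0.108/0.323), Q = 1.86, P_Q = 0.967, I2 = 0.0%
AG-RT: pooled r = 0.240 (0.130/0.343), Q = 3.23, P_Q = 0.863, I2 = 0.0%
```

Read: in this simulated 8-season study the novelty-avoidance/aggression
correlation flips sign between years (strong heterogeneity, I² = 81%, so
its pooled mean is not interpretable as a stable syndrome), while the two
risk-taking correlations are homogeneous and positive — exactly the
situation the moderator regression (step 2) and the within/between
partition (step 3) are there to dissect.

## The analysis, step by step

Numbered drivers under `analysis/` run the whole study design on simulated
data and write flat tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1        # assays + moderator table
python analysis/02_effect_sizes.py             # year x pair Fisher-Z effects
python analysis/03_meta_analysis.py            # pooling + heterogeneity
python analysis/04_meta_regression.py          # moderators, gated pairs only
python analysis/05_variance_partition.py       # R, r_ind, r_e per season
python analysis/06_decomposition.py            # reconstruction audit
python analysis/07_weighted_tests.py           # weighted t, Fisher combined
```

The same stages are available programmatically (`behavmeta.run_pipeline`)
and through a thin CLI (`behavmeta run-all --seed 1 --out results/pipeline`).

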
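"""Calibration and recovery experiments for the pipeline's inference layer.

Each function sets up a simulation at fixed, pre-registered study
conditions, runs the relevant stage of the pipeline, and returns the
measured operating characteristic (coverage, type-I error, recovery error,
reconstruction correlation).  The same experiments back the validation
tests and the reproduction script, so their problem sizes are chosen to be
informative yet quick: see the methods note for the rationale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .decomposition import expected_phenotypic_r, reconstruction_validation, truth_decomposition
from .effects import EffectSize, year_effect_table
from .meta import dl_pool
from .studydata import PAIRS, TRAIT_CODES, yearly_summaries
from .synthetic import (
    CaptureModel,
    TruthConfig,
    assemble_covariances,
    simulate_multiyear,
)
from .varcomp import MixedModelSpec, gibbs_bivariate, gibbs_univariate

#: Year-specific first-assay sample sizes of the emulated study design.
STUDY_YEAR_N = tuple(
    int(max(r.na_n, r.ag_n, r.rt_n)) for r in yearly_summaries().itertuples()
)


def _effects_from_z(z: np.ndarray, v: np.ndarray) -> list[EffectSize]:
    return [
        EffectSize(i, "NA-AG", float(np.tanh(zz)), float(zz), float(vv), int(3 + round(1 / vv)))
        for i, (zz, vv) in enumerate(zip(z, v))
    ]


def dl_coverage_experiment(
    seed: int,
    n_reps: int = 2000,
    true_z: float = 0.33,
    tau: float = 0.15,
    year_n: tuple = STUDY_YEAR_N,
) -> float:
    """95% CI coverage of the DL pooled effect, in percent.

    Eight yearly effects per replicate with the study's sample sizes, a true
    mean on the Z scale and genuine between-year spread ``tau``.
    """
    rng = np.random.default_rng(seed)
    v = 1.0 / (np.asarray(year_n, dtype=float) - 3.0)
    hits = 0
    true_r = np.tanh(true_z)
    for _ in range(n_reps):
        z = true_z + rng.normal(0, tau, len(v)) + rng.normal(0, np.sqrt(v))
        res = dl_pool(_effects_from_z(z, v))
        hits += res.ci95_r[0] <= true_r <= res.ci95_r[1]
    return 100.0 * hits / n_reps


def heterogeneity_type1_experiment(
    seed: int, n_reps: int = 5000, year_n: tuple = STUDY_YEAR_N
) -> float:
    """Rejection rate (percent) of the Q test at alpha=0.05 when tau = 0."""
    rng = np.random.default_rng(seed)
    v = 1.0 / (np.asarray(year_n, dtype=float) - 3.0)
    rejections = 0
    for _ in range(n_reps):
        z = 0.2 + rng.normal(0, np.sqrt(v))
        res = dl_pool(_effects_from_z(z, v))
        rejections += res.p_Q < 0.05
    return 100.0 * rejections / n_reps


def gibbs_recovery_experiment(seed: int, spec: MixedModelSpec | None = None) -> dict:
    """Recovery of R = 0.5 and (r_ind, r_e) = (0.6, 0.1) at n = 200 x 4.

    Returns the univariate and bivariate posterior means, their absolute
    errors against the truth, and the worst PSRF across all parameters.
    """
    if spec is None:
        spec = MixedModelSpec(seed=seed)
    sigma_ind, sigma_e = assemble_covariances(
        (1.0, 1.0, 1.0), (0.5, 0.5, 0.5), {"NA-AG": 0.6}, {"NA-AG": 0.1}
    )
    cfg = TruthConfig(
        years=(2001,),
        n_individuals_per_year=200,
        repeats_distribution={4: 1.0},
        mu=(0.0, 20.0, 20.0),
        sigma_ind=sigma_ind,
        sigma_e=sigma_e,
        censor_threshold=1e9,
        capture_model=CaptureModel(intercept=np.inf),
        seed=seed,
    )
    table = simulate_multiyear(cfg)
    uni = gibbs_univariate(table, "NA", replace(spec, seed=spec.seed))
    biv = gibbs_bivariate(table, "NA", "AG", replace(spec, seed=spec.seed + 1))
    return {
        "R_mean": uni.mean("R_NA"),
        "R_abs_error": abs(uni.mean("R_NA") - 0.5),
        "r_ind_mean": biv.mean("r_ind"),
        "r_ind_abs_error": abs(biv.mean("r_ind") - 0.6),
        "r_e_mean": biv.mean("r_e"),
        "r_e_abs_error": abs(biv.mean("r_e") - 0.1),
        "max_psrf": max(uni.max_psrf(), biv.max_psrf()),
    }


def decomposition_consistency_experiment(seed: int, n: int = 5000) -> float:
    """Max |observed - expected| phenotypic correlation over the three pairs.

    Single observation per bird at n individuals; the observed Pearson
    correlation is compared with the decomposition formula applied to the
    generator's ground truth.
    """
    sigma_ind, sigma_e = assemble_covariances(
        (1.0, 1.0, 1.0),
        (0.5, 0.4, 0.3),
        {"NA-AG": 0.6, "NA-RT": 0.3, "AG-RT": 0.5},
        {"NA-AG": 0.1, "NA-RT": 0.1, "AG-RT": 0.2},
    )
    cfg = TruthConfig(
        years=(2001,),
        n_individuals_per_year=n,
        repeats_distribution={1: 1.0},
        mu=(0.0, 20.0, 20.0),
        sigma_ind=sigma_ind,
        sigma_e=sigma_e,
        censor_threshold=1e9,
        capture_model=CaptureModel(intercept=np.inf),
        seed=seed,
    )
    table = simulate_multiyear(cfg)
    idx = {"NA-AG": (0, 1), "NA-RT": (0, 2), "AG-RT": (1, 2)}
    worst = 0.0
    for pair, (i, j) in idx.items():
        a, b = pair.split("-")
        expected = truth_decomposition(sigma_ind, sigma_e, i, j).r_p_expected
        observed = float(
            np.corrcoef(table[TRAIT_CODES[a]], table[TRAIT_CODES[b]])[0, 1]
        )
        worst = max(worst, abs(observed - expected))
    return worst


def _reconstruction_truth(seed: int) -> TruthConfig:
    """5-year design with cell-varying correlation structure, n = 300/year."""
    years = tuple(range(2009, 2014))
    r_ind_series = {
        "NA-AG": (0.5, -0.3, 0.2, 0.6, -0.1),
        "NA-RT": (0.3, 0.5, -0.2, 0.1, 0.6),
        "AG-RT": (0.7, 0.4, 0.6, -0.2, 0.3),
    }
    r_e_series = {
        "NA-AG": (0.4, -0.2, 0.1, 0.5, 0.0),
        "NA-RT": (0.2, 0.4, -0.3, 0.1, 0.5),
        "AG-RT": (0.5, 0.2, 0.4, -0.1, 0.2),
    }
    repeat_by_year = ((0.4, 0.3, 0.5), (0.3, 0.4, 0.4), (0.5, 0.2, 0.3),
                      (0.35, 0.35, 0.45), (0.25, 0.45, 0.5))
    sigma_ind, sigma_e = {}, {}
    for i, y in enumerate(years):
        sigma_ind[y], sigma_e[y] = assemble_covariances(
            (120.0, 70.0, 6.5),
            repeat_by_year[i],
            {p: r_ind_series[p][i] for p in PAIRS},
            {p: r_e_series[p][i] for p in PAIRS},
        )
    return TruthConfig(
        years=years,
        n_individuals_per_year=300,
        mu=(130.0, 47.0, 11.5),
        sigma_ind=sigma_ind,
        sigma_e=sigma_e,
        seed=seed,
    )


def reconstruction_experiment(
    seed: int, spec: MixedModelSpec | None = None
) -> dict:
    """End-to-end audit of the variance partition via reconstruction.

    Simulates five seasons (n = 300 males each, capture bias and censoring
    active), fits the bivariate model per year x pair on the re-assayed
    subsample, combines posterior-mean components into expected phenotypic
    correlations, and correlates them with the phenotypic correlations
    observed in the full samples (15 cells).
    """
    if spec is None:
        spec = MixedModelSpec(
            iterations=6000, burn_in=2000, thin=5, chains=2, seed=seed
        )
    cfg = _reconstruction_truth(seed)
    table = simulate_multiyear(cfg)
    effects = year_effect_table(table)
    obs = {(e.year, e.pair): e.r for e in effects}
    expected, observed = [], []
    max_psrf = 0.0
    for i, year in enumerate(cfg.years):
        sub = table[table["year"] == year]
        for j, pair in enumerate(PAIRS):
            a, b = pair.split("-")
            post = gibbs_bivariate(
                sub, a, b, replace(spec, seed=spec.seed + 131 * i + j)
            )
            r_p = expected_phenotypic_r(
                float(np.clip(post.mean(f"R_{a}"), 0.0, 1.0)),
                float(np.clip(post.mean(f"R_{b}"), 0.0, 1.0)),
                float(np.clip(post.mean("r_ind"), -1.0, 1.0)),
                float(np.clip(post.mean("r_e"), -1.0, 1.0)),
            )
            expected.append(r_p)
            observed.append(obs[(year, pair)])
            max_psrf = max(max_psrf, post.max_psrf())
    r, n, p = reconstruction_validation(expected, observed)
    return {"r": r, "n": n, "p": p, "max_psrf": max_psrf,
            "expected": expected, "observed": observed}


def capture_bias_experiment(seed: int, n: int = 1000) -> dict:
    """Direction of trappability bias under a bold-biased capture model.

    With a strong negative slope on the stored scores (smaller = bolder),
    captured birds should be bolder than the full sample; returns the
    standardized mean difference and a one-sided Mann-Whitney p-value.
    """
    from scipy.stats import mannwhitneyu

    from .synthetic import apply_capture_bias

    cfg = TruthConfig(
        years=(2001,),
        n_individuals_per_year=n,
        repeats_distribution={1: 1.0},
        mu=(0.0, 20.0, 20.0),
        sigma_ind=np.diag([0.5, 0.5, 0.5]),
        sigma_e=np.diag([0.5, 0.5, 0.5]),
        censor_threshold=1e9,
        capture_model=CaptureModel(intercept=np.inf),
        seed=seed,
    )
    table = simulate_multiyear(cfg)
    model = CaptureModel(intercept=0.0, slopes=(-2.0, 0.0, 0.0))
    out = apply_capture_bias(table, model, seed=seed + 1)
    captured = out.loc[out["captured"], "novelty_avoidance_s"]
    missed = out.loc[~out["captured"], "novelty_avoidance_s"]
    shift = float((missed.mean() - captured.mean()) / out["novelty_avoidance_s"].std())
    p = float(mannwhitneyu(captured, missed, alternative="less").pvalue)
    return {"standardized_shift": shift, "p_one_sided": p}
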
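"""End-to-end orchestration of the yearly-correlation analysis.

Stage order mirrors the study design: effect sizes per year and trait pair
-> random-effects pooling and heterogeneity per pair -> meta-regression on
socio-ecological moderators, but only for pairs whose effects are actually
heterogeneous -> variance partitioning for seasons with repeated assays ->
phenotypic-correlation reconstruction -> sample-size-weighted tests.  Each
stage writes a flat TSV; the whole run is summarized in a JSON report whose
bytes are reproducible given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import moderators as mod
from .decomposition import expected_phenotypic_r, reconstruction_validation
from .effects import effects_to_frame, year_effect_table
from .meta import MetaResult, compare_pooled, dl_pool, meta_regression
from .studydata import PAIRS, TRAIT_CODES
from .synthetic import (
    TruthConfig,
    read_assay_csv,
    simulate_moderators,
    simulate_multiyear,
    write_assay_csv,
)
from .varcomp import (
    MixedModelSpec,
    UnidentifiedModelError,
    between_year_fit,
    gibbs_bivariate,
    gibbs_univariate,
)
from .weighted import fisher_combined, weighted_t_one_sample, weighted_t_paired

logger = logging.getLogger(__name__)

TRAITS = tuple(TRAIT_CODES)  # ("NA", "AG", "RT")


@dataclass
class PipelineConfig:
    """Everything one run needs: data source, MCMC settings, meta options."""

    assay_csv: str | Path | None = None
    moderator_csv: str | Path | None = None
    truth: TruthConfig | None = None
    mcmc: MixedModelSpec = field(default_factory=MixedModelSpec)
    ci_coverage: float = 0.95
    heterogeneity_p_gate: float = 0.05
    heterogeneity_i2_gate: float = 25.0
    collinearity_threshold: float = 0.8
    min_year_n: int = 5
    outdir: str | Path = "results/pipeline"
    seed: int = 0

    def validate(self) -> None:
        have_files = self.assay_csv is not None
        have_sim = self.truth is not None
        if have_files == have_sim:
            raise ValueError("supply exactly one of an assay CSV or a simulation config")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # -- data ---------------------------------------------------------------
    if config.truth is not None:
        truth = replace(config.truth, seed=config.seed)
        table = simulate_multiyear(truth)
        mod_raw = simulate_moderators(truth, table)
        write_assay_csv(table, outdir / "assays.csv")
        mod_raw.to_csv(outdir / "moderators_raw.csv", index=False)
        report["stages"]["data"] = {"mode": "simulated", "n_assays": int(len(table))}
    else:
        table = read_assay_csv(config.assay_csv)
        mod_raw = pd.read_csv(config.moderator_csv) if config.moderator_csv else None
        report["stages"]["data"] = {"mode": "files", "n_assays": int(len(table))}

    # -- effect sizes -------------------------------------------------------
    effects = year_effect_table(table, min_n=config.min_year_n)
    eff_frame = effects_to_frame(effects)
    eff_frame.to_csv(outdir / "effect_sizes.tsv", sep="\t", index=False)
    report["stages"]["effect_sizes"] = {"n_effects": len(effects)}

    # -- random-effects pooling per pair -------------------------------------
    meta_rows = []
    meta_by_pair: dict[str, MetaResult] = {}
    for pair in PAIRS:
        sub = [e for e in effects if e.pair == pair]
        if not sub:
            continue
        res = dl_pool(sub, ci_coverage=config.ci_coverage)
        meta_by_pair[pair] = res
        meta_rows.append(
            {
                "pair": pair,
                "k": res.k,
                "pooled_r": res.pooled_r,
                "ci_lo": res.ci95_r[0],
                "ci_hi": res.ci95_r[1],
                "p": res.p,
                "tau2": res.tau2,
                "Q": res.Q,
                "df": res.df,
                "p_Q": res.p_Q,
                "I2": res.I2,
            }
        )
    meta_frame = pd.DataFrame(meta_rows)
    meta_frame.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    report["stages"]["meta"] = {
        row["pair"]: {k: _num(v) for k, v in row.items() if k != "pair"}
        for row in meta_rows
    }

    # pooled-effect comparison of the two largest positive pooled effects
    positives = sorted(
        (r for r in meta_by_pair.values() if r.pooled_r > 0 and r.p < 0.05),
        key=lambda r: r.pooled_r,
    )
    if len(positives) >= 2:
        lo_res, hi_res = positives[0], positives[-1]
        n_lo = sum(e.n for e in effects if e.pair == _pair_of(meta_by_pair, lo_res))
        n_hi = sum(e.n for e in effects if e.pair == _pair_of(meta_by_pair, hi_res))
        z_cmp, p_cmp = compare_pooled(lo_res.pooled_r, n_lo, hi_res.pooled_r, n_hi)
        report["stages"]["meta"]["pooled_comparison"] = {"z": _num(z_cmp), "p": _num(p_cmp)}

    # -- meta-regression, gated on heterogeneity -----------------------------
    metareg_rows = []
    if mod_raw is not None:
        mod_table = mod.build_moderator_table(mod_raw)
        mod_table.to_csv(outdir / "moderators.tsv", sep="\t", index=False)
        screen = mod.collinearity_screen(
            mod_table[list(mod.MODEL_COLUMNS)].dropna(), config.collinearity_threshold
        )
        screen.to_csv(outdir / "moderator_collinearity.tsv", sep="\t", index=False)
        excluded = _excluded_moderators(screen)
        for pair, res in meta_by_pair.items():
            gated = res.p_Q < config.heterogeneity_p_gate or res.I2 > config.heterogeneity_i2_gate
            if not gated:
                logger.info("pair %s: homogeneous effects, meta-regression skipped", pair)
                continue
            sub = [e for e in effects if e.pair == pair]
            years = [e.year for e in sub]
            # pair-wise models: each moderator alone
            for name in mod.MODEL_COLUMNS:
                x, kept = mod.design_for_years(mod_table, years, [name])
                kept_eff = [e for e in sub if e.year in kept]
                reg = meta_regression(kept_eff, x, names=[name])
                metareg_rows.append(_reg_row(pair, "pairwise", name, reg))
            # multivariate model without collinear moderators
            multi = [c for c in mod.MODEL_COLUMNS if c not in excluded]
            x, kept = mod.design_for_years(mod_table, years, multi)
            kept_eff = [e for e in sub if e.year in kept]
            if len(kept_eff) > len(multi) + 1:
                reg = meta_regression(kept_eff, x, names=multi)
                for name in multi:
                    metareg_rows.append(_reg_row(pair, "multivariate", name, reg))
    metareg_frame = pd.DataFrame(metareg_rows)
    metareg_frame.to_csv(outdir / "meta_regression.tsv", sep="\t", index=False)
    report["stages"]["meta_regression"] = {
        "n_models": len(metareg_rows),
        "gated_pairs": sorted(
            {r["pair"] for r in metareg_rows}
        ),
    }

    # -- variance partition for seasons with repeats --------------------------
    rep_rows, cor_rows, dec_rows = [], [], []
    repeat_years = sorted(
        set(
            table.loc[
                (table["assay_order"] > 1) & table["individual_id"].notna(), "year"
            ]
        )
    )
    if repeat_years:
        obs_r = {(e.year, e.pair): e.r for e in effects}
        for i, year in enumerate(repeat_years):
            sub = table[table["year"] == year]
            for j, trait in enumerate(TRAITS):
                spec = replace(config.mcmc, seed=config.seed + 7919 * i + j)
                try:
                    post = gibbs_univariate(sub, trait, spec)
                except UnidentifiedModelError as err:
                    logger.warning("year %s trait %s: %s", year, trait, err)
                    continue
                lo, hi = post.cri(f"R_{trait}")
                rep_rows.append(
                    {
                        "year": year,
                        "trait": trait,
                        "n_individuals": post.n_individuals,
                        "n_observations": post.n_observations,
                        "R_mean": post.mean(f"R_{trait}"),
                        "R_lo": lo,
                        "R_hi": hi,
                        "psrf_max": post.max_psrf(),
                    }
                )
            for j, pair in enumerate(PAIRS):
                a, b = pair.split("-")
                spec = replace(config.mcmc, seed=config.seed + 7919 * i + 100 + j)
                try:
                    post = gibbs_bivariate(sub, a, b, spec)
                except UnidentifiedModelError as err:
                    logger.warning("year %s pair %s: %s", year, pair, err)
                    continue
                row = {
                    "year": year,
                    "pair": pair,
                    "n_individuals": post.n_individuals,
                    "n_observations": post.n_observations,
                    "r_ind": post.mean("r_ind"),
                    "r_ind_lo": post.cri("r_ind")[0],
                    "r_ind_hi": post.cri("r_ind")[1],
                    "r_e": post.mean("r_e"),
                    "r_e_lo": post.cri("r_e")[0],
                    "r_e_hi": post.cri("r_e")[1],
                    "R_x": post.mean(f"R_{a}"),
                    "R_y": post.mean(f"R_{b}"),
                    "psrf_max": post.max_psrf(),
                }
                cor_rows.append(row)
                if (year, pair) in obs_r:
                    dec_rows.append(
                        {
                            "year": year,
                            "pair": pair,
                            "R_x": row["R_x"],
                            "R_y": row["R_y"],
                            "r_ind": row["r_ind"],
                            "r_e": row["r_e"],
                            "r_P_expected": expected_phenotypic_r(
                                min(max(row["R_x"], 0.0), 1.0),
                                min(max(row["R_y"], 0.0), 1.0),
                                min(max(row["r_ind"], -1.0), 1.0),
                                min(max(row["r_e"], -1.0), 1.0),
                            ),
                            "r_P_observed": obs_r[(year, pair)],
                        }
                    )
        pd.DataFrame(rep_rows).to_csv(outdir / "repeatability.tsv", sep="\t", index=False)
        pd.DataFrame(cor_rows).to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        dec_frame = pd.DataFrame(dec_rows)
        dec_frame.to_csv(outdir / "decomposition.tsv", sep="\t", index=False)
        report["stages"]["variance_partition"] = {
            "repeat_years": [int(y) for y in repeat_years],
            "n_univariate_fits": len(rep_rows),
            "n_bivariate_fits": len(cor_rows),
            "max_psrf": _num(
                max(
                    [r["psrf_max"] for r in rep_rows + cor_rows],
                    default=float("nan"),
                )
            ),
        }
        if len(dec_rows) >= 4:
            r_val, n_val, p_val = reconstruction_validation(
                dec_frame["r_P_expected"], dec_frame["r_P_observed"]
            )
            report["stages"]["reconstruction"] = {
                "r": _num(r_val), "n": n_val, "p": _num(p_val)
            }

        # -- weighted tests ----------------------------------------------------
        report["stages"]["weighted_tests"] = _weighted_stage(
            table, config, pd.DataFrame(rep_rows), outdir
        )
    else:
        logger.info("no repeated measurements: variance-partition stages skipped")
        report["stages"]["variance_partition"] = {"skipped": "no repeated measurements"}

    report_json = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_json)
    (outdir / "report.txt").write_text(_human_report(report))
    return report


def _weighted_stage(table, config, rep_frame, outdir) -> dict:
    """Weighted paired trait comparisons and within-vs-between-year tests."""
    out: dict = {}
    rows = []
    if rep_frame.empty:
        return {"skipped": "no identified repeatability fits"}
    by_trait = {
        t: rep_frame[rep_frame["trait"] == t].sort_values("year") for t in TRAITS
    }
    # paired within-year comparisons between traits
    for a, b in (("NA", "AG"), ("NA", "RT"), ("AG", "RT")):
        fa, fb = by_trait[a], by_trait[b]
        years = sorted(set(fa["year"]) & set(fb["year"]))
        if len(years) < 2:
            continue
        va = fa.set_index("year").loc[years, "R_mean"].to_numpy()
        vb = fb.set_index("year").loc[years, "R_mean"].to_numpy()
        wa = fa.set_index("year").loc[years, "n_individuals"].to_numpy()
        wb = fb.set_index("year").loc[years, "n_individuals"].to_numpy()
        t, df, p = weighted_t_paired(va, vb, wa, wb)
        rows.append({"test": f"paired_{a}_vs_{b}", "t": t, "df": df, "p": p})
    # within-year vs between-year repeatability, when identifiable
    one_sample_p = []
    for trait in TRAITS:
        f = by_trait[trait]
        if len(f) < 2:
            continue
        try:
            spec = replace(config.mcmc, seed=config.seed + 104729)
            between = between_year_fit(table, trait, spec)
        except UnidentifiedModelError as err:
            logger.info("trait %s: %s", trait, err)
            out[f"between_year_{trait}"] = "unidentified"
            continue
        mu0 = between.mean(f"R_{trait}")
        t, df, p = weighted_t_one_sample(
            f["R_mean"].to_numpy(), f["n_individuals"].to_numpy(), mu0
        )
        rows.append({"test": f"within_vs_between_{trait}", "t": t, "df": df, "p": p})
        one_sample_p.append(p)
    if one_sample_p:
        chi2, df, p = fisher_combined(one_sample_p)
        rows.append({"test": "fisher_combined_within_vs_between", "t": chi2, "df": df, "p": p})
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "weighted_tests.tsv", sep="\t", index=False)
    out["tests"] = {r["test"]: {"t": _num(r["t"]), "df": r["df"], "p": _num(r["p"])} for r in rows}
    return out


def _pair_of(meta_by_pair: dict, res) -> str:
    return next(p for p, r in meta_by_pair.items() if r is res)


def _excluded_moderators(screen: pd.DataFrame) -> set[str]:
    """Drop the second member of each flagged collinear pair (stable order)."""
    excluded: set[str] = set()
    for row in screen[screen["flagged"]].itertuples():
        if row.moderator_a not in excluded:
            excluded.add(row.moderator_b)
    return excluded


def _reg_row(pair, model, name, reg) -> dict:
    i = reg.names.index(name)
    return {
        "pair": pair,
        "model": model,
        "moderator": name,
        "Q_M": reg.Q_M,
        "beta_z": reg.beta[i],
        "se": reg.se[i],
        "p": reg.p[i],
        "tau2": reg.tau2,
        "r_at_min": reg.r_at_range[name][0],
        "r_at_max": reg.r_at_range[name][1],
    }


def _num(x) -> float:
    return float(np.round(float(x), 10))


def _human_report(report: dict) -> str:
    lines = [f"behavmeta pipeline report (seed {report['seed']})", ""]
    for stage, content in report["stages"].items():
        lines.append(f"[{stage}]")
        lines.append(json.dumps(content, indent=2, sort_keys=True, default=str))
        lines.append("")
    return "\n".join(lines)
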
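#!/usr/bin/env python
"""Meta-regression of heterogeneous trait-pair correlations on moderators.

Builds the modeling-scale moderator table (lagged predation, per-day
competition index, sqrt-transformed proportions), screens for collinear
moderators, and — only for pairs whose effects are heterogeneous — fits
single-moderator and multivariate weighted regressions.
"""

import argparse
from pathlib import Path

import pandas as pd

from behavmeta import moderators as mod
from behavmeta.effects import EffectSize
from behavmeta.meta import dl_pool, meta_regression
from behavmeta.studydata import PAIRS

parser = argparse.ArgumentParser()
parser.add_argument("--effects", type=Path, default=Path("results/effect_sizes.tsv"))
parser.add_argument("--moderators", type=Path, default=Path("results/data/moderators_raw.csv"))
parser.add_argument("--out", type=Path, default=Path("results/meta_regression.tsv"))
args = parser.parse_args()

frame = pd.read_csv(args.effects, sep="\t")
mod_table = mod.build_moderator_table(pd.read_csv(args.moderators))
screen = mod.collinearity_screen(mod_table[list(mod.MODEL_COLUMNS)].dropna())
excluded = set()
for row in screen[screen["flagged"]].itertuples():
    print(f"collinear moderators: {row.moderator_a} vs {row.moderator_b} "
          f"(r = {row.r:.3f}) -> excluding {row.moderator_b} from the joint model")
    if row.moderator_a not in excluded:
        excluded.add(row.moderator_b)

rows = []
for pair in PAIRS:
    sub = [
        EffectSize(r.year, r.pair, r.r, r.z, r.var_z, int(r.n))
        for r in frame[frame["pair"] == pair].itertuples()
    ]
    pool = dl_pool(sub)
    if pool.p_Q >= 0.05 and pool.I2 <= 25.0:
        print(f"{pair}: homogeneous effects (P_Q = {pool.p_Q:.3f}, "
              f"I2 = {pool.I2:.1f}%), moderators not examined")
        continue
    print(f"{pair}: heterogeneous effects (P_Q = {pool.p_Q:.3f}, I2 = {pool.I2:.1f}%)")
    years = [e.year for e in sub]
    for name in mod.MODEL_COLUMNS:
        x, kept = mod.design_for_years(mod_table, years, [name])
        reg = meta_regression([e for e in sub if e.year in kept], x, names=[name])
        i = reg.names.index(name)
        rows.append({"pair": pair, "model": "pairwise", "moderator": name,
                     "Q_M": reg.Q_M, "beta_z": reg.beta[i], "se": reg.se[i],
                     "p": reg.p[i], "tau2": reg.tau2})
        print(f"  {name:22s} Q_M = {reg.Q_M:6.3f}  beta_z = {reg.beta[i]:+.3f}  "
              f"P = {reg.p[i]:.3f}")
    joint = [c for c in mod.MODEL_COLUMNS if c not in excluded]
    x, kept = mod.design_for_years(mod_table, years, joint)
    if len(kept) > len(joint) + 1:
        reg = meta_regression([e for e in sub if e.year in kept], x, names=joint)
        for name in joint:
            i = reg.names.index(name)
            rows.append({"pair": pair, "model": "multivariate", "moderator": name,
                         "Q_M": reg.Q_M, "beta_z": reg.beta[i], "se": reg.se[i],
                         "p": reg.p[i], "tau2": reg.tau2})
        print(f"  multivariate model ({', '.join(joint)}): "
              f"Q_M = {reg.Q_M:.3f}, P = {reg.p_M:.3f}")

out = pd.DataFrame(rows)
args.out.parent.mkdir(parents=True, exist_ok=True)
out.to_csv(args.out, sep="\t", index=False)
print(f"\nmeta-regression table -> {args.out}")
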
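#!/usr/bin/env python
"""Year-specific Spearman correlations as Fisher-Z effect sizes.

One correlation per season and trait pair, first assays only, all males
(captured or not), pairwise-complete sample sizes, variance 1/(n - 3).
"""

import argparse
from pathlib import Path

from behavmeta.effects import effects_to_frame, year_effect_table
from behavmeta.synthetic import read_assay_csv

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data/assays.csv"))
parser.add_argument("--out", type=Path, default=Path("results/effect_sizes.tsv"))
args = parser.parse_args()

table = read_assay_csv(args.data)
frame = effects_to_frame(year_effect_table(table))
args.out.parent.mkdir(parents=True, exist_ok=True)
frame.to_csv(args.out, sep="\t", index=False)

print(frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\n{len(frame)} year x pair effect sizes -> {args.out}")
for pair, sub in frame.groupby("pair"):
    signs = (sub["r"] > 0).sum()
    print(f"  {pair}: r from {sub['r'].min():.2f} to {sub['r'].max():.2f} "
          f"({signs}/{len(sub)} positive)")
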
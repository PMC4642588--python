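"""Year-specific Spearman correlations as Fisher-Z effect sizes.

Each study year is treated as an independent "study": for every pair of
behaviors the Spearman rank correlation of first-assay scores is computed
on pairwise-complete cases, transformed to the Fisher-Z scale, and given
the large-sample sampling variance 1/(n - 3).  Midranks handle the tie
blocks created by ceiling-censored latencies.  Because all three traits
are stored so that smaller = bolder, a positive correlation always means
"bold in one test, bold in the other".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .studydata import PAIRS, TRAIT_CODES

logger = logging.getLogger(__name__)

#: Correlations are clamped to this magnitude before atanh so that degenerate
#: (perfect) correlations keep finite meta-analytic weights.
R_CLAMP = 0.9999


class ConstantInputError(ValueError):
    """Correlation undefined because one input vector is constant."""


@dataclass(frozen=True)
class EffectSize:
    """One year x trait-pair correlation on the Fisher-Z scale."""

    year: object
    pair: str
    r: float
    z: float
    var_z: float
    n: int


def rank_with_ties(values: Sequence[float]) -> np.ndarray:
    """Midranks of ``values``; NaNs are excluded and returned as NaN.

    Tied observations (e.g. a block of ceiling-censored latencies) all get
    the mean of the ranks they span.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.isfinite(v).any():
        raise ValueError("rank_with_ties needs at least one finite value")
    out = np.full(v.shape, np.nan)
    finite = np.isfinite(v)
    out[finite] = rankdata(v[finite], method="average")
    return out


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman correlation: Pearson correlation of midranks.

    Uses pairwise-complete observations; requires n >= 4 and non-constant
    ranks on both sides.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise ValueError(f"need >= 4 pairwise-complete observations, got {int(ok.sum())}")
    rx = rankdata(x[ok], method="average")
    ry = rankdata(y[ok], method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def fisher_z(r: float, clamp: float = R_CLAMP) -> float:
    """Fisher Z transform atanh(r), with |r| clamped to keep z finite."""
    return float(np.arctanh(np.clip(r, -clamp, clamp)))


def inv_fisher_z(z: float) -> float:
    """Inverse Fisher transform tanh(z)."""
    return float(np.tanh(z))


def effect_size(year, pair: str, x, y) -> EffectSize:
    """Build one :class:`EffectSize` from paired trait vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    r = spearman_rho(x[ok], y[ok])
    z = fisher_z(r)
    return EffectSize(year=year, pair=pair, r=r, z=z, var_z=1.0 / (n - 3), n=n)


def year_effect_table(
    table: pd.DataFrame,
    min_n: int = 5,
    pairs: Sequence[str] = PAIRS,
) -> list[EffectSize]:
    """One effect size per year x trait pair from first assays of all birds.

    Only each bird's first assay enters (phenotypic correlations are defined
    on single observations per individual, and non-captured, anonymous birds
    contribute too).  Sample sizes are pairwise-complete and may differ
    between pairs within a year.  Years with fewer than ``min_n`` complete
    pairs are dropped with a warning, mirroring the exclusion of
    under-sampled seasons.
    """
    first = table[table["assay_order"] == 1]
    out: list[EffectSize] = []
    for year, sub in first.groupby("year", sort=True):
        for pair in pairs:
            a, b = pair.split("-")
            x = sub[TRAIT_CODES[a]].to_numpy(dtype=float)
            y = sub[TRAIT_CODES[b]].to_numpy(dtype=float)
            n = int((np.isfinite(x) & np.isfinite(y)).sum())
            if n < min_n:
                logger.warning(
                    "year %s pair %s dropped: n=%d below minimum %d", year, pair, n, min_n
                )
                continue
            out.append(effect_size(year, pair, x, y))
    return out


def effects_to_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Tabular view (TSV-ready): year, pair, n, r, z, var_z."""
    return pd.DataFrame(
        [
            {"year": e.year, "pair": e.pair, "n": e.n, "r": e.r, "z": e.z, "var_z": e.var_z}
            for e in effects
        ]
    )
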
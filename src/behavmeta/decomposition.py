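"""Reconstructing phenotypic correlations from their components.

A phenotypic correlation (single observation per individual per trait)
mixes the between-individual and within-individual correlations, weighted
by how repeatable each trait is:

    r_P = r_ind * sqrt(R_x * R_y) + r_e * sqrt((1 - R_x) * (1 - R_y))

Comparing this expectation — built from mixed-model estimates on the
subsample of re-assayed birds — against the phenotypic correlation observed
in the full sample is the standard audit that the variance partition is
trustworthy despite the capture-biased subsample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class Decomposition:
    """Components of one trait-pair correlation in one year."""

    R_x: float
    R_y: float
    r_ind: float
    r_e: float

    @property
    def r_p_expected(self) -> float:
        return expected_phenotypic_r(self.R_x, self.R_y, self.r_ind, self.r_e)


def expected_phenotypic_r(R_x: float, R_y: float, r_ind: float, r_e: float) -> float:
    """Expected phenotypic correlation from repeatabilities and components.

    Convex-weight combination of the between- and within-individual
    correlations; reduces to ``r_ind`` for perfectly repeatable traits and
    to ``r_e`` for unrepeatable ones.
    """
    for name, val, lo, hi in (
        ("R_x", R_x, 0.0, 1.0),
        ("R_y", R_y, 0.0, 1.0),
        ("r_ind", r_ind, -1.0, 1.0),
        ("r_e", r_e, -1.0, 1.0),
    ):
        if not lo <= val <= hi:
            raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
    return float(
        r_ind * np.sqrt(R_x * R_y) + r_e * np.sqrt((1.0 - R_x) * (1.0 - R_y))
    )


def truth_decomposition(sigma_ind: np.ndarray, sigma_e: np.ndarray, i: int, j: int) -> Decomposition:
    """Ground-truth decomposition of a trait pair from generator covariances."""
    si = np.asarray(sigma_ind, dtype=float)
    se = np.asarray(sigma_e, dtype=float)
    r_x = si[i, i] / (si[i, i] + se[i, i])
    r_y = si[j, j] / (si[j, j] + se[j, j])
    r_ind = si[i, j] / np.sqrt(si[i, i] * si[j, j]) if si[i, i] * si[j, j] > 0 else 0.0
    r_e = se[i, j] / np.sqrt(se[i, i] * se[j, j]) if se[i, i] * se[j, j] > 0 else 0.0
    return Decomposition(R_x=float(r_x), R_y=float(r_y), r_ind=float(r_ind), r_e=float(r_e))


def reconstruction_validation(
    expected: Sequence[float], observed: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson correlation between expected and observed phenotypic correlations.

    Returns ``(r, n, p)`` over the paired year x trait-pair cells.
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expected and observed must be equal-length 1-D sequences")
    if x.size < 4:
        raise ValueError("need at least 4 paired cells")
    res = stats.pearsonr(x, y)
    return float(res.statistic), int(x.size), float(res.pvalue)
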
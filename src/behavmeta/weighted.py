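"""Sample-size-weighted t-tests and Fisher's combined probability.

Year-level statistics (e.g. within-year repeatabilities) come from very
different sample sizes, so simple t-tests across years would give every
season equal say.  The tests here weight each year's value by its number
of individuals: the weighted mean and the frequency-weighted variance
(rescaled by ``n/(n-1)`` with ``n`` the number of years) feed a t statistic
with ``n - 1`` degrees of freedom.  Paired comparisons apply the one-sample
test to per-year differences, weighting each year by the smaller of the two
traits' sample sizes.  Fisher's method combines independent p-values via
``-2 * sum(log p) ~ chi^2(2k)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class WeightedSample:
    """Per-year statistics with their sample-size weights."""

    values: tuple[float, ...]
    weights: tuple[float, ...]
    labels: tuple = ()

    def __post_init__(self):
        if len(self.values) != len(self.weights):
            raise ValueError("values and weights must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")


def weighted_mean_var(values: Sequence[float], weights: Sequence[float]) -> tuple[float, float]:
    """Weighted mean and the n/(n-1)-corrected frequency-weighted variance."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1 or v.size < 2:
        raise ValueError("need equal-length 1-D values and weights, length >= 2")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    n = v.size
    mean = float(w @ v / w.sum())
    var = float(w @ (v - mean) ** 2 / w.sum()) * n / (n - 1)
    return mean, var


def weighted_t_one_sample(
    values: Sequence[float], weights: Sequence[float], mu0: float = 0.0
) -> tuple[float, int, float]:
    """Weighted one-sample t-test of the year values against ``mu0``.

    Returns ``(t, df, p)`` with ``df = n - 1`` (n = number of years) and a
    two-sided p-value.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    mean, var = weighted_mean_var(values, weights)
    diff = mean - mu0
    t = 0.0 if diff == 0.0 else diff / np.sqrt(var / n)
    return float(t), n - 1, float(2.0 * stats.t.sf(abs(t), n - 1))


def weighted_t_paired(
    values_a: Sequence[float],
    values_b: Sequence[float],
    weights_a: Sequence[float],
    weights_b: Sequence[float] | None = None,
) -> tuple[float, int, float]:
    """Weighted paired t-test on per-year differences ``a - b``.

    Each year is weighted by the pairwise minimum of the two traits' sample
    sizes (pass a single weight vector to use it directly).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    wa = np.asarray(weights_a, dtype=float)
    w = wa if weights_b is None else np.minimum(wa, np.asarray(weights_b, dtype=float))
    return weighted_t_one_sample(a - b, w, 0.0)


def fisher_combined(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined probability: ``(chi2, df=2k, p)``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))
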
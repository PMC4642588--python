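"""Random-effects meta-analysis of yearly Fisher-Z effect sizes.

DerSimonian-Laird pooling with heterogeneity statistics (Q, tau^2, I^2),
method-of-moments meta-regression on year-level moderators, and the two
small inferential utilities used to compare and audit pooled correlations.

Effect sizes enter on the Fisher-Z scale with sampling variance
``1/(n - 3)``; pooled results are reported back on the correlation scale
via ``tanh``.  I^2 is computed as ``100 * tau^2 / (tau^2 + s2)`` with the
"typical" within-study variance ``s2 = (k-1) * sum(w) / ((sum w)^2 - sum w^2)``,
the convention of the standard meta-analysis tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .effects import EffectSize


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects estimate with heterogeneity statistics."""

    k: int
    pooled_z: float
    pooled_r: float
    se_z: float
    ci95_r: tuple[float, float]
    p: float
    tau2: float
    Q: float
    df: int
    p_Q: float
    I2: float


@dataclass(frozen=True)
class MetaRegResult:
    """Weighted meta-regression fit (method-of-moments residual tau^2)."""

    k: int
    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    Q_M: float
    df_M: int
    p_M: float
    tau2: float
    r_at_range: dict = field(default_factory=dict)


def _extract(effects: Sequence[EffectSize] | tuple) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) == 0:
        raise ValueError("need at least one effect size")
    z = np.array([e.z for e in effects], dtype=float)
    v = np.array([e.var_z for e in effects], dtype=float)
    if (v <= 0).any():
        raise ValueError("all sampling variances must be positive")
    return z, v


def dl_pool(effects: Sequence[EffectSize], ci_coverage: float = 0.95) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of Fisher-Z effects.

    Fixed-effect weights ``w = 1/v`` give the heterogeneity statistic
    ``Q = sum w (z - z_FE)^2``; the moment estimator
    ``tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))`` then defines the
    random-effects weights ``1/(v + tau2)``.  Confidence interval and
    p-value use the normal approximation on the Z scale.
    """
    z, v = _extract(effects)
    k = len(z)
    w = 1.0 / v
    z_fe = float(w @ z / w.sum())
    Q = float(w @ (z - z_fe) ** 2)
    df = k - 1
    if df > 0:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - df) / denom)
        p_Q = float(stats.chi2.sf(Q, df))
    else:
        tau2, p_Q = 0.0, 1.0
    w_star = 1.0 / (v + tau2)
    pooled_z = float(w_star @ z / w_star.sum())
    se_z = float(w_star.sum() ** -0.5)
    crit = float(stats.norm.ppf(0.5 + ci_coverage / 2.0))
    ci = (float(np.tanh(pooled_z - crit * se_z)), float(np.tanh(pooled_z + crit * se_z)))
    p = float(2.0 * stats.norm.sf(abs(pooled_z) / se_z))
    i2 = _i_squared(tau2, w, k)
    return MetaResult(
        k=k,
        pooled_z=pooled_z,
        pooled_r=float(np.tanh(pooled_z)),
        se_z=se_z,
        ci95_r=ci,
        p=p,
        tau2=tau2,
        Q=Q,
        df=df,
        p_Q=p_Q,
        I2=i2,
    )


def _i_squared(tau2: float, w: np.ndarray, k: int) -> float:
    if k < 2:
        return 0.0
    s2 = (k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
    return float(100.0 * tau2 / (tau2 + s2))


def heterogeneity(effects: Sequence[EffectSize]) -> tuple[float, int, float, float]:
    """(Q, df, p_Q, I2) of the DerSimonian-Laird heterogeneity test."""
    res = dl_pool(effects)
    return res.Q, res.df, res.p_Q, res.I2


class CollinearityError(ValueError):
    """Moderator design matrix is rank-deficient."""


def meta_regression(
    effects: Sequence[EffectSize],
    X: np.ndarray,
    names: Sequence[str] | None = None,
    add_intercept: bool = True,
) -> MetaRegResult:
    """Mixed-effects meta-regression with method-of-moments residual tau^2.

    The fixed-effect WLS residual statistic ``Q_E`` is compared with its
    expectation under the model to estimate the residual between-year
    variance, after which coefficients are re-estimated by WLS with weights
    ``1/(v + tau2)``.  ``Q_M`` is the Wald omnibus test of all non-intercept
    coefficients.  An intercept-only design reduces exactly to
    :func:`dl_pool`.
    """
    z, v = _extract(effects)
    k = len(z)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(k), X])
        names = ["intercept"] + names
    if X.shape[0] != k:
        raise ValueError("design matrix rows must match number of effects")
    p = X.shape[1]
    if k <= p:
        raise ValueError(f"need more effects ({k}) than coefficients ({p})")
    if np.linalg.matrix_rank(X) < p:
        offenders = _collinear_columns(X, names)
        raise CollinearityError(f"rank-deficient design; collinear columns: {offenders}")

    w = 1.0 / v
    xtw = X.T * w
    xtwx_inv = np.linalg.inv(xtw @ X)
    beta_fe = xtwx_inv @ (xtw @ z)
    resid = z - X @ beta_fe
    q_e = float(w @ resid**2)
    # E[Q_E] = (k - p) + tau2 * (tr(W) - tr((X'WX)^-1 X'W^2X))
    trace_term = w.sum() - float(np.trace(xtwx_inv @ ((X.T * w**2) @ X)))
    tau2 = max(0.0, (q_e - (k - p)) / trace_term)

    w_star = 1.0 / (v + tau2)
    xtw_s = X.T * w_star
    cov = np.linalg.inv(xtw_s @ X)
    beta = cov @ (xtw_s @ z)
    se = np.sqrt(np.diag(cov))
    pvals = 2.0 * stats.norm.sf(np.abs(beta) / se)

    slope_idx = np.arange(1 if add_intercept else 0, p)
    if slope_idx.size:
        b_s = beta[slope_idx]
        cov_s = cov[np.ix_(slope_idx, slope_idx)]
        q_m = float(b_s @ np.linalg.solve(cov_s, b_s))
        df_m = int(slope_idx.size)
        p_m = float(stats.chi2.sf(q_m, df_m))
    else:
        q_m, df_m, p_m = 0.0, 0, 1.0

    r_at_range = _moderator_ranges(X, beta, names, add_intercept)
    return MetaRegResult(
        k=k,
        names=tuple(names),
        beta=beta,
        se=se,
        p=np.asarray(pvals),
        Q_M=q_m,
        df_M=df_m,
        p_M=p_m,
        tau2=tau2,
        r_at_range=r_at_range,
    )


def _moderator_ranges(X, beta, names, add_intercept) -> dict:
    """Model-implied correlation at each moderator's min and max (others at mean)."""
    out = {}
    start = 1 if add_intercept else 0
    means = X.mean(axis=0)
    for j in range(start, X.shape[1]):
        lo_x = means.copy()
        hi_x = means.copy()
        lo_x[j] = X[:, j].min()
        hi_x[j] = X[:, j].max()
        out[names[j]] = (float(np.tanh(lo_x @ beta)), float(np.tanh(hi_x @ beta)))
    return out


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    with np.errstate(invalid="ignore"):  # constant columns give NaN correlations
        corr = np.corrcoef(X.T)
    offenders = set()
    p = X.shape[1]
    for i in range(p):
        if np.ptp(X[:, i]) == 0 and not np.allclose(X[:, i], 1.0):
            offenders.add(names[i])
        for j in range(i + 1, p):
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) > 1 - 1e-10:
                offenders.update((names[i], names[j]))
    return sorted(offenders)


def compare_pooled(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Normal z-test for the difference of two independent pooled correlations.

    ``z = (atanh r2 - atanh r1) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    z = (np.arctanh(r2) - np.arctanh(r1)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def p_from_estimate_ci(r: float, ci_lo: float, ci_hi: float) -> float:
    """Two-sided p implied by a correlation and its symmetric-on-Z 95% CI."""
    if not ci_lo < r < ci_hi:
        raise ValueError("estimate must lie strictly inside its confidence interval")
    se_z = (np.arctanh(ci_hi) - np.arctanh(ci_lo)) / (2.0 * 1.959963984540054)
    return float(2.0 * stats.norm.sf(abs(np.arctanh(r)) / se_z))


def magnitude_label(r: float) -> str:
    """Qualitative effect-magnitude benchmark: ~0.1 small, ~0.3 moderate, ~0.5 strong."""
    a = abs(r)
    if a < 0.2:
        return "small"
    if a < 0.4:
        return "moderate"
    return "strong"
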
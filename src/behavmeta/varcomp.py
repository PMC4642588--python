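"""Bayesian variance partitioning via a conjugate Gibbs sampler.

Random-intercept linear mixed models estimate how much behavioral variance
sits between versus within individuals:

* univariate fits give the repeatability ``R = V_ind / (V_ind + V_e)`` of a
  single behavior;
* bivariate fits partition the covariance of two behaviors into a
  between-individual correlation ``r_ind`` (correlation of individual mean
  levels — the quantity that defines a behavioral syndrome) and a
  within-individual residual correlation ``r_e``.

The sampler uses fully conjugate updates: normal draws for fixed effects
(flat prior) and individual effects, inverse-gamma draws for univariate
variances and inverse-Wishart draws for 2x2 covariance matrices.  The
variance prior is the weakly informative inverse-gamma(0.001, 0.001); for
2x2 matrices the matching inverse-Wishart has ``nu0 = 1.002`` and scale
``0.002 * I`` so that each diagonal's marginal is again IG(0.001, 0.001).
Convergence is monitored with the Gelman-Rubin potential scale reduction
factor across independent chains (gate: PSRF < 1.1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .studydata import TRAIT_CODES

PSRF_GATE = 1.1


class UnidentifiedModelError(RuntimeError):
    """Repeatability is unidentified: no individual has repeated measures."""


@dataclass(frozen=True)
class MixedModelSpec:
    """MCMC settings for the random-intercept models.

    Defaults are desk-scale (3 chains x 20,000 iterations, 5,000 burn-in,
    thinning 10); heavier schedules are a matter of configuration.  The
    ``prior_*`` fields encode the weakly informative variance prior; see
    the module docstring for the exact mapping.
    """

    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    chains: int = 3
    prior_shape: float = 0.001
    prior_scale: float = 0.001
    prior_nu: float = 1.002
    include_date: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_saved(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


class VarCompPosterior:
    """Posterior draws of variance components and derived quantities.

    ``params`` maps parameter name to an array of shape ``(chains, draws)``.
    Derived parameters (``R_<trait>``, ``r_ind``, ``r_e``) are stored per
    draw, so their credible intervals need no extra computation.
    """

    def __init__(
        self,
        params: Mapping[str, np.ndarray],
        traits: tuple[str, ...],
        n_individuals: int,
        n_observations: int,
        resample_count: int = 0,
    ):
        self.params = {k: np.asarray(v) for k, v in params.items()}
        self.traits = traits
        self.n_individuals = n_individuals
        self.n_observations = n_observations
        self.resample_count = resample_count

    def draws(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return self.params[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.draws(name).mean())

    def median(self, name: str) -> float:
        return float(np.median(self.draws(name)))

    def cri(self, name: str, coverage: float = 0.95) -> tuple[float, float]:
        """Central (equal-tailed) credible interval."""
        a = (1.0 - coverage) / 2.0
        lo, hi = np.quantile(self.draws(name), [a, 1.0 - a])
        return float(lo), float(hi)

    def psrf(self, name: str) -> float:
        return psrf(self.params[name])

    def max_psrf(self) -> float:
        return max(self.psrf(name) for name in self.params)

    def converged(self, gate: float = PSRF_GATE) -> bool:
        return self.max_psrf() < gate

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.params:
            lo, hi = self.cri(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": self.mean(name),
                    "median": self.median(name),
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "psrf": self.psrf(name),
                }
            )
        return pd.DataFrame(rows)


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape ``(m, n)``.  With within-chain variance ``W`` and
    between-chain variance ``B = n * var(chain means)``, the pooled variance
    estimate is ``(n-1)/n * W + B/n`` and PSRF is the square root of its
    ratio to ``W``.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    m, n = c.shape
    if m < 2:
        return 1.0
    w = c.var(axis=1, ddof=1).mean()
    b = n * c.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


# ---------------------------------------------------------------------------
# Conjugate full-conditional helpers (unit-testable against closed forms)
# ---------------------------------------------------------------------------


def invgamma_post_params(
    prior_shape: float, prior_scale: float, values: np.ndarray
) -> tuple[float, float]:
    """Posterior (shape, scale) of a variance given zero-mean normal values."""
    v = np.asarray(values, dtype=float)
    return prior_shape + v.size / 2.0, prior_scale + 0.5 * float(v @ v)


def draw_invgamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def draw_invwishart_2x2(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition (2x2 only)."""
    # W ~ Wishart(df, scale^-1)  =>  W^-1 ~ InvWishart(df, scale)
    l_inv = np.linalg.cholesky(np.linalg.inv(scale))
    a = np.zeros((2, 2))
    a[0, 0] = np.sqrt(rng.chisquare(df))
    a[1, 1] = np.sqrt(rng.chisquare(df - 1.0))
    a[1, 0] = rng.standard_normal()
    f = l_inv @ a
    w = f @ f.T
    return np.linalg.inv(w)


def _inv2(m: np.ndarray) -> np.ndarray:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def _chol2(m: np.ndarray) -> np.ndarray:
    l00 = np.sqrt(m[0, 0])
    l10 = m[1, 0] / l00
    l11 = np.sqrt(max(m[1, 1] - l10 * l10, 1e-300))
    return np.array([[l00, 0.0], [l10, l11]])


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def _prepare(table: pd.DataFrame, traits: Sequence[str], include_date: bool):
    """Identified rows with all requested traits observed, grouped by bird."""
    cols = [TRAIT_CODES.get(t, t) for t in traits]
    sub = table[table["individual_id"].notna()].copy()
    mask = np.ones(len(sub), dtype=bool)
    for c in cols:
        mask &= np.isfinite(sub[c].to_numpy(dtype=float))
    sub = sub[mask]
    if sub.empty:
        raise UnidentifiedModelError("no identified observations with complete traits")
    codes, _ = pd.factorize(sub["individual_id"], sort=True)
    counts = np.bincount(codes)
    if (counts >= 2).sum() < 2:
        raise UnidentifiedModelError(
            "repeatability unidentified: need >= 2 individuals with >= 2 observations"
        )
    y = sub[cols].to_numpy(dtype=float)
    if include_date:
        x = np.column_stack([np.ones(len(sub)), sub["assay_date"].to_numpy(dtype=float)])
    else:
        x = np.ones((len(sub), 1))
    return y, x, codes, counts


# ---------------------------------------------------------------------------
# Univariate sampler
# ---------------------------------------------------------------------------


def gibbs_univariate(
    table: pd.DataFrame, trait: str, spec: MixedModelSpec
) -> VarCompPosterior:
    """Random-intercept model ``y = X beta + b_ind + e`` for one behavior.

    Returns posterior draws of the fixed effects, the between- and
    within-individual variances, and the per-draw repeatability
    ``R = V_ind / (V_ind + V_e)``.
    """
    spec.validate()
    y, x, g, counts = _prepare(table, [trait], spec.include_date)
    y = y[:, 0]
    n, p = x.shape
    q = counts.size
    xtx_inv = np.linalg.inv(x.T @ x)
    xtx_inv_l = np.linalg.cholesky(xtx_inv)
    beta_names = ["intercept"] + (["date_slope"] if p == 2 else [])

    root = np.random.SeedSequence(spec.seed)
    chain_store: dict[str, list[np.ndarray]] = {
        name: [] for name in beta_names + ["V_ind", "V_e", f"R_{trait}"]
    }
    for child in root.spawn(spec.chains):
        rng = np.random.default_rng(child)
        beta = xtx_inv @ (x.T @ y)
        v_total = max(float(np.var(y)), 1e-12)
        v_ind, v_e = 0.5 * v_total, 0.5 * v_total
        b = np.zeros(q)
        saved = {name: np.empty(spec.n_saved) for name in chain_store}
        s_idx = 0
        for it in range(spec.iterations):
            # individual effects | rest
            resid_f = y - x @ beta
            s = np.bincount(g, weights=resid_f, minlength=q)
            prec = counts / v_e + 1.0 / v_ind
            mean_b = (s / v_e) / prec
            b = mean_b + rng.standard_normal(q) / np.sqrt(prec)
            # V_ind | b
            shape, scale = invgamma_post_params(spec.prior_shape, spec.prior_scale, b)
            v_ind = draw_invgamma(rng, shape, scale)
            # fixed effects | rest (flat prior)
            y_adj = y - b[g]
            beta_hat = xtx_inv @ (x.T @ y_adj)
            beta = beta_hat + np.sqrt(v_e) * (xtx_inv_l @ rng.standard_normal(p))
            # V_e | rest
            e = y_adj - x @ beta
            shape, scale = invgamma_post_params(spec.prior_shape, spec.prior_scale, e)
            v_e = draw_invgamma(rng, shape, scale)
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                for j, name in enumerate(beta_names):
                    saved[name][s_idx] = beta[j]
                saved["V_ind"][s_idx] = v_ind
                saved["V_e"][s_idx] = v_e
                saved[f"R_{trait}"][s_idx] = v_ind / (v_ind + v_e)
                s_idx += 1
        for name, arr in saved.items():
            chain_store[name].append(arr)

    params = {name: np.vstack(arrs) for name, arrs in chain_store.items()}
    return VarCompPosterior(params, (trait,), q, n)


# ---------------------------------------------------------------------------
# Bivariate sampler
# ---------------------------------------------------------------------------


def gibbs_bivariate(
    table: pd.DataFrame, trait_x: str, trait_y: str, spec: MixedModelSpec
) -> VarCompPosterior:
    """Bivariate random-intercept model partitioning a trait-pair covariance.

    Per draw the 2x2 between- and within-individual covariance matrices
    yield ``r_ind``, ``r_e`` and both repeatabilities.  Inverse-Wishart
    full conditionals keep every draw positive definite; the rare
    numerically non-PD draw is resampled and counted.
    """
    spec.validate()
    yy, x, g, counts = _prepare(table, [trait_x, trait_y], spec.include_date)
    n, p = x.shape
    q = counts.size
    xtx_inv = np.linalg.inv(x.T @ x)
    xtx_inv_l = np.linalg.cholesky(xtx_inv)
    psi0 = 2.0 * spec.prior_scale * np.eye(2)
    nu0 = spec.prior_nu
    unique_counts = np.unique(counts)
    groups_by_count = {c: np.flatnonzero(counts == c) for c in unique_counts}

    names = (
        [f"intercept_{t}" for t in (trait_x, trait_y)]
        + ([f"date_slope_{t}" for t in (trait_x, trait_y)] if p == 2 else [])
        + [
            f"V_ind_{trait_x}", f"V_ind_{trait_y}", "C_ind_xy",
            f"V_e_{trait_x}", f"V_e_{trait_y}", "C_e_xy",
            f"R_{trait_x}", f"R_{trait_y}", "r_ind", "r_e",
        ]
    )
    root = np.random.SeedSequence(spec.seed)
    chain_store: dict[str, list[np.ndarray]] = {name: [] for name in names}
    resamples = 0
    for child in root.spawn(spec.chains):
        rng = np.random.default_rng(child)
        bmat = xtx_inv @ (x.T @ yy)
        v0 = np.maximum(yy.var(axis=0), 1e-12)
        c_ind = np.diag(0.5 * v0)
        c_e = np.diag(0.5 * v0)
        b = np.zeros((q, 2))
        saved = {name: np.empty(spec.n_saved) for name in names}
        s_idx = 0
        for it in range(spec.iterations):
            e_inv = _inv2(c_e)
            i_inv = _inv2(c_ind)
            # individual effects | rest, grouped by replicate count
            resid_f = yy - x @ bmat
            s = np.column_stack(
                [np.bincount(g, weights=resid_f[:, j], minlength=q) for j in (0, 1)]
            )
            for c in unique_counts:
                idx = groups_by_count[c]
                prec = c * e_inv + i_inv
                cov = _inv2(prec)
                mean = s[idx] @ e_inv @ cov
                b[idx] = mean + rng.standard_normal((idx.size, 2)) @ _chol2(cov).T
            # C_ind | b
            c_ind, resamples = _draw_cov(rng, nu0 + q, psi0 + b.T @ b, resamples)
            # fixed effects | rest
            y_adj = yy - b[g]
            b_hat = xtx_inv @ (x.T @ y_adj)
            bmat = b_hat + xtx_inv_l @ rng.standard_normal((p, 2)) @ _chol2(c_e).T
            # C_e | rest
            e = y_adj - x @ bmat
            c_e, resamples = _draw_cov(rng, nu0 + n, psi0 + e.T @ e, resamples)
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                saved[f"intercept_{trait_x}"][s_idx] = bmat[0, 0]
                saved[f"intercept_{trait_y}"][s_idx] = bmat[0, 1]
                if p == 2:
                    saved[f"date_slope_{trait_x}"][s_idx] = bmat[1, 0]
                    saved[f"date_slope_{trait_y}"][s_idx] = bmat[1, 1]
                saved[f"V_ind_{trait_x}"][s_idx] = c_ind[0, 0]
                saved[f"V_ind_{trait_y}"][s_idx] = c_ind[1, 1]
                saved["C_ind_xy"][s_idx] = c_ind[0, 1]
                saved[f"V_e_{trait_x}"][s_idx] = c_e[0, 0]
                saved[f"V_e_{trait_y}"][s_idx] = c_e[1, 1]
                saved["C_e_xy"][s_idx] = c_e[0, 1]
                saved[f"R_{trait_x}"][s_idx] = c_ind[0, 0] / (c_ind[0, 0] + c_e[0, 0])
                saved[f"R_{trait_y}"][s_idx] = c_ind[1, 1] / (c_ind[1, 1] + c_e[1, 1])
                saved["r_ind"][s_idx] = c_ind[0, 1] / np.sqrt(c_ind[0, 0] * c_ind[1, 1])
                saved["r_e"][s_idx] = c_e[0, 1] / np.sqrt(c_e[0, 0] * c_e[1, 1])
                s_idx += 1
        for name, arr in saved.items():
            chain_store[name].append(arr)

    params = {name: np.vstack(arrs) for name, arrs in chain_store.items()}
    return VarCompPosterior(params, (trait_x, trait_y), q, n, resample_count=resamples)


def _draw_cov(
    rng: np.random.Generator, df: float, scale: np.ndarray, resamples: int
) -> tuple[np.ndarray, int]:
    """Inverse-Wishart draw, resampling the rare numerically non-PD result."""
    for _ in range(100):
        draw = draw_invwishart_2x2(rng, df, scale)
        if draw[0, 0] > 0 and np.linalg.det(draw) > 0:
            return draw, resamples
        resamples += 1
    raise RuntimeError("inverse-Wishart sampling failed repeatedly; scale matrix ill-conditioned")


# ---------------------------------------------------------------------------
# Study-layout drivers
# ---------------------------------------------------------------------------


def within_year_fits(
    table: pd.DataFrame,
    years: Sequence,
    traits: Sequence[str],
    spec: MixedModelSpec,
) -> dict:
    """Univariate repeatability fits per year x trait (repeat seasons only)."""
    out: dict = {}
    for i, year in enumerate(years):
        sub = table[table["year"] == year]
        out[year] = {
            trait: gibbs_univariate(sub, trait, replace(spec, seed=spec.seed + 1000 * i + j))
            for j, trait in enumerate(traits)
        }
    return out


def between_year_table(table: pd.DataFrame) -> pd.DataFrame:
    """First assay per (individual, year) for birds seen in >= 2 years."""
    first = table[(table["assay_order"] == 1) & table["individual_id"].notna()]
    n_years = first.groupby("individual_id")["year"].nunique()
    keep = n_years[n_years >= 2].index
    out = first[first["individual_id"].isin(keep)]
    if out.empty:
        raise UnidentifiedModelError(
            "between-year repeatability unidentified: no individual observed in >= 2 years"
        )
    return out.copy()


def between_year_fit(
    table: pd.DataFrame, trait: str, spec: MixedModelSpec
) -> VarCompPosterior:
    """Between-year repeatability: year-first observations as the repeats."""
    return gibbs_univariate(between_year_table(table), trait, spec)


def repeatability_frame(fits: Mapping, traits: Sequence[str]) -> pd.DataFrame:
    """Year x trait repeatability table (posterior mean with 95% CrI)."""
    rows = []
    for year, per_trait in fits.items():
        for trait in traits:
            post = per_trait[trait]
            lo, hi = post.cri(f"R_{trait}")
            rows.append(
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
    return pd.DataFrame(rows)
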
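"""Meta-analysis core: DL pooling, heterogeneity, meta-regression, comparisons."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from behavmeta.effects import EffectSize
from behavmeta.meta import (
    CollinearityError,
    compare_pooled,
    dl_pool,
    heterogeneity,
    magnitude_label,
    meta_regression,
    p_from_estimate_ci,
)


def make_effects(z, v, pair="NA-AG"):
    return [
        EffectSize(year=i, pair=pair, r=float(np.tanh(zz)), z=float(zz), var_z=float(vv), n=10)
        for i, (zz, vv) in enumerate(zip(z, v))
    ]


def naive_dl(z, v):
    """Two-pass textbook DerSimonian-Laird oracle (independent of dl_pool)."""
    z = np.asarray(z, float)
    v = np.asarray(v, float)
    w = 1 / v
    zbar = sum(wi * zi for wi, zi in zip(w, z)) / sum(w)
    q = sum(wi * (zi - zbar) ** 2 for wi, zi in zip(w, z))
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (len(z) - 1)) / c)
    ws = [1 / (vi + tau2) for vi in v]
    pooled = sum(wi * zi for wi, zi in zip(ws, z)) / sum(ws)
    se = sum(ws) ** -0.5
    return pooled, se, tau2, q


class TestDlPool:
    def test_single_effect_passthrough(self):
        res = dl_pool(make_effects([0.4], [0.02]))
        assert res.pooled_z == pytest.approx(0.4)
        assert res.tau2 == 0.0 and res.Q == 0.0 and res.I2 == 0.0
        assert res.se_z == pytest.approx(np.sqrt(0.02))

    def test_identical_effects_have_no_heterogeneity(self):
        res = dl_pool(make_effects([0.3] * 5, [0.04] * 5))
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.I2 == 0.0 and res.tau2 == 0.0
        assert res.pooled_z == pytest.approx(0.3)

    def test_empty_or_bad_variance_rejected(self):
        with pytest.raises(ValueError):
            dl_pool([])
        with pytest.raises(ValueError):
            dl_pool(make_effects([0.1, 0.2], [0.02, 0.0]))

    def test_pooled_within_range_of_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(2, 12)
            z = rng.normal(0, 0.5, k)
            v = rng.uniform(0.005, 0.2, k)
            res = dl_pool(make_effects(z, v))
            assert z.min() - 1e-12 <= res.pooled_z <= z.max() + 1e-12
            assert res.tau2 >= 0 and 0 <= res.I2 < 100

    def test_matches_r_metafor_exactly(self):
        z = [0.3, -0.1, 0.5, 0.2, 0.15]
        v = [0.02, 0.05, 0.01, 0.04, 0.03]
        script = (
            "suppressMessages(library(metafor));"
            f"fit <- rma(yi=c({','.join(map(str, z))}), vi=c({','.join(map(str, v))}), method='DL');"
            "cat(sprintf('%.12f %.12f %.12f %.12f %.12f', fit$b, fit$se, fit$tau2, fit$QE, fit$I2))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        ref = [float(x) for x in out]
        res = dl_pool(make_effects(z, v))
        assert res.pooled_z == pytest.approx(ref[0], abs=1e-10)
        assert res.se_z == pytest.approx(ref[1], abs=1e-10)
        assert res.tau2 == pytest.approx(ref[2], abs=1e-10)
        assert res.Q == pytest.approx(ref[3], abs=1e-10)
        assert res.I2 == pytest.approx(ref[4], abs=1e-8)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_dl_pool_equals_naive_textbook_implementation(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 11))
    z = rng.normal(0.2, 0.4, k)
    v = rng.uniform(0.004, 0.3, k)
    pooled, se, tau2, q = naive_dl(z, v)
    res = dl_pool(make_effects(z, v))
    assert res.pooled_z == pytest.approx(pooled, abs=1e-10)
    assert res.se_z == pytest.approx(se, abs=1e-10)
    assert res.tau2 == pytest.approx(tau2, abs=1e-10)
    assert res.Q == pytest.approx(q, abs=1e-10)


class TestHeterogeneity:
    def test_equal_effects(self):
        q, df, p_q, i2 = heterogeneity(make_effects([0.2] * 4, [0.03] * 4))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 3 and p_q == pytest.approx(1.0) and i2 == 0.0

    def test_q_below_df_truncates_i2_to_zero(self):
        rng = np.random.default_rng(3)
        found = False
        for _ in range(50):
            z = rng.normal(0.3, 0.02, 6)
            res = dl_pool(make_effects(z, [0.1] * 6))
            if res.Q < res.df:
                assert res.I2 == 0.0 and res.tau2 == 0.0
                found = True
        assert found


class TestMetaRegression:
    def test_intercept_only_reduces_to_dl_pool(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0.3, 0.3, 8)
        v = rng.uniform(0.01, 0.1, 8)
        effects = make_effects(z, v)
        pool = dl_pool(effects)
        reg = meta_regression(effects, np.empty((8, 0)), names=[])
        assert reg.beta[0] == pytest.approx(pool.pooled_z, abs=1e-10)
        assert reg.se[0] == pytest.approx(pool.se_z, abs=1e-10)
        assert reg.tau2 == pytest.approx(pool.tau2, abs=1e-10)

    def test_noiseless_slope_recovery(self):
        x = np.linspace(-1, 1, 10)
        z = 0.5 * x
        effects = make_effects(z, [0.01] * 10)
        reg = meta_regression(effects, x, names=["mod"])
        assert reg.beta[reg.names.index("mod")] == pytest.approx(0.5, abs=0.05)
        assert reg.tau2 == pytest.approx(0.0, abs=1e-10)

    def test_null_moderator_rejection_rate_near_nominal(self):
        # under a null moderator the Wald test should reject ~5% of the
        # time; the normal approximation at k=8 is mildly conservative, so
        # the band is asymmetric around the nominal level
        rng = np.random.default_rng(11)
        rejections = 0
        n_reps = 5000
        for _ in range(n_reps):
            z = rng.normal(0.3, 0.1, 8)
            x = rng.normal(size=8)
            reg = meta_regression(make_effects(z, [0.01] * 8), x, names=["mod"])
            rejections += reg.p[reg.names.index("mod")] < 0.05
        assert 0.025 <= rejections / n_reps <= 0.065

    def test_rank_deficient_design_names_columns(self):
        x = np.column_stack([np.arange(8.0), 2.0 * np.arange(8.0)])
        with pytest.raises(CollinearityError, match="dup"):
            meta_regression(
                make_effects(np.linspace(0, 1, 8), [0.02] * 8),
                x,
                names=["mod", "dup"],
            )

    def test_needs_more_effects_than_coefficients(self):
        with pytest.raises(ValueError, match="more effects"):
            meta_regression(
                make_effects([0.1, 0.2, 0.3], [0.02] * 3),
                np.arange(6.0).reshape(3, 2),
                names=["a", "b"],
            )


class TestComparisons:
    def test_pooled_effect_comparison_matches_published_value(self):
        z, p = compare_pooled(0.155, 255, 0.320, 307)
        assert z == pytest.approx(2.06, abs=0.01)
        assert p == pytest.approx(0.039, abs=0.001)

    def test_equal_correlations_give_zero(self):
        z, p = compare_pooled(0.25, 50, 0.25, 80)
        assert z == 0.0 and p == 1.0

    def test_brute_force_formula(self):
        z, _ = compare_pooled(0.1, 103, 0.3, 103)
        brute = (np.arctanh(0.3) - np.arctanh(0.1)) / np.sqrt(2 / 100)
        assert z == pytest.approx(brute, abs=1e-12)

    def test_p_from_estimate_ci_published_value(self):
        assert p_from_estimate_ci(0.155, 0.027, 0.278) == pytest.approx(0.018, abs=0.002)

    def test_p_from_centered_ci_is_one(self):
        assert p_from_estimate_ci(0.0, -0.2, 0.2) == pytest.approx(1.0)

    def test_symmetric_z_ci_reproduces_se(self):
        se = 0.0817
        z0 = 0.31
        lo, hi = np.tanh(z0 - 1.959963984540054 * se), np.tanh(z0 + 1.959963984540054 * se)
        implied_se = (np.arctanh(hi) - np.arctanh(lo)) / (2 * 1.959963984540054)
        assert implied_se == pytest.approx(se, abs=1e-12)
        p = p_from_estimate_ci(np.tanh(z0), lo, hi)
        from scipy.stats import norm

        assert p == pytest.approx(2 * norm.sf(z0 / se), abs=1e-12)


def test_magnitude_benchmarks():
    assert magnitude_label(0.1) == "small"
    assert magnitude_label(-0.3) == "moderate"
    assert magnitude_label(0.5) == "strong"
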
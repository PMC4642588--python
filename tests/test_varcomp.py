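"""Gibbs sampler: conjugate updates, PSRF, recovery, study-layout drivers."""

import numpy as np
import pandas as pd
import pytest

from behavmeta.synthetic import simulate_multiyear
from behavmeta.varcomp import (
    MixedModelSpec,
    UnidentifiedModelError,
    between_year_fit,
    between_year_table,
    draw_invgamma,
    draw_invwishart_2x2,
    gibbs_bivariate,
    gibbs_univariate,
    invgamma_post_params,
    psrf,
    repeatability_frame,
    within_year_fits,
)
from conftest import make_balanced_config

FAST = MixedModelSpec(iterations=4000, burn_in=1000, thin=4, chains=2, seed=17)


class TestPsrf:
    def test_identical_chains_give_one(self):
        draws = np.tile(np.random.default_rng(0).normal(size=500), (2, 1))
        assert psrf(draws) == pytest.approx(1.0, abs=0.02)

    def test_disjoint_chains_blow_up(self):
        rng = np.random.default_rng(1)
        chains = np.vstack([rng.normal(0, 1, 400), rng.normal(5, 1, 400)])
        assert psrf(chains) > 2.0

    def test_matches_textbook_formula_on_fixed_array(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        m, n = chains.shape
        w = chains.var(axis=1, ddof=1).mean()
        b = n * chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert psrf(chains) == pytest.approx(expected, abs=1e-14)


class TestConjugateUpdates:
    def test_invgamma_posterior_params_match_closed_form(self):
        # toy data: 3 individual effects with known sum of squares
        b = np.array([0.5, -1.0, 2.0])
        shape, scale = invgamma_post_params(0.001, 0.001, b)
        assert shape == pytest.approx(0.001 + 1.5)
        assert scale == pytest.approx(0.001 + 0.5 * 5.25)

    def test_invgamma_draw_moments(self):
        rng = np.random.default_rng(2)
        a, b = 12.0, 30.0
        draws = np.array([draw_invgamma(rng, a, b) for _ in range(40000)])
        assert draws.mean() == pytest.approx(b / (a - 1), rel=0.02)
        assert draws.var() == pytest.approx(b**2 / ((a - 1) ** 2 * (a - 2)), rel=0.1)

    def test_invwishart_draw_moments(self):
        rng = np.random.default_rng(3)
        scale = np.array([[2.0, 0.6], [0.6, 1.0]])
        df = 12.0
        draws = np.mean(
            [draw_invwishart_2x2(rng, df, scale) for _ in range(40000)], axis=0
        )
        expected = scale / (df - 2 - 1)  # mean = scale / (df - p - 1)
        np.testing.assert_allclose(draws, expected, rtol=0.05)


class TestUnivariate:
    def test_null_repeatability_recovered(self):
        cfg = make_balanced_config(n=200, reps=4, repeatability=(0.0, 0.0, 0.0), seed=21)
        table = simulate_multiyear(cfg)
        post = gibbs_univariate(table, "NA", FAST)
        assert post.mean("R_NA") < 0.08

    def test_half_repeatability_recovered_and_matches_anova(self):
        cfg = make_balanced_config(n=200, reps=4, seed=3)
        table = simulate_multiyear(cfg)
        post = gibbs_univariate(table, "NA", FAST)
        assert post.mean("R_NA") == pytest.approx(0.5, abs=0.10)
        g = table.groupby("individual_id")["novelty_avoidance_s"]
        msb = 4 * g.mean().var(ddof=1)
        msw = g.var(ddof=1).mean()
        icc = (msb - msw) / (msb + 3 * msw)
        assert post.mean("R_NA") == pytest.approx(icc, abs=0.05)
        assert post.max_psrf() < 1.1

    def test_date_slope_recovered_against_demeaned_ols(self):
        cfg = make_balanced_config(n=200, reps=4, date_slopes=(2.0, 0.0, 0.0), seed=29)
        table = simulate_multiyear(cfg)
        post = gibbs_univariate(table, "NA", FAST)
        assert post.mean("date_slope") == pytest.approx(2.0, abs=0.2)
        # OLS on individual-demeaned data as the frequentist oracle
        d = table.copy()
        d["y_dm"] = d["novelty_avoidance_s"] - d.groupby("individual_id")[
            "novelty_avoidance_s"
        ].transform("mean")
        d["x_dm"] = d["assay_date"] - d.groupby("individual_id")["assay_date"].transform(
            "mean"
        )
        ols = (d["x_dm"] @ d["y_dm"]) / (d["x_dm"] @ d["x_dm"])
        assert post.mean("date_slope") == pytest.approx(ols, abs=0.1)

    def test_no_repeats_raises_unidentified(self):
        cfg = make_balanced_config(n=30, reps=1, seed=5)
        table = simulate_multiyear(cfg)
        with pytest.raises(UnidentifiedModelError, match="unidentified"):
            gibbs_univariate(table, "NA", FAST)

    def test_repeatability_invariant_to_affine_rescaling(self):
        cfg = make_balanced_config(n=120, reps=3, seed=37)
        table = simulate_multiyear(cfg)
        post_raw = gibbs_univariate(table, "NA", FAST)
        scaled = table.copy()
        scaled["novelty_avoidance_s"] = 10.0 * scaled["novelty_avoidance_s"] + 5.0
        post_scaled = gibbs_univariate(scaled, "NA", FAST)
        assert post_scaled.mean("R_NA") == pytest.approx(post_raw.mean("R_NA"), abs=0.02)

    def test_seed_determinism(self):
        cfg = make_balanced_config(n=60, reps=3, seed=41)
        table = simulate_multiyear(cfg)
        a = gibbs_univariate(table, "NA", FAST)
        b = gibbs_univariate(table, "NA", FAST)
        np.testing.assert_array_equal(a.params["R_NA"], b.params["R_NA"])


class TestBivariate:
    def test_component_recovery(self, balanced_table):
        table, _ = balanced_table
        post = gibbs_bivariate(table, "NA", "AG", FAST)
        assert post.mean("r_ind") == pytest.approx(0.6, abs=0.15)
        assert post.mean("r_e") == pytest.approx(0.1, abs=0.15)
        assert post.mean("R_NA") == pytest.approx(0.5, abs=0.10)
        assert post.mean("R_AG") == pytest.approx(0.5, abs=0.10)
        assert post.max_psrf() < 1.1

    def test_zero_individual_variance_leaves_r_ind_diffuse(self):
        cfg = make_balanced_config(
            n=150, reps=3, repeatability=(0.02, 0.02, 0.02), seed=43
        )
        table = simulate_multiyear(cfg)
        post = gibbs_bivariate(table, "NA", "AG", FAST)
        lo, hi = post.cri("r_ind")
        assert hi - lo > 0.5  # weakly identified: wide posterior

    def test_null_correlations_covered_by_credible_intervals(self):
        covered_ind = covered_e = 0
        n_reps = 12
        spec = MixedModelSpec(iterations=3000, burn_in=800, thin=4, chains=2, seed=0)
        for rep in range(n_reps):
            cfg = make_balanced_config(n=100, reps=3, seed=600 + rep)
            table = simulate_multiyear(cfg)
            post = gibbs_bivariate(
                table, "NA", "AG", MixedModelSpec(**{**spec.__dict__, "seed": rep})
            )
            lo, hi = post.cri("r_ind")
            covered_ind += lo <= 0.0 <= hi
            lo, hi = post.cri("r_e")
            covered_e += lo <= 0.0 <= hi
        assert covered_ind >= n_reps - 2
        assert covered_e >= n_reps - 2

    def test_every_draw_is_valid(self, balanced_table):
        table, _ = balanced_table
        post = gibbs_bivariate(table, "NA", "AG", FAST)
        for trait in ("NA", "AG"):
            draws = post.draws(f"R_{trait}")
            assert ((draws >= 0) & (draws <= 1)).all()
        for name in ("r_ind", "r_e"):
            draws = post.draws(name)
            assert ((draws >= -1) & (draws <= 1)).all()


class TestStudyLayout:
    def test_within_year_fits_subset_years(self, study_table):
        table, cfg = study_table
        spec = MixedModelSpec(iterations=1500, burn_in=500, thin=5, chains=2, seed=7)
        fits = within_year_fits(table, [2009], ["RT"], spec)
        assert set(fits) == {2009}
        post = fits[2009]["RT"]
        n_year = table[
            (table["year"] == 2009) & table["individual_id"].notna()
        ]["individual_id"].nunique()
        assert post.n_individuals == n_year
        frame = repeatability_frame(fits, ["RT"])
        assert list(frame["year"]) == [2009] and list(frame["trait"]) == ["RT"]

    def test_all_singletons_raise_unidentified(self):
        cfg = make_balanced_config(n=40, reps=1, seed=47)
        table = simulate_multiyear(cfg)
        spec = MixedModelSpec(iterations=1000, burn_in=200, thin=2, chains=2, seed=1)
        with pytest.raises(UnidentifiedModelError):
            within_year_fits(table, [2001], ["NA"], spec)[2001]

    def test_between_year_table_requires_multi_year_birds(self, study_table):
        table, _ = study_table
        # the generator never re-uses identities across years
        with pytest.raises(UnidentifiedModelError, match="between-year"):
            between_year_table(table)

    def test_between_smaller_than_within_on_crossed_design(self):
        # hand-built cross-year data: between-year R = 0.1, within-year R = 0.4
        rng = np.random.default_rng(53)
        n_ind, n_years = 60, 4
        rows = []
        b_across = rng.normal(0, np.sqrt(0.1), n_ind)  # stable across years
        for year in range(2001, 2001 + n_years):
            b_within = rng.normal(0, np.sqrt(0.3), n_ind)  # year-specific level
            for i in range(n_ind):
                for j in range(3):
                    rows.append(
                        {
                            "year": year,
                            "individual_id": f"id{i}",
                            "assay_order": j + 1,
                            "assay_date": int(rng.integers(1, 30)),
                            "novelty_avoidance_s": b_across[i]
                            + b_within[i]
                            + rng.normal(0, np.sqrt(0.6)),
                            "aggression_latency_s": 20.0,
                            "fid_m": 20.0,
                            "captured": True,
                            "age_class": "adult",
                            "censored_aggression": False,
                        }
                    )
        table = pd.DataFrame(rows)
        spec = MixedModelSpec(iterations=3000, burn_in=1000, thin=4, chains=2, seed=3)
        between = between_year_fit(table, "NA", spec)
        within = gibbs_univariate(table[table["year"] == 2001], "NA", spec)
        assert between.mean("R_NA") < within.mean("R_NA")
        assert between.mean("R_NA") == pytest.approx(0.1, abs=0.12)
        assert within.mean("R_NA") == pytest.approx(0.4, abs=0.15)
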
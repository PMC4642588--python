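"""Simulator: ground-truth recovery, censoring, capture bias, CSV round trip."""

import numpy as np
import pandas as pd
import pytest

from behavmeta.studydata import TRAIT_COLUMNS
from behavmeta.synthetic import (
    CaptureModel,
    CovarianceError,
    SchemaError,
    apply_capture_bias,
    assay_csv_text,
    assemble_covariances,
    read_assay_csv,
    simulate_multiyear,
    study_like_config,
    write_assay_csv,
)
from conftest import make_balanced_config


def anova_icc(table: pd.DataFrame, column: str, reps: int) -> float:
    """One-way ANOVA intraclass correlation (closed-form oracle)."""
    g = table.groupby("individual_id")[column]
    msb = reps * g.mean().var(ddof=1)
    msw = g.var(ddof=1).mean()
    return (msb - msw) / (msb + (reps - 1) * msw)


class TestConfigValidation:
    def test_non_psd_sigma_rejected_with_matrix_name(self):
        bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        cfg = make_balanced_config()
        cfg.sigma_ind = bad
        with pytest.raises(CovarianceError, match="sigma_ind"):
            cfg.validate()
        cfg = make_balanced_config()
        cfg.sigma_e = bad
        with pytest.raises(CovarianceError, match="sigma_e"):
            simulate_multiyear(cfg)

    def test_repeats_support_outside_1_to_6_rejected(self):
        cfg = make_balanced_config()
        cfg.repeats_distribution = {7: 1.0}
        with pytest.raises(ValueError, match="1..6"):
            cfg.validate()

    def test_nonpositive_censor_threshold_rejected(self):
        cfg = make_balanced_config()
        cfg.censor_threshold = 0.0
        with pytest.raises(ValueError, match="censor_threshold"):
            cfg.validate()


class TestGroundTruth:
    def test_no_individual_signal_shrinks_between_individual_variance(self):
        # sigma_ind = 0: variance of per-individual means is V_e / reps
        reps = 6
        cfg = make_balanced_config(
            n=2000, reps=reps, repeatability=(0.0, 0.0, 0.0), seed=11
        )
        table = simulate_multiyear(cfg)
        means = table.groupby("individual_id")["novelty_avoidance_s"].mean()
        assert means.var(ddof=1) == pytest.approx(1.0 / reps, rel=0.15)

    def test_perfect_individual_correlation_without_noise(self):
        cfg = make_balanced_config(
            n=50,
            reps=2,
            repeatability=(1.0, 1.0, 1.0),
            r_ind={"NA-AG": 1.0},
            seed=7,
        )
        table = simulate_multiyear(cfg)
        means = table.groupby("individual_id")[list(TRAIT_COLUMNS)].mean()
        rho = (
            means["novelty_avoidance_s"]
            .rank()
            .corr(means["aggression_latency_s"].rank())
        )
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_icc_recovery_against_anova_oracle(self):
        cfg = make_balanced_config(n=500, reps=4, seed=19)
        table = simulate_multiyear(cfg)
        for col in TRAIT_COLUMNS:
            assert anova_icc(table, col, 4) == pytest.approx(0.5, abs=0.07)


class TestCensoring:
    def test_ceiling_respected(self, study_table):
        table, cfg = study_table
        assert (table["aggression_latency_s"] <= cfg.censor_threshold).all()
        assert (table["novelty_avoidance_s"].abs() <= cfg.censor_threshold).all()
        ceiling = table["aggression_latency_s"] == cfg.censor_threshold
        assert (table["censored_aggression"] == ceiling).all()

    def test_censored_fraction_increases_with_latency_mean(self):
        fractions = []
        for mu_ag in (100.0, 200.0, 300.0, 400.0):
            cfg = make_balanced_config(n=400, reps=1, mu=(0.0, mu_ag, 20.0), seed=23)
            cfg.censor_threshold = 301.0
            cfg.sigma_e = np.diag([1.0, 80.0**2, 1.0])
            cfg.sigma_ind = np.diag([0.5, 40.0**2, 0.5])
            fractions.append(simulate_multiyear(cfg)["censored_aggression"].mean())
        assert all(a < b for a, b in zip(fractions, fractions[1:]))


class TestCaptureBias:
    def test_infinite_intercept_captures_everyone(self, balanced_table):
        table, _ = balanced_table
        out = apply_capture_bias(table, CaptureModel(intercept=np.inf), seed=0)
        assert out["captured"].all()
        assert out["individual_id"].notna().all()
        assert len(out) == len(table)

    def test_negative_infinite_intercept_loses_all_identities(self, balanced_table):
        table, _ = balanced_table
        out = apply_capture_bias(table, CaptureModel(intercept=-np.inf), seed=0)
        assert not out["captured"].any()
        assert out["individual_id"].isna().all()
        assert (out["assay_order"] == 1).all()

    def test_shy_birds_harder_to_capture(self):
        # strong negative slope on the stored (smaller = bolder) score:
        # captured birds should be bolder, i.e. have smaller scores
        cfg = make_balanced_config(n=1000, reps=1, seed=31)
        table = simulate_multiyear(cfg)
        model = CaptureModel(intercept=0.0, slopes=(-2.0, 0.0, 0.0))
        out = apply_capture_bias(table, model, seed=5)
        full = out["novelty_avoidance_s"]
        captured = out.loc[out["captured"], "novelty_avoidance_s"]
        from scipy.stats import mannwhitneyu

        stat = mannwhitneyu(captured, full[~out["captured"]], alternative="less")
        assert captured.mean() < full.mean()
        assert stat.pvalue < 1e-6

    def test_anonymous_birds_never_reassayed(self, study_table):
        table, _ = study_table
        anonymous = table[table["individual_id"].isna()]
        assert (anonymous["assay_order"] == 1).all()


class TestDeterminism:
    def test_identical_config_and_seed_gives_byte_identical_csv(self):
        cfg_a = study_like_config(seed=9)
        cfg_b = study_like_config(seed=9)
        assert assay_csv_text(simulate_multiyear(cfg_a)) == assay_csv_text(
            simulate_multiyear(cfg_b)
        )

    def test_different_seed_gives_different_data(self):
        a = simulate_multiyear(study_like_config(seed=1))
        b = simulate_multiyear(study_like_config(seed=2))
        assert assay_csv_text(a) != assay_csv_text(b)

    def test_appending_a_year_preserves_earlier_years(self):
        cfg = make_balanced_config(n=40, reps=2, seed=13)
        short = simulate_multiyear(cfg)
        cfg_long = make_balanced_config(n=40, reps=2, seed=13)
        cfg_long.years = (2001, 2002)
        long = simulate_multiyear(cfg_long)
        pd.testing.assert_frame_equal(
            short.reset_index(drop=True),
            long[long["year"] == 2001].reset_index(drop=True),
        )


class TestCsvRoundTrip:
    def test_empty_table_gives_header_only_file(self):
        empty = simulate_multiyear(make_balanced_config(n=1, reps=1)).iloc[:0]
        text = assay_csv_text(empty)
        assert text.strip().count("\n") == 0
        assert text.startswith("year,individual_id")

    def test_round_trip_equality(self, study_table, tmp_path):
        table, _ = study_table
        path = tmp_path / "assays.csv"
        write_assay_csv(table, path)
        back = read_assay_csv(path)
        assert len(back) == len(table)
        assert back["individual_id"].isna().sum() == table["individual_id"].isna().sum()
        for col in TRAIT_COLUMNS:
            np.testing.assert_allclose(back[col], table[col], atol=1e-6)
        assert (back["captured"] == table["captured"].to_numpy()).all()
        assert (back["censored_aggression"] == table["censored_aggression"].to_numpy()).all()
        # a second write of the parsed table is byte-identical
        assert assay_csv_text(back) == path.read_text()

    def test_unknown_column_raises_schema_error(self, tmp_path):
        table = simulate_multiyear(make_balanced_config(n=3, reps=1))
        path = tmp_path / "assays.csv"
        frame = table.copy()
        frame["extra"] = 1
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="extra"):
            read_assay_csv(path)

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        table = simulate_multiyear(make_balanced_config(n=3, reps=1))
        path = tmp_path / "assays.csv"
        write_assay_csv(table, path)
        lines = path.read_text().splitlines()
        fields = lines[2].split(",")
        fields[3] = "not-a-date"
        lines[2] = ",".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError, match=r"lines \[3\]"):
            read_assay_csv(path)


def test_mean_repeats_matches_design(study_table):
    table, _ = study_table
    per_bird = table[table["individual_id"].notna()].groupby(
        ["year", "individual_id"]
    ).size()
    resampled = per_bird[per_bird >= 2]
    assert resampled.mean() == pytest.approx(2.74, abs=0.25)
    assert resampled.min() >= 2 and resampled.max() <= 6


def test_assemble_covariances_round_trip():
    si, se = assemble_covariances(
        (2.0, 3.0, 4.0), (0.3, 0.4, 0.5), {"NA-AG": 0.6, "AG-RT": -0.2}, {"NA-RT": 0.3}
    )
    np.testing.assert_allclose(np.diag(si) + np.diag(se), [4.0, 9.0, 16.0])
    assert si[0, 1] / np.sqrt(si[0, 0] * si[1, 1]) == pytest.approx(0.6)
    assert si[1, 2] / np.sqrt(si[1, 1] * si[2, 2]) == pytest.approx(-0.2)
    assert se[0, 2] / np.sqrt(se[0, 0] * se[2, 2]) == pytest.approx(0.3)
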
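"""Published summary statistics of the 8-year collared flycatcher field study.

The pipeline was designed around a long-term nest-box study of male collared
flycatchers (*Ficedula albicollis*) in which three boldness-related behaviors
were assayed during courtship: novelty avoidance (latency difference to land
on the nest-box with vs. without a novel object, seconds), aggression
(latency to attack a caged decoy male, seconds) and risk-taking (flight
initiation distance toward an approaching observer, meters).  The raw field
data were never deposited; what is public are the yearly summary tables.
Those printed summaries are kept here as plain data.  They serve two roles:

* the synthetic-data generator uses them as the template for realistic
  year sizes, trait scales and repeatability levels;
* the sample-size-weighted inference layer can be re-run directly on the
  published year-specific repeatability estimates.

All latencies and distances are stored so that a SMALLER value means a
BOLDER bird (shorter approach/attack latency, shorter flight initiation
distance).
"""

from __future__ import annotations

import pandas as pd

#: Trait column names used across the package (assay CSV schema).
TRAIT_COLUMNS = ("novelty_avoidance_s", "aggression_latency_s", "fid_m")

#: Short trait codes: NA = novelty avoidance, AG = aggression (latency to
#: fight), RT = risk-taking (flight initiation distance).
TRAIT_CODES = {"NA": "novelty_avoidance_s", "AG": "aggression_latency_s", "RT": "fid_m"}

#: Trait-pair labels in canonical order.
PAIRS = ("NA-AG", "NA-RT", "AG-RT")

#: Assay ceiling: latencies were recorded as 301 s when the bird never
#: performed the focal act within the 5-minute observation.
CENSOR_THRESHOLD_S = 301.0

#: Mean number of assays per re-sampled male (range 2..6).
MEAN_REPEATS_RESAMPLED = 2.74

# ---------------------------------------------------------------------------
# Yearly first-assay summaries (per trait: sample size, mean, SE of the mean).
# The 2008 season had fewer than five assayed males and was excluded from all
# published analyses; it is kept here only as template metadata.
# ---------------------------------------------------------------------------

_YEARLY_ROWS = [
    # year, na_n, na_mean, na_se, ag_n, ag_mean, ag_se, rt_n, rt_mean, rt_se
    (2007, 21, 113.2, 36.8, 23, 50.4, 21.8, 21, 11.8, 1.5),
    (2008, 2, 121.5, 154.5, 0, float("nan"), float("nan"), 3, 10.0, 5.5),
    (2009, 33, 12.5, 23.1, 34, 29.7, 12.7, 32, 13.0, 1.4),
    (2010, 28, 108.5, 27.5, 31, 50.3, 17.2, 31, 14.0, 1.2),
    (2011, 40, 195.6, 17.6, 54, 55.8, 13.9, 51, 10.3, 0.7),
    (2012, 17, 201.1, 26.9, 25, 92.3, 24.4, 22, 13.5, 1.9),
    (2013, 44, 138.6, 22.8, 56, 44.5, 12.8, 54, 9.8, 0.8),
    (2014, 45, 119.1, 18.3, 53, 40.0, 11.7, 52, 12.6, 1.1),
    (2015, 40, 110.6, 24.1, 46, 17.4, 7.8, 47, 7.5, 0.7),
]

_YEARLY_COLS = [
    "year",
    "na_n", "na_mean", "na_se",
    "ag_n", "ag_mean", "ag_se",
    "rt_n", "rt_mean", "rt_se",
]


def yearly_summaries(include_excluded: bool = False) -> pd.DataFrame:
    """Published per-year first-assay summaries for the three behaviors.

    Parameters
    ----------
    include_excluded
        If True, keep the under-sampled 2008 season (n < 5, not all
        behaviors screened); by default it is dropped, mirroring how the
        study treated it.
    """
    df = pd.DataFrame(_YEARLY_ROWS, columns=_YEARLY_COLS)
    if not include_excluded:
        df = df[df["year"] != 2008].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Published pooled phenotypic correlations (all 8 analysis years, first
# assays, all males including non-captured ones).
# ---------------------------------------------------------------------------

#: pair -> (pooled r, 95% CI low, 95% CI high, total pairwise N, two-sided p)
POOLED_PHENOTYPIC = {
    "NA-AG": (0.182, -0.011, 0.361, 264, 0.065),
    "NA-RT": (0.155, 0.027, 0.278, 255, 0.018),
    "AG-RT": (0.320, 0.211, 0.420, 307, None),  # printed only as P < 0.001
}

# ---------------------------------------------------------------------------
# Published within-year repeatabilities (5 seasons with repeated assays) and
# between-year repeatabilities (males tested in >= 2 seasons, first assay of
# each season).  N is the number of individuals entering the fit.
# ---------------------------------------------------------------------------

REPEAT_YEARS = (2009, 2011, 2013, 2014, 2015)

_REPEATABILITY_ROWS = [
    # year, na_n, na_R, ag_n, ag_R, rt_n, rt_R
    (2009, 27, 0.449, 27, 0.345, 26, 0.652),
    (2011, 16, 0.047, 16, 0.037, 16, 0.116),
    (2013, 25, 0.235, 28, 0.061, 28, 0.414),
    (2014, 16, 0.046, 17, 0.185, 17, 0.517),
    (2015, 18, 0.104, 19, 0.147, 19, 0.109),
]


def within_year_repeatabilities() -> pd.DataFrame:
    """Published within-year repeatability point estimates with their N."""
    return pd.DataFrame(
        _REPEATABILITY_ROWS,
        columns=["year", "na_n", "na_R", "ag_n", "ag_R", "rt_n", "rt_R"],
    )


#: trait code -> (N individuals, between-year repeatability point estimate)
BETWEEN_YEAR_REPEATABILITY = {
    "NA": (19, 0.021),
    "AG": (21, 0.058),
    "RT": (21, 0.117),
}

#: Two-sided p-values of the three weighted one-sample comparisons of
#: within-year vs between-year repeatability (novelty avoidance, aggression,
#: risk-taking), inputs to the combined-probability summary.
WITHIN_VS_BETWEEN_P = (0.078, 0.145, 0.062)
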
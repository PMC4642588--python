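"""Year-level socio-ecological moderators for the meta-regression.

Four covariates describe each breeding season: mean daily spring
temperature (a food-supply proxy), previous-year nest predation rate,
a per-day competition index for nest boxes, and the proportion of
juvenile males among those assayed.  Proportion-based covariates are
square-root transformed before entering the design; predation acts with a
one-year lag (predation happens after the assays, so it can only shape the
next season's males).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns treated as proportions (square-root transformed before modeling).
PROPORTION_COLUMNS = ("predation_prev", "competition", "prop_juvenile")


def shortest_window_days(dates: Sequence[float], coverage: float = 0.9) -> int:
    """Length in days of the shortest window holding >= ``coverage`` of dates.

    Window length counts both endpoints (a single day is length 1).  The
    alternative central-quantile convention is in :func:`central_window_days`.
    """
    d = np.sort(np.asarray(dates, dtype=float))
    if d.size == 0:
        raise ValueError("need at least one breeding date")
    m = int(np.ceil(coverage * d.size))
    m = max(m, 1)
    spans = d[m - 1 :] - d[: d.size - m + 1]
    return int(max(1, np.round(spans.min() + 1)))


def central_window_days(dates: Sequence[float], coverage: float = 0.9) -> int:
    """Central-quantile alternative: distance between the (1-c)/2 and (1+c)/2 quantiles."""
    d = np.asarray(dates, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one breeding date")
    a = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(d, [a, 1.0 - a])
    return int(max(1, np.round(hi - lo + 1)))


def competition_index(
    breeding_efforts: int,
    available_boxes: int,
    breeding_dates: Sequence[float] | None = None,
    interval_days: int | None = None,
    coverage: float = 0.9,
    window: str = "shortest",
) -> float:
    """Per-day competition: (efforts / boxes) / days-of-the-90%-breeding-window.

    Either raw breeding initiation dates or a precomputed ``interval_days``
    may be supplied.
    """
    if available_boxes <= 0:
        raise ValueError("available_boxes must be positive")
    if breeding_efforts < 0:
        raise ValueError("breeding_efforts must be non-negative")
    if interval_days is None:
        if breeding_dates is None:
            raise ValueError("supply either breeding_dates or interval_days")
        fn = shortest_window_days if window == "shortest" else central_window_days
        interval_days = fn(breeding_dates, coverage)
    if interval_days < 1:
        raise ValueError("interval_days must be >= 1")
    return breeding_efforts / available_boxes / interval_days


def age_structure(n_juvenile: int, n_total: int) -> float:
    """Proportion of juveniles among assayed males."""
    if n_total <= 0 or not 0 <= n_juvenile <= n_total:
        raise ValueError("need 0 <= n_juvenile <= n_total with n_total > 0")
    return n_juvenile / n_total


def lag_predation(series: Mapping[int, float]) -> dict[int, float]:
    """Shift predation rates forward one year: year y gets the rate of y - 1.

    Years whose predecessor is absent are dropped (with a warning), which in
    practice removes the first study year from the meta-regression design.
    """
    years = sorted(series)
    out: dict[int, float] = {}
    for y in years:
        if y - 1 in series:
            out[y] = float(series[y - 1])
        else:
            logger.warning("year %s dropped from lagged predation: no rate for %s", y, y - 1)
    return out


def sqrt_transform(values):
    """Square root of proportion-scale values; negative input is a domain error."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("square-root transform undefined for negative values")
    return np.sqrt(v)


def collinearity_screen(X: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Pairwise moderator correlations, flagging |r| > threshold for exclusion."""
    cols = list(X.columns)
    rows = []
    arr = X.to_numpy(dtype=float)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if len(X) < 3:
                r = float("nan")  # too few years to judge collinearity
            else:
                r = float(np.corrcoef(arr[:, i], arr[:, j])[0, 1])
            rows.append(
                {
                    "moderator_a": cols[i],
                    "moderator_b": cols[j],
                    "r": r,
                    "flagged": bool(abs(r) > threshold),
                }
            )
    return pd.DataFrame(rows)


def build_moderator_table(raw: pd.DataFrame, window: str = "shortest") -> pd.DataFrame:
    """Assemble the modeling-scale moderator table from raw yearly inputs.

    ``raw`` columns: ``year``, ``mean_temp_c``, ``predation_rate`` (same
    year; lagging is applied here), ``breeding_efforts``,
    ``available_boxes``, and either ``interval_days`` or a
    ``breeding_dates`` list column, plus ``n_juvenile`` and ``n_total``.
    Output has the four moderators with proportion-based ones also given as
    ``*_sqrt`` columns; the first year has no lagged predation (NaN).
    """
    req = {"year", "mean_temp_c", "predation_rate", "breeding_efforts",
           "available_boxes", "n_juvenile", "n_total"}
    missing = req - set(raw.columns)
    if missing:
        raise ValueError(f"moderator table missing columns: {sorted(missing)}")
    lagged = lag_predation(dict(zip(raw["year"].astype(int), raw["predation_rate"])))
    rows = []
    for rec in raw.to_dict("records"):
        year = int(rec["year"])
        comp = competition_index(
            int(rec["breeding_efforts"]),
            int(rec["available_boxes"]),
            breeding_dates=rec.get("breeding_dates"),
            interval_days=(
                int(rec["interval_days"]) if "interval_days" in rec and pd.notna(rec.get("interval_days")) else None
            ),
            window=window,
        )
        rows.append(
            {
                "year": year,
                "mean_temp": float(rec["mean_temp_c"]),
                "predation_prev": lagged.get(year, np.nan),
                "competition": comp,
                "prop_juvenile": age_structure(int(rec["n_juvenile"]), int(rec["n_total"])),
            }
        )
    out = pd.DataFrame(rows)
    for col in PROPORTION_COLUMNS:
        vals = out[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        transformed = np.full_like(vals, np.nan)
        transformed[ok] = sqrt_transform(vals[ok])
        out[f"{col}_sqrt"] = transformed
    return out


#: Modeling-scale moderator columns in canonical order (temperature raw,
#: proportions square-root transformed).
MODEL_COLUMNS = ("mean_temp", "predation_prev_sqrt", "competition_sqrt", "prop_juvenile_sqrt")


def design_for_years(
    moderators: pd.DataFrame, years: Sequence, columns: Sequence[str]
) -> tuple[np.ndarray, list]:
    """Moderator design matrix aligned to the given effect-size years.

    Years with any missing moderator value (e.g. no lagged predation for the
    first season) are dropped; the retained year list is returned alongside.
    """
    sub = moderators.set_index("year").reindex(list(years))[list(columns)]
    keep = sub.notna().all(axis=1)
    dropped = [y for y, k in zip(years, keep) if not k]
    if dropped:
        logger.warning("years %s dropped from meta-regression design (missing moderators)", dropped)
    return sub[keep].to_numpy(dtype=float), list(sub.index[keep])
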
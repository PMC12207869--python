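"""Model covariates on the study's exact averaging windows.

For day records: air temperature averaged over the active-phase
(07:00-17:00) of the same date, and that date's maximum wind speed.
For night records: air temperature averaged over the 24 h from 07:00 of
the preceding active-phase to 07:00 after the rest-phase, and the maximum
wind speed of the preceding daytime's date. Body mass (at capture) and sex
come from the bird metadata. All windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from datetime import date as date_t, datetime, time, timedelta

import numpy as np
import pandas as pd

from .config import AnalysisOptions
from .ingest import LoadedData

__all__ = ["ta_window_mean", "join_covariates"]

log = logging.getLogger(__name__)


def ta_window_mean(
    weather: pd.DataFrame,
    start: datetime,
    end: datetime,
    interval_min: int = 10,
    min_coverage: float = 0.9,
) -> float:
    """Mean air temperature over ``[start, end)``; NaN when coverage of the
    window's grid slots falls below ``min_coverage``."""
    ts = weather["timestamp"]
    mask = (ts >= start) & (ts < end)
    vals = weather.loc[mask, "ta_c"].dropna()
    n_slots = (end - start).total_seconds() / 60.0 / interval_min
    if n_slots <= 0:
        raise ValueError("empty averaging window")
    if len(vals) < min_coverage * n_slots:
        log.info("weather coverage %.0f%% below %.0f%% for window %s..%s",
                 100 * len(vals) / n_slots, 100 * min_coverage, start, end)
        return float("nan")
    return float(vals.mean())


def _meta_maps(metadata: pd.DataFrame):
    mass = dict(zip(metadata["bird_id"], metadata["body_mass_g"]))
    sex = dict(zip(metadata["bird_id"], metadata["sex"]))
    return mass, sex


def join_covariates(
    nights: pd.DataFrame,
    days: pd.DataFrame,
    data: LoadedData,
    options: AnalysisOptions | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model-ready night and day tables.

    The treatment factor is coded 0/1 with control as the reference level,
    so fitted coefficients read as treatment minus control. Records with
    an incomplete covariate row (insufficient weather coverage, missing
    mass or sex) are excluded with a logged reason.
    """
    options = options or AnalysisOptions()
    cov = options.weather_coverage
    interval = data.config.sample_interval_min
    mass, sex = _meta_maps(data.metadata)
    wind = dict(zip(data.wind["date"], data.wind["wind_max_kmh"]))

    def at(day: date_t, clock: time) -> datetime:
        return datetime.combine(day, clock)

    def finish(records: pd.DataFrame, ta_col: str) -> pd.DataFrame:
        records = records.copy()
        for i, r in records.iterrows():
            if not r["included"]:
                continue
            reason = None
            if pd.isna(r[ta_col]):
                reason = "no_weather"
            elif pd.isna(r["wind_daily_max"]):
                reason = "no_wind"
            elif pd.isna(r["body_mass_g"]) or pd.isna(r["sex"]):
                reason = "no_metadata"
            if reason:
                records.loc[i, ["included", "exclusion_reason"]] = [False, reason]
                log.info("%s %s excluded: %s", r["bird_id"],
                         r.get("night_date", r.get("date")), reason)
        records["treatment"] = (records["condition"] == "treatment").astype(int)
        return records

    nights = nights.copy()
    ta24 = {}
    for nd in nights["night_date"].unique():
        ta24[nd] = ta_window_mean(
            data.weather, at(nd, time(7, 0)),
            at(nd + timedelta(days=1), time(7, 0)), interval, cov,
        )
    nights["ta_24h_mean"] = nights["night_date"].map(ta24)
    nights["wind_daily_max"] = nights["night_date"].map(wind)
    nights["body_mass_g"] = nights["bird_id"].map(mass)
    nights["sex"] = nights["bird_id"].map(sex)
    nights = finish(nights, "ta_24h_mean")

    days = days.copy()
    taday = {}
    for dd in days["date"].unique():
        taday[dd] = ta_window_mean(
            data.weather, at(dd, time(7, 0)), at(dd, time(17, 0)), interval, cov,
        )
    days["ta_active_mean"] = days["date"].map(taday)
    days["wind_daily_max"] = days["date"].map(wind)
    days["body_mass_g"] = days["bird_id"].map(mass)
    days["sex"] = days["bird_id"].map(sex)
    days = finish(days, "ta_active_mean")

    for name, tbl, keys in (("nights", nights, ["bird_id", "night_date"]),
                            ("days", days, ["bird_id", "date"])):
        if tbl.duplicated(keys).any():
            raise ValueError(f"duplicate {name} records after join")
    return nights, days
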
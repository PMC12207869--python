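"""Normothermic baselines, torpor thresholds, and nightly torpor metrics.

Each bird's resting normothermic skin temperature is estimated as the mean
of its lowest daily active-phase readings over (retained) control days;
the individual torpor threshold is 5 degC below that. Nightly torpor depth
is the minimum rest-phase sample, and torpor duration is the total sampled
time strictly below the threshold, contiguous or not. Samples exactly at
the threshold count as normothermic (the comparison is strict), and
missing samples contribute zero duration: gaps are never interpolated, and
nights with large gaps have already been excluded upstream.
"""

from __future__ import annotations

import logging
from datetime import timedelta
from typing import Iterable

import numpy as np
import pandas as pd

from .config import AnalysisOptions
from .ingest import LoadedData

__all__ = [
    "estimate_baseline",
    "baseline_table",
    "night_metrics",
    "fill_night_metrics",
    "torpor_bouts",
    "summarize_by_condition",
]

log = logging.getLogger(__name__)


def estimate_baseline(
    bird_days: pd.DataFrame, bird_id: str, offset: float = 5.0
) -> dict:
    """One baseline-table row from a bird's day records.

    Qualifying days are included control days with a ``lowest_active_ts``
    value (the sample-count rule is applied when the day table is built).
    A bird with no qualifying day is flagged unusable and later dropped
    from the night models.
    """
    sub = bird_days[
        (bird_days["bird_id"] == bird_id)
        & (bird_days["condition"] == "control")
        & bird_days["included"]
        & bird_days["lowest_active_ts"].notna()
    ]
    n = len(sub)
    if n == 0:
        log.warning("%s: no qualifying control day; bird unusable for "
                    "night metrics", bird_id)
        return {"bird_id": bird_id, "normothermic_ts": np.nan,
                "torpor_threshold": np.nan, "n_control_days_used": 0,
                "usable": False}
    base = float(sub["lowest_active_ts"].mean())
    return {"bird_id": bird_id, "normothermic_ts": base,
            "torpor_threshold": base - offset, "n_control_days_used": n,
            "usable": True}


def baseline_table(bird_days: pd.DataFrame,
                   options: AnalysisOptions | None = None) -> pd.DataFrame:
    options = options or AnalysisOptions()
    birds = sorted(bird_days["bird_id"].unique())
    return pd.DataFrame(
        [estimate_baseline(bird_days, b, options.torpor_threshold_offset)
         for b in birds]
    )


def night_metrics(
    samples: Iterable[float], threshold: float, interval_min: int
) -> tuple[float, float]:
    """(minimum Ts, torpor duration in hours) for one night's samples.

    Duration counts non-missing samples strictly below ``threshold``
    times the sampling interval; ties at the threshold are normothermic.
    """
    vals = np.asarray(list(samples), dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("night has no samples; should be excluded upstream")
    below = int(np.sum(vals < threshold))
    return float(vals.min()), below * interval_min / 60.0


def _rest_values(series, night_date, windows) -> np.ndarray:
    idx = series.samples.index
    tod = np.array(idx.time)
    dates = np.array(idx.date)
    mask = ((tod >= windows.rest_start) & (dates == night_date)) | (
        (tod < windows.rest_end) & (dates == night_date + timedelta(days=1))
    )
    return series.samples.to_numpy(float)[mask]


def fill_night_metrics(
    nights: pd.DataFrame, data: LoadedData, baselines: pd.DataFrame,
    options: AnalysisOptions | None = None,
) -> pd.DataFrame:
    """Attach min_rest_ts and torpor_duration_h to included bird-nights.

    Nights of birds without a usable baseline are excluded with reason
    ``no_baseline``.
    """
    options = options or AnalysisOptions()
    nights = nights.copy()
    nights["min_rest_ts"] = np.nan
    nights["torpor_duration_h"] = np.nan
    nights["torpor_threshold"] = np.nan
    thr = baselines.set_index("bird_id")
    interval = data.config.sample_interval_min
    for i, r in nights.iterrows():
        if not r["included"]:
            continue
        row = thr.loc[r["bird_id"]]
        if not row["usable"]:
            nights.loc[i, ["included", "exclusion_reason"]] = [False, "no_baseline"]
            continue
        vals = _rest_values(data.series[r["bird_id"]], r["night_date"],
                            options.windows)
        mn, dur = night_metrics(vals, row["torpor_threshold"], interval)
        nights.loc[i, ["min_rest_ts", "torpor_duration_h", "torpor_threshold"]] = [
            mn, dur, row["torpor_threshold"]]
    return nights


def torpor_bouts(
    samples: pd.Series, threshold: float
) -> pd.DataFrame:
    """Contiguous runs of samples below the threshold (onset, offset, length).

    Provided for inspection; the modeled quantity is total time below the
    threshold, not bout structure.
    """
    vals = samples.to_numpy(float)
    below = (vals < threshold) & ~np.isnan(vals)
    edges = np.diff(np.concatenate([[0], below.astype(int), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return pd.DataFrame(
        {
            "onset": samples.index[starts],
            "offset": samples.index[ends - 1],
            "n_samples": ends - starts,
        }
    )


def summarize_by_condition(
    nights: pd.DataFrame,
    columns: tuple[str, ...] = ("min_rest_ts", "torpor_duration_h"),
) -> pd.DataFrame:
    """Condition-level descriptives (mean, SD, min-max, n) of night metrics."""
    inc = nights[nights["included"]]
    rows = []
    for condition in ("control", "treatment"):
        sub = inc[inc["condition"] == condition]
        if sub.empty:
            log.warning("no included nights for condition %r", condition)
        row = {"condition": condition, "n_nights": len(sub)}
        for c in columns:
            vals = sub[c].dropna()
            row[f"{c}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{c}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            row[f"{c}_min"] = vals.min() if len(vals) else np.nan
            row[f"{c}_max"] = vals.max() if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
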
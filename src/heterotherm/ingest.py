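"""Reading logger bundles and circadian segmentation.

Turns raw receiver-logger files (timestamp, transmitter, pulse interval)
into per-bird skin-temperature series on a regular sampling grid, then
cuts each series into bird-nights (rest-phase 17:00-08:00, attributed the
condition of the preceding daytime) and bird-days, applying the study's
exclusion rules: nights missing more than 3 h of data, and the first two
days of any control block that follows a treatment block (carry-over).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as date_t, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from .config import AnalysisOptions, PhaseWindows, ScenarioConfig

__all__ = [
    "TsSeries",
    "LoadedData",
    "load_dataset",
    "from_dataset",
    "assign_nights",
    "apply_carryover_exclusion",
    "carryover_dates",
    "daily_summaries",
]

log = logging.getLogger(__name__)

TS_SANITY_LOW = 10.0
TS_SANITY_HIGH = 50.0


@dataclass
class TsSeries:
    """One bird's skin-temperature record on the regular sampling grid."""

    bird_id: str
    site: str
    samples: pd.Series  # DatetimeIndex -> ts_c, NaN where missing

    def __post_init__(self) -> None:
        idx = self.samples.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError(f"{self.bird_id}: grid index must be strictly increasing")
        vals = self.samples.to_numpy(float)
        bad = (vals < TS_SANITY_LOW) | (vals > TS_SANITY_HIGH)
        if np.any(bad & ~np.isnan(vals)):
            raise ValueError(f"{self.bird_id}: temperatures outside sanity bounds")


@dataclass
class LoadedData:
    """A validated in-memory study ready for segmentation."""

    config: ScenarioConfig
    series: dict[str, TsSeries]
    metadata: pd.DataFrame
    schedule: pd.DataFrame
    weather: pd.DataFrame
    wind: pd.DataFrame
    curves: dict[str, cal.CalibrationCurve] = field(default_factory=dict)
    n_unknown_rows: int = 0


def _grid(config: ScenarioConfig) -> pd.DatetimeIndex:
    start = datetime.combine(config.start_date, time(7, 0))
    end = datetime.combine(config.start_date + timedelta(days=config.n_days),
                           time(0, 0))
    return pd.date_range(start, end, freq=f"{config.sample_interval_min}min",
                         inclusive="left")


def _read_timestamps(raw: pd.Series, path: Path) -> pd.Series:
    out = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    if out.isna().any():
        line = int(out.index[out.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: unparseable timestamp at line {line}: "
                         f"{raw[out.isna()].iloc[0]!r}")
    return out


def load_dataset(datadir: str | Path,
                 config: ScenarioConfig | None = None) -> LoadedData:
    """Load a file bundle: fit calibrations, convert pulses, grid-align.

    Every transmitter appearing in a logger file must have a calibration
    table and a metadata row (hard error otherwise is reserved for known
    birds; entirely unknown transmitter ids are dropped with a warning).
    Duplicate (bird, timestamp) rows collapse to their median.
    """
    d = Path(datadir)
    if config is None:
        scen = d / "scenario.yaml"
        if not scen.exists():
            raise FileNotFoundError(f"{scen}: no scenario.yaml and no config given")
        config = ScenarioConfig.from_yaml(scen)
    for name in ("calibration.csv", "metadata.csv", "schedule.csv",
                 "weather.csv", "wind.csv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"required input file missing: {d / name}")

    metadata = pd.read_csv(d / "metadata.csv")
    cal_table = pd.read_csv(d / "calibration.csv")
    curves = cal.load_calibration_table(cal_table)
    missing_cal = set(metadata["transmitter_id"]) - set(curves)
    if missing_cal:
        raise ValueError(f"no calibration table for transmitter(s): "
                         f"{sorted(missing_cal)}")

    schedule = pd.read_csv(d / "schedule.csv", parse_dates=["date"])
    schedule["date"] = schedule["date"].dt.date
    weather = pd.read_csv(d / "weather.csv")
    weather["timestamp"] = _read_timestamps(weather["timestamp"],
                                            d / "weather.csv")
    wind = pd.read_csv(d / "wind.csv", parse_dates=["date"])
    wind["date"] = wind["date"].dt.date

    bird_of = dict(zip(metadata["transmitter_id"], metadata["bird_id"]))
    site_of = dict(zip(metadata["bird_id"], metadata["site"]))
    grid = _grid(config)
    frames, n_unknown = [], 0
    for path in sorted(d.glob("logger_*.csv")):
        logger = pd.read_csv(path)
        logger["timestamp"] = _read_timestamps(logger["timestamp"], path)
        known = logger["transmitter_id"].isin(bird_of)
        n_unknown += int((~known).sum())
        if (~known).any():
            log.warning("%s: dropped %d row(s) with unknown transmitter",
                        path.name, int((~known).sum()))
        logger = logger[known].copy()
        temps = np.empty(len(logger))
        for tx, idx in logger.groupby("transmitter_id").groups.items():
            temps[logger.index.get_indexer(idx)] = cal.pulse_to_temperature(
                curves[tx], logger.loc[idx, "pulse_interval_ms"].to_numpy()
            )
        logger["ts_c"] = temps
        logger["bird_id"] = logger["transmitter_id"].map(bird_of)
        frames.append(logger[["bird_id", "timestamp", "ts_c"]])
    rows = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["bird_id", "timestamp", "ts_c"]))
    # duplicate (bird, timestamp) rows -> median
    rows = rows.groupby(["bird_id", "timestamp"], as_index=False)["ts_c"].median()

    series = {}
    for bird_id in metadata["bird_id"]:
        sub = rows[rows["bird_id"] == bird_id]
        samples = sub.set_index("timestamp")["ts_c"].reindex(grid)
        series[bird_id] = TsSeries(bird_id, site_of[bird_id], samples)
    return LoadedData(config=config, series=series, metadata=metadata,
                      schedule=schedule, weather=weather, wind=wind,
                      curves=curves, n_unknown_rows=n_unknown)


def from_dataset(ds) -> LoadedData:
    """Build a :class:`LoadedData` directly from an in-memory simulation."""
    grid = _grid(ds.config)
    series = {}
    for bird_id, sub in ds.ts.groupby("bird_id"):
        samples = sub.set_index("timestamp")["ts_c"].reindex(grid)
        series[bird_id] = TsSeries(bird_id, sub["site"].iloc[0], samples)
    return LoadedData(config=ds.config, series=series, metadata=ds.metadata,
                      schedule=ds.schedule, weather=ds.weather, wind=ds.wind)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _night_slots(windows: PhaseWindows, interval_min: int) -> int:
    return int(round(windows.rest_hours() * 60 / interval_min))


def assign_nights(
    data: LoadedData, options: AnalysisOptions | None = None
) -> pd.DataFrame:
    """One row per bird-night with at least one rest-phase sample.

    ``night_date`` is the evening date on which the rest window opens; the
    night inherits the treatment condition of that date (the preceding
    daytime). ``missing_h`` counts empty grid slots against the full rest
    window, and nights missing more than ``max_missing_h`` are excluded
    with reason ``gap_gt_3h``.
    """
    options = options or AnalysisOptions()
    w = options.windows
    interval = next(iter(data.series.values())).samples.index.freq
    interval_min = int(interval.nanos / 60e9) if interval is not None else \
        data.config.sample_interval_min
    full_slots = _night_slots(w, interval_min)
    cond = {(r.site, r.date): r.condition for r in data.schedule.itertuples()}

    rows = []
    for bird_id, s in sorted(data.series.items()):
        idx = s.samples.index
        tod = idx.time
        in_rest = (tod >= w.rest_start) | (np.array(tod) < w.rest_end)
        night_date = np.where(
            tod >= w.rest_start,
            idx.date,
            np.array(idx.date) - timedelta(days=1),
        )
        present = s.samples.notna().to_numpy()
        sub = pd.DataFrame({"night_date": night_date[in_rest],
                            "present": present[in_rest]})
        for nd, grp in sub.groupby("night_date"):
            n = int(grp["present"].sum())
            if n == 0:
                continue
            key = (s.site, nd)
            if key not in cond:
                first = data.schedule[data.schedule["site"] == s.site]["date"].min()
                if nd < first:  # window opened before the study started
                    continue
                raise KeyError(f"schedule does not cover {s.site} {nd}")
            missing_h = (full_slots - n) * interval_min / 60.0
            included = missing_h <= options.max_missing_h
            rows.append(
                {
                    "bird_id": bird_id,
                    "site": s.site,
                    "night_date": nd,
                    "condition": cond[key],
                    "n_samples": n,
                    "missing_h": missing_h,
                    "included": included,
                    "exclusion_reason": "none" if included else "gap_gt_3h",
                }
            )
    return pd.DataFrame(rows)


def carryover_dates(schedule: pd.DataFrame, carryover_days: int = 2
                    ) -> dict[str, set]:
    """Per site: dates in the first ``carryover_days`` of any control block
    immediately preceded by a treatment block."""
    out: dict[str, set] = {}
    for site, grp in schedule.groupby("site"):
        grp = grp.sort_values("date")
        excluded: set = set()
        prev_cond = None
        block: list = []
        blocks: list = []
        for r in grp.itertuples():
            if r.condition != prev_cond:
                if block:
                    blocks.append((prev_cond, block))
                block, prev_cond = [], r.condition
            block.append(r.date)
        if block:
            blocks.append((prev_cond, block))
        for i, (c, dates) in enumerate(blocks):
            if c == "control" and i > 0 and blocks[i - 1][0] == "treatment":
                excluded.update(dates[:carryover_days])
        out[site] = excluded
    return out


def apply_carryover_exclusion(
    records: pd.DataFrame, schedule: pd.DataFrame, carryover_days: int = 2,
    date_col: str | None = None,
) -> pd.DataFrame:
    """Flag records falling on carry-over dates (first days of a control
    block that follows treatment). A leading control block is untouched.
    Already-excluded records keep their original reason."""
    if records.empty:
        return records
    if date_col is None:
        date_col = "night_date" if "night_date" in records.columns else "date"
    excl = carryover_dates(schedule, carryover_days)
    records = records.copy()
    hit = records.apply(
        lambda r: r[date_col] in excl.get(r["site"], ()), axis=1
    )
    mark = hit & records["included"]
    records.loc[mark, "included"] = False
    records.loc[mark, "exclusion_reason"] = "carryover_day"
    return records


def daily_summaries(
    data: LoadedData, options: AnalysisOptions | None = None
) -> pd.DataFrame:
    """Per bird-day medians and active-phase minima.

    The daily median uses the 08:00-17:00 window and requires strictly
    more than 20 samples; the lowest active-phase reading uses the stated
    07:00-17:00 active window with the same sample-count rule.
    """
    options = options or AnalysisOptions()
    w = options.windows
    cond = {(r.site, r.date): r.condition for r in data.schedule.itertuples()}
    rows = []
    for bird_id, s in sorted(data.series.items()):
        idx = s.samples.index
        tod = np.array(idx.time)
        dates = np.array(idx.date)
        vals = s.samples.to_numpy(float)
        in_med = (tod >= w.median_start) & (tod < w.median_end)
        in_act = (tod >= w.active_start) & (tod < w.active_end)
        for day in np.unique(dates):
            if (s.site, day) not in cond:
                continue
            m_med = in_med & (dates == day) & ~np.isnan(vals)
            m_act = in_act & (dates == day) & ~np.isnan(vals)
            n_med, n_act = int(m_med.sum()), int(m_act.sum())
            rows.append(
                {
                    "bird_id": bird_id,
                    "site": s.site,
                    "date": day,
                    "condition": cond[(s.site, day)],
                    "n_median_samples": n_med,
                    "median_active_ts": (float(np.median(vals[m_med]))
                                         if n_med >= options.min_median_samples
                                         else np.nan),
                    "n_active_samples": n_act,
                    "lowest_active_ts": (float(np.min(vals[m_act]))
                                         if n_act >= options.min_active_samples
                                         else np.nan),
                    "included": True,
                    "exclusion_reason": "none",
                }
            )
    return pd.DataFrame(rows)
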
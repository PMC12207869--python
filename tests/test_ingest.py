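from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest

import heterotherm as ht
from heterotherm.config import AnalysisOptions
from heterotherm.ingest import (
    apply_carryover_exclusion,
    assign_nights,
    carryover_dates,
    daily_summaries,
    from_dataset,
    load_dataset,
)


@pytest.fixture(scope="module")
def bundle(tmp_path_factory, dataset):
    out = tmp_path_factory.mktemp("bundle")
    ht.emit_dataset(dataset, out)
    return out


def test_load_gives_grid_complete_series(bundle, paper_cfg):
    data = load_dataset(bundle)
    assert len(data.series) == 16
    n_expected = (paper_cfg.n_days * 24 - 7) * 6  # 07:00 day 0 .. 00:00 day 15
    for s in data.series.values():
        assert len(s.samples) == n_expected
        assert s.samples.index.is_monotonic_increasing


def test_unknown_transmitter_dropped_with_count(bundle, tmp_path):
    import shutil
    d = tmp_path / "tampered"
    shutil.copytree(bundle, d)
    path = d / "logger_site_a.csv"
    with path.open("a") as fh:
        fh.write("2023-06-17T12:00:00,TX99,1200.00\n")
    data = load_dataset(d)
    assert data.n_unknown_rows == 1


def test_duplicate_rows_collapse_to_median(bundle, tmp_path):
    import shutil
    d = tmp_path / "dup"
    shutil.copytree(bundle, d)
    data0 = load_dataset(d)
    t = "2023-06-17T12:00:00"
    tt = pd.Timestamp(t)
    # two extra rows for TX01 at one timestamp: with the original sample the
    # median of three values is taken; use values bracketing a known middle
    tx = "TX01"
    curve = data0.curves[tx]
    bird = data0.metadata.set_index("transmitter_id").loc[tx, "bird_id"]
    p_lo = float(np.interp(31.0, *_curve_table(curve)))
    p_hi = float(np.interp(31.4, *_curve_table(curve)))
    with (d / "logger_site_a.csv").open("a") as fh:
        fh.write(f"{t},{tx},{p_lo:.2f}\n{t},{tx},{p_hi:.2f}\n")
    data = load_dataset(d)
    vals = [31.0, 31.4]
    orig = data0.series[bird].samples.loc[tt]
    if not np.isnan(orig):
        vals.append(float(orig))
    assert data.series[bird].samples.loc[tt] == pytest.approx(
        float(np.median(vals)), abs=0.02)


def _curve_table(curve):
    grid = np.linspace(*curve.pulse_range, 2048)
    temps = curve(grid)
    return temps[::-1], grid[::-1]


def test_missing_required_file_is_named(bundle, tmp_path):
    import shutil
    d = tmp_path / "broken"
    shutil.copytree(bundle, d)
    (d / "weather.csv").unlink()
    with pytest.raises(FileNotFoundError, match="weather.csv"):
        load_dataset(d)


def test_unparseable_timestamp_reports_line(bundle, tmp_path):
    import shutil
    d = tmp_path / "badts"
    shutil.copytree(bundle, d)
    with (d / "logger_site_b.csv").open("a") as fh:
        fh.write("not-a-time,TX09,1200.00\n")
    with pytest.raises(ValueError, match="line"):
        load_dataset(d)


# ---------------------------------------------------------------------------
# night assignment
# ---------------------------------------------------------------------------

def test_night_windows_and_gap_rule(loaded, paper_cfg):
    nights = assign_nights(loaded)
    one = nights[(nights["bird_id"] == "B01")
                 & (nights["night_date"] == paper_cfg.start_date)]
    assert len(one) == 1
    # full rest window is 90 slots of 10 min = 15 h
    assert one["missing_h"].iloc[0] == pytest.approx(
        (90 - one["n_samples"].iloc[0]) / 6)
    # the final evening's window is cut at the end of the study: > 3 h missing
    last = nights[nights["night_date"]
                  == paper_cfg.start_date + timedelta(days=14)]
    assert (~last["included"]).all()
    assert (last["exclusion_reason"] == "gap_gt_3h").all()


def test_19_missing_slots_cross_the_3h_rule(clean_dataset):
    # delete 19 samples (3.17 h) from one bird's first rest window
    ds = clean_dataset
    data = from_dataset(ds)
    s = data.series["B01"].samples.copy()
    start = datetime.combine(ds.config.start_date, time(17, 0))
    s.loc[start:start + timedelta(minutes=10 * 18)] = np.nan
    data.series["B01"] = ht.TsSeries("B01", "site_a", s)
    nights = assign_nights(data)
    row = nights[(nights["bird_id"] == "B01")
                 & (nights["night_date"] == ds.config.start_date)].iloc[0]
    assert row["missing_h"] > 3
    assert not row["included"] and row["exclusion_reason"] == "gap_gt_3h"


def test_night_condition_follows_preceding_daytime(loaded, paper_cfg):
    nights = assign_nights(loaded)
    sch = {(r.site, r.date): r.condition
           for r in loaded.schedule.itertuples()}
    for r in nights.itertuples():
        assert r.condition == sch[(r.site, r.night_date)]


def test_exclusion_monotone_under_added_missingness(clean_dataset):
    """Deleting samples can only remove retained nights, never add them."""
    data = from_dataset(clean_dataset)
    before = assign_nights(data)
    kept_before = set(map(tuple, before.loc[before["included"],
                                            ["bird_id", "night_date"]].values))
    rng = np.random.default_rng(3)
    for bird_id, s in data.series.items():
        drop = rng.random(len(s.samples)) < 0.15
        vals = s.samples.copy()
        vals[drop] = np.nan
        data.series[bird_id] = ht.TsSeries(bird_id, s.site, vals)
    after = assign_nights(data)
    kept_after = set(map(tuple, after.loc[after["included"],
                                          ["bird_id", "night_date"]].values))
    assert kept_after <= kept_before


# ---------------------------------------------------------------------------
# carry-over exclusion
# ---------------------------------------------------------------------------

def test_carryover_dates_from_block_structure(paper_cfg):
    sch = ht.make_schedule(paper_cfg)
    excl = carryover_dates(sch, 2)
    d0 = paper_cfg.start_date
    # site_a: T(0-4) C(5-9) T(10-14): first two control dates excluded
    assert excl["site_a"] == {d0 + timedelta(days=5), d0 + timedelta(days=6)}
    # site_b: leading control block untouched; C(10-14) follows treatment
    assert excl["site_b"] == {d0 + timedelta(days=10), d0 + timedelta(days=11)}


def test_leading_control_block_untouched():
    cfg = ht.paper_winter().replace(n_days=10, block_length_days=5)
    sch = ht.make_schedule(cfg)
    excl = carryover_dates(sch, 2)
    # site_b runs C then T: no control block follows a treatment block
    assert excl["site_b"] == set()


def test_retained_night_count_matches_enumeration(clean_result, clean_cfg):
    """Gap-free data: retained nights equal a brute-force schedule count."""
    sch = ht.make_schedule(clean_cfg)
    cond = {(r.site, r.date): r.condition for r in sch.itertuples()}
    excl = carryover_dates(sch, 2)
    expected = 0
    for site in ("site_a", "site_b"):
        for d in range(clean_cfg.n_days):
            day = clean_cfg.start_date + timedelta(days=d)
            complete = d < clean_cfg.n_days - 1  # last window is cut short
            if complete and day not in excl[site]:
                expected += clean_cfg.birds_per_site
    nights = clean_result.nights
    assert int(nights["included"].sum()) == expected == 192


# ---------------------------------------------------------------------------
# daily summaries
# ---------------------------------------------------------------------------

def test_median_rule_strictly_greater_than_20(clean_dataset):
    data = from_dataset(clean_dataset)
    bird = "B01"
    s = data.series[bird].samples.copy()
    day = clean_dataset.config.start_date
    sel = (s.index.date == day) & (s.index.time >= time(8, 0)) \
        & (s.index.time < time(17, 0))
    keep = np.flatnonzero(sel)[:20]  # exactly 20 samples survive
    drop = np.setdiff1d(np.flatnonzero(sel), keep)
    s.iloc[drop] = np.nan
    data.series[bird] = ht.TsSeries(bird, "site_a", s)
    days = daily_summaries(data)
    row = days[(days["bird_id"] == bird) & (days["date"] == day)].iloc[0]
    assert row["n_median_samples"] == 20
    assert np.isnan(row["median_active_ts"])


def test_noiseless_day_low_equals_planted_resting_level(clean_dataset):
    days = daily_summaries(from_dataset(clean_dataset))
    truth = clean_dataset.true_birds.set_index("bird_id")["resting_ts"]
    sub = days[days["lowest_active_ts"].notna()]
    for r in sub.itertuples():
        assert r.lowest_active_ts == pytest.approx(truth[r.bird_id], abs=1e-9)
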
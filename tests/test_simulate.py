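import filecmp
from datetime import date, time, timedelta

import numpy as np
import pandas as pd
import pytest

import heterotherm as ht
from heterotherm.simulate import emit_dataset, make_schedule, simulate_bird_trace, simulate_dataset, simulate_weather


# ---------------------------------------------------------------------------
# treatment schedule
# ---------------------------------------------------------------------------

def _pattern(schedule, site):
    sub = schedule[schedule["site"] == site].sort_values("date")
    return "".join("T" if c == "treatment" else "C" for c in sub["condition"])


def test_schedule_opposing_five_day_blocks(paper_cfg):
    sch = make_schedule(paper_cfg)
    assert _pattern(sch, "site_a") == "TTTTTCCCCCTTTTT"
    assert _pattern(sch, "site_b") == "CCCCCTTTTTCCCCC"


def test_schedule_single_block():
    cfg = ht.paper_winter().replace(n_days=5, block_length_days=5)
    sch = make_schedule(cfg)
    assert _pattern(sch, "site_a") == "TTTTT"
    assert _pattern(sch, "site_b") == "CCCCC"


def test_schedule_indivisible_rejected():
    with pytest.raises(ValueError, match="multiple"):
        ht.paper_winter().replace(n_days=14)


@pytest.mark.parametrize("n_days,block", [(10, 5), (15, 5), (12, 3), (20, 4)])
def test_schedule_date_complementarity_and_pooled_balance(n_days, block):
    cfg = ht.paper_winter().replace(n_days=n_days, block_length_days=block)
    sch = make_schedule(cfg)
    by_date = sch.pivot(index="date", columns="site", values="condition")
    # every date: one site treated, the other a control
    assert (by_date["site_a"] != by_date["site_b"]).all()
    counts = sch.groupby("condition").size()
    assert counts["control"] == counts["treatment"] == n_days


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def test_weather_daily_minima_match_regime():
    """Monte-Carlo: realized daily minima track the configured regime."""
    mins = []
    for seed in range(12):
        cfg = ht.paper_winter(seed)
        weather, _ = simulate_weather(cfg)
        daily = weather.set_index("timestamp")["ta_c"].resample("D").min()
        mins.append(daily.mean())
    assert np.mean(mins) == pytest.approx(2.5, abs=1.5)


def test_weather_degenerate_constant():
    cfg = ht.paper_winter(0).replace(
        ta_daily_min_mean=10.0, ta_daily_min_sd=0.0,
        ta_daily_max_mean=10.0, ta_daily_max_sd=0.0, ta_noise_sd=0.0,
    )
    weather, _ = simulate_weather(cfg)
    # maxima are kept >= min + 2, so the diel arc spans [10, 12]
    assert weather["ta_c"].between(10.0, 12.0).all()


def test_wind_floor_clamped():
    cfg = ht.paper_winter(0).replace(wind_daily_max_mean=0.0,
                                     wind_daily_max_sd=1.0)
    _, wind = simulate_weather(cfg)
    assert (wind["wind_max_kmh"] >= cfg.wind_floor).all()
    assert len(wind) == cfg.n_days


# ---------------------------------------------------------------------------
# trace construction identities (noiseless)
# ---------------------------------------------------------------------------

def _flat_weather(cfg, ta=9.85):
    grid = pd.date_range(
        pd.Timestamp.combine(cfg.start_date, time(7, 0)),
        periods=200, freq="10min",
    )
    return pd.DataFrame({"timestamp": grid, "ta_c": ta})


def test_trace_minimum_and_duration_match_planted_values(paper_cfg):
    cfg = paper_cfg.replace(measurement_noise_sd=0.0, median_ts_day_sd=0.0)
    bird = {"bird_id": "B00", "site": "site_a", "resting_ts": 37.3,
            "plateau_ts": 39.6, "min_ts_bird_effect": 0.0,
            "duration_bird_effect": 0.0}
    rng = np.random.default_rng(5)
    frame, truth = simulate_bird_trace(
        bird, cfg.start_date, "treatment", _flat_weather(cfg), cfg, rng
    )
    vals = frame["ts_true"].to_numpy()
    tod = frame["timestamp"].dt.time
    night = (tod >= time(17, 0)) | (tod < time(7, 0))
    threshold = 37.3 - 5.0
    assert vals[night].min() == pytest.approx(truth["planted_min_ts"], abs=1e-9)
    sampled_h = (vals[night] < threshold).sum() * 10 / 60
    assert sampled_h == pytest.approx(truth["planted_duration_h"], abs=10 / 60)


def test_active_phase_minimum_equals_resting_level(paper_cfg):
    cfg = paper_cfg.replace(measurement_noise_sd=0.0, median_ts_day_sd=0.0)
    bird = {"bird_id": "B00", "site": "site_a", "resting_ts": 37.3,
            "plateau_ts": 39.6, "min_ts_bird_effect": 0.0,
            "duration_bird_effect": 0.0}
    frame, _ = simulate_bird_trace(
        bird, cfg.start_date, "control", _flat_weather(cfg), cfg,
        np.random.default_rng(5),
    )
    tod = frame["timestamp"].dt.time
    active = (tod >= time(7, 0)) & (tod < time(17, 0))
    assert frame["ts_true"][active].min() == pytest.approx(37.3, abs=1e-9)


def test_planted_control_minima_center_on_configured_mean():
    """Monte-Carlo over replicate studies: planted control-night minima."""
    means = []
    for seed in range(20):
        ds = simulate_dataset(ht.paper_winter(seed))
        te = ds.true_effects
        means.append(te.loc[te["condition"] == "control", "planted_min_ts"].mean())
    assert np.mean(means) == pytest.approx(30.0, abs=0.2)


def test_true_effects_invariants(dataset):
    te = dataset.true_effects
    tb = dataset.true_birds.set_index("bird_id")
    assert len(te) == dataset.config.n_birds * dataset.config.n_days
    assert (te["planted_duration_h"] >= 0).all()
    resting = te["bird_id"].map(tb["resting_ts"])
    assert (te["planted_min_ts"] <= resting + 1e-9).all()


def test_guard_band(dataset):
    vals = dataset.ts["ts_c"].dropna()
    assert vals.between(15.0, 45.0).all()


# ---------------------------------------------------------------------------
# determinism and the file bundle
# ---------------------------------------------------------------------------

def test_same_seed_same_dataset(paper_cfg):
    a = simulate_dataset(paper_cfg)
    b = simulate_dataset(paper_cfg)
    pd.testing.assert_frame_equal(a.ts, b.ts)
    pd.testing.assert_frame_equal(a.true_effects, b.true_effects)


def test_bundle_byte_identical(tmp_path, dataset):
    emit_dataset(dataset, tmp_path / "one")
    emit_dataset(dataset, tmp_path / "two")
    names = [p.name for p in sorted((tmp_path / "one").iterdir())]
    match, mismatch, errors = filecmp.cmpfiles(
        tmp_path / "one", tmp_path / "two", names, shallow=False)
    assert not mismatch and not errors
    assert len(match) == len(names)


def test_bundle_round_trip_reproduces_temperatures(tmp_path, dataset):
    out = emit_dataset(dataset, tmp_path / "bundle")
    loaded = ht.load_dataset(out)
    assert len(loaded.series) == dataset.config.n_birds
    for bird_id, s in loaded.series.items():
        orig = dataset.ts[dataset.ts["bird_id"] == bird_id]
        orig = orig.set_index("timestamp")["ts_c"].reindex(s.samples.index)
        assert s.samples.isna().equals(orig.isna())
        diff = (s.samples - orig).abs().dropna()
        assert diff.max() < 0.01


def test_minimal_one_day_bundle(tmp_path):
    cfg = ht.paper_winter(2).replace(n_days=1, block_length_days=1)
    ds = simulate_dataset(cfg)
    out = emit_dataset(ds, tmp_path / "mini")
    loaded = ht.load_dataset(out)
    assert len(loaded.series) == cfg.n_birds
    assert not loaded.schedule.empty and not loaded.weather.empty
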
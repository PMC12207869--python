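"""Study-scenario and analysis configuration.

A :class:`ScenarioConfig` fully describes a simulated field experiment:
the crossover design (alternating treatment/control blocks run in opposing
sequence at two sites), the winter weather regime, the thermal biology of
the birds (normothermic levels, torpor depth/duration distributions and
their responses to the predation-risk treatment and to air temperature),
and the measurement process (sampling interval, noise, missingness).

:class:`PhaseWindows` holds the circadian segmentation used throughout the
analysis: the nocturnal rest-phase (17:00 to 08:00 next day), the diurnal
active-phase (07:00 to 17:00), and the narrower window (08:00 to 17:00)
over which daily median skin temperature is computed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, time
from pathlib import Path

import yaml

__all__ = [
    "ScenarioConfig",
    "PhaseWindows",
    "AnalysisOptions",
    "paper_winter",
    "get_scenario",
]


@dataclass(frozen=True)
class PhaseWindows:
    """Clock-time windows defining rest-phase, active-phase and the median window.

    The rest window spans midnight (evening ``rest_start`` to next-morning
    ``rest_end``). Active and rest phases deliberately overlap between
    07:00 and 08:00: the morning hour contributes both to the nightly
    minimum and to the lowest daily active-phase reading. All windows are
    half-open ``[start, end)``.
    """

    rest_start: time = time(17, 0)
    rest_end: time = time(8, 0)  # next day
    active_start: time = time(7, 0)
    active_end: time = time(17, 0)
    median_start: time = time(8, 0)
    median_end: time = time(17, 0)

    def rest_hours(self) -> float:
        start = self.rest_start.hour + self.rest_start.minute / 60
        end = self.rest_end.hour + self.rest_end.minute / 60
        return (24 - start) + end


@dataclass
class ScenarioConfig:
    """Parameters of a simulated predation-risk playback experiment.

    Temperature fields are in degrees Celsius, durations in hours, wind in
    km/h. ``treatment_effect_*`` fields are shifts applied on nights that
    follow a playback (treatment) day, relative to control. Air-temperature
    slopes act on the deviation of the relevant window mean from the fixed
    scenario references ``ta_reference_night`` / ``ta_reference_daytime``.
    """

    n_sites: int = 2
    birds_per_site: int = 8
    n_females: int = 6
    n_males: int = 10
    start_date: date = date(2023, 6, 16)
    n_days: int = 15
    block_length_days: int = 5
    sample_interval_min: int = 10

    # daytime thermoregulation
    active_plateau_mean: float = 39.6
    active_plateau_sd_between_birds: float = 1.0
    ta_slope_daytime: float = 0.17
    treatment_effect_daytime: float = -0.2
    resting_normothermic_mean: float = 37.3
    resting_normothermic_sd_between_birds: float = 1.2
    plateau_resting_correlation: float = 0.9
    median_ts_day_sd: float = 0.4

    # nightly torpor depth (minimum rest-phase Ts)
    control_min_ts_mean: float = 30.0
    control_min_ts_sd: float = 1.5
    min_ts_bird_sd: float = 0.8
    treatment_effect_min_ts: float = -1.25
    ta_slope_min_ts: float = 0.15

    # nightly torpor duration (time below individual threshold)
    control_torpor_duration_mean: float = 3.8
    control_torpor_duration_sd: float = 2.3
    duration_bird_sd: float = 1.0
    treatment_effect_duration: float = 2.1
    ta_slope_duration: float = -0.15
    max_duration_h: float = 12.0

    # measurement process
    measurement_noise_sd: float = 0.3
    daytime_missing_prob: float = 0.25
    nighttime_missing_prob: float = 0.02
    pulse_jitter_ms: float = 0.05

    # weather
    ta_daily_min_mean: float = 2.5
    ta_daily_min_sd: float = 3.1
    ta_daily_max_mean: float = 17.2
    ta_daily_max_sd: float = 2.4
    ta_noise_sd: float = 0.3
    ta_noise_ar: float = 0.7
    wind_daily_max_mean: float = 32.2
    wind_daily_max_sd: float = 15.5
    wind_floor: float = 11.0

    # fixed references for the air-temperature slope terms: analytic means
    # of the weather model over a 24-h day and over the 07:00-17:00 window
    ta_reference_night: float = 9.85
    ta_reference_daytime: float = 12.6

    body_mass_mean_g: float = 9.0
    body_mass_sd_g: float = 0.5

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_days <= 0 or self.block_length_days <= 0:
            raise ValueError("n_days and block_length_days must be positive")
        if self.n_days % self.block_length_days != 0:
            raise ValueError(
                f"n_days={self.n_days} is not a multiple of "
                f"block_length_days={self.block_length_days}"
            )
        if self.sample_interval_min <= 0:
            raise ValueError("sample_interval_min must be positive")
        for name in ("daytime_missing_prob", "nighttime_missing_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for f_ in dataclasses.fields(self):
            if f_.name.endswith("_sd") or "_sd_" in f_.name:
                v = getattr(self, f_.name)
                if v < 0:
                    raise ValueError(f"{f_.name}={v} must be >= 0")
        if self.n_females + self.n_males != self.n_sites * self.birds_per_site:
            raise ValueError("n_females + n_males must equal total birds")
        if not -1.0 <= self.plateau_resting_correlation <= 1.0:
            raise ValueError("plateau_resting_correlation outside [-1, 1]")

    @property
    def n_birds(self) -> int:
        return self.n_sites * self.birds_per_site

    @property
    def n_blocks(self) -> int:
        return self.n_days // self.block_length_days

    # residual (within-bird, night-to-night) SDs so that the total SDs
    # equal the configured control_*_sd values
    @property
    def min_ts_resid_sd(self) -> float:
        v = self.control_min_ts_sd**2 - self.min_ts_bird_sd**2
        if v < 0:
            raise ValueError("min_ts_bird_sd exceeds control_min_ts_sd")
        return float(v**0.5)

    @property
    def duration_resid_sd(self) -> float:
        v = self.control_torpor_duration_sd**2 - self.duration_bird_sd**2
        if v < 0:
            raise ValueError("duration_bird_sd exceeds control_torpor_duration_sd")
        return float(v**0.5)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if isinstance(d.get("start_date"), str):
            d["start_date"] = date.fromisoformat(d["start_date"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class AnalysisOptions:
    """Tunable rules of the downstream analysis (exclusions, threshold, models)."""

    windows: PhaseWindows = field(default_factory=PhaseWindows)
    torpor_threshold_offset: float = 5.0  # deg C below normothermic baseline
    max_missing_h: float = 3.0  # nights with more missing data are excluded
    carryover_days: int = 2  # leading days of post-treatment control blocks
    min_median_samples: int = 21  # strictly more than 20 points required
    min_active_samples: int = 21  # same rule for the daily active-phase low
    weather_coverage: float = 0.9  # fraction of window slots required
    alpha_drop: float = 0.05
    n_boot: int = 1000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = {k: v.isoformat() for k, v in d["windows"].items()}
        return d


def paper_winter(seed: int = 0) -> ScenarioConfig:
    """The default winter scenario: 2 sites x 8 birds, 15 days of
    alternating 5-day control/playback blocks in opposing sequence."""
    return ScenarioConfig(rng_seed=seed)


_SCENARIOS = {"paper-winter": paper_winter}


def get_scenario(name: str, seed: int = 0) -> ScenarioConfig:
    try:
        return _SCENARIOS[name](seed)
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(_SCENARIOS)}"
        ) from None
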
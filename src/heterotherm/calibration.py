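"""Transmitter calibration: cubic pulse-interval -> temperature curves.

Temperature-sensitive transmitters encode temperature in the interval
between radio pulses (ms); the interval shortens as the transmitter warms.
Each transmitter is calibrated against known temperatures and converted
with a third-order polynomial fitted to those points. Because cubic
extrapolation is unbounded (a single out-of-range pulse could fabricate a
torpor bout), pulses outside the calibrated range (plus a small margin)
are treated as missing rather than extrapolated, and fits that are not
strictly monotone over the calibrated range are rejected outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

__all__ = [
    "CalibrationCurve",
    "CalibrationError",
    "fit_calibration",
    "pulse_to_temperature",
    "load_calibration_table",
    "curves_to_frame",
]

log = logging.getLogger(__name__)

MIN_POINTS = 5
R2_WARN = 0.99
DEFAULT_MARGIN = 0.05  # fraction of the pulse range allowed beyond each end


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    """A fitted cubic mapping pulse interval (ms) to temperature (deg C)."""

    transmitter_id: str
    coefficients: np.ndarray  # ascending powers, standard basis
    pulse_range: tuple[float, float]
    r_squared: float
    n_points: int
    low_r2: bool = False
    _poly: Polynomial = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (4,):
            raise CalibrationError("a cubic needs exactly 4 coefficients")
        if self._poly is None:
            self._poly = Polynomial(self.coefficients)

    def __call__(self, pulse_ms):
        return self._poly(np.asarray(pulse_ms, dtype=float))

    def to_row(self) -> dict:
        c = self.coefficients
        return {
            "transmitter_id": self.transmitter_id,
            "c0": c[0], "c1": c[1], "c2": c[2], "c3": c[3],
            "pulse_min_ms": self.pulse_range[0],
            "pulse_max_ms": self.pulse_range[1],
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def _check_monotone(poly: Polynomial, lo: float, hi: float) -> bool:
    grid = np.linspace(lo, hi, 512)
    dv = np.diff(poly(grid))
    return bool(np.all(dv > 0) or np.all(dv < 0))


def fit_calibration(points, transmitter_id: str) -> CalibrationCurve:
    """Least-squares cubic fit of temperature on pulse interval.

    Parameters
    ----------
    points
        Sequence of ``(pulse_ms, temp_c)`` pairs (order irrelevant), or a
        DataFrame with columns ``pulse_interval_ms`` and ``temperature_c``.

    Raises
    ------
    CalibrationError
        With fewer than 5 distinct pulse values, or if the fitted cubic is
        not strictly monotone over the calibrated pulse range.
    """
    if isinstance(points, pd.DataFrame):
        pulse = points["pulse_interval_ms"].to_numpy(float)
        temp = points["temperature_c"].to_numpy(float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise CalibrationError("points must be (pulse_ms, temp_c) pairs")
        pulse, temp = arr[:, 0], arr[:, 1]
    n_distinct = np.unique(pulse).size
    if n_distinct < MIN_POINTS:
        raise CalibrationError(
            f"{transmitter_id}: {n_distinct} distinct pulse values; "
            f"need >= {MIN_POINTS} for a cubic"
        )
    # fit in a scaled domain for conditioning, convert back to standard basis
    fitted = Polynomial.fit(pulse, temp, deg=3)
    poly = fitted.convert()
    pred = poly(pulse)
    ss_res = float(np.sum((temp - pred) ** 2))
    ss_tot = float(np.sum((temp - temp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    lo, hi = float(pulse.min()), float(pulse.max())
    if not _check_monotone(poly, lo, hi):
        raise CalibrationError(
            f"{transmitter_id}: fitted cubic is not strictly monotone over "
            f"[{lo:.1f}, {hi:.1f}] ms; temperature-interval relation must be "
            "invertible"
        )
    low_r2 = r2 < R2_WARN
    if low_r2:
        log.warning("%s: calibration R^2=%.4f < %.2f", transmitter_id, r2, R2_WARN)
    return CalibrationCurve(
        transmitter_id=transmitter_id,
        coefficients=poly.coef.copy(),
        pulse_range=(lo, hi),
        r_squared=r2,
        n_points=int(len(pulse)),
        low_r2=low_r2,
    )


def pulse_to_temperature(
    curve: CalibrationCurve, pulse_ms, margin: float = DEFAULT_MARGIN
):
    """Convert pulse intervals to temperatures; out-of-range pulses -> NaN.

    Pulses within ``margin`` (a fraction of the calibrated span) beyond
    either end of the calibrated range are still converted; anything
    further out becomes NaN and is counted in the log.
    """
    pulse = np.asarray(pulse_ms, dtype=float)
    scalar = pulse.ndim == 0
    pulse = np.atleast_1d(pulse)
    lo, hi = curve.pulse_range
    slack = (hi - lo) * margin
    ok = (pulse >= lo - slack) & (pulse <= hi + slack)
    out = np.where(ok, curve(pulse), np.nan)
    n_bad = int((~ok & ~np.isnan(pulse)).sum())
    if n_bad:
        log.info("%s: %d pulse(s) outside calibrated range -> missing",
                 curve.transmitter_id, n_bad)
    return float(out[0]) if scalar else out


def load_calibration_table(table: pd.DataFrame) -> dict[str, CalibrationCurve]:
    """Fit one curve per transmitter from a long calibration table."""
    return {
        tx: fit_calibration(grp, tx)
        for tx, grp in table.groupby("transmitter_id", sort=True)
    }


def curves_to_frame(curves: dict[str, CalibrationCurve]) -> pd.DataFrame:
    """Serialize fitted curves to a small table (id, coefficients, range, R^2)."""
    return pd.DataFrame([c.to_row() for c in curves.values()])
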
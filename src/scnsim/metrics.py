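"""Rhythm analytics: period, circadian phase, peak/trough/amplitude.

Phase is expressed in circadian time (CT): the cytosolic calcium peak is
the anchor and is defined to occur at CT 1.5, so the phase of any other
observable is

    CT = (1.5 + 24 * dt_peak / period) mod 24

with dt_peak the time from the preceding calcium peak to the observable's
peak.  Period is the mean peak-to-peak interval after transient discard,
with three-point parabolic interpolation of every peak.  A series whose
half-range amplitude falls below a relative threshold of its mean is
classified arrhythmic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "RhythmMetrics",
    "peak_times_values",
    "estimate_period",
    "phase_CT",
    "percent_change",
    "analyze_series",
]

#: relative half-range amplitude below which a series counts as arrhythmic
RHYTHM_THRESHOLD = 0.01


@dataclass(frozen=True)
class RhythmMetrics:
    """Per-observable rhythm summary."""

    variable: str
    period_h: float          # nan if arrhythmic
    peak_CT: float           # nan if arrhythmic
    peak: float
    trough: float
    amplitude: float         # (peak - trough) / 2
    is_rhythmic: bool

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "period_h": self.period_h,
            "peak_CT": self.peak_CT,
            "peak": self.peak,
            "trough": self.trough,
            "amplitude": self.amplitude,
            "is_rhythmic": self.is_rhythmic,
        }


def _parabolic(t: np.ndarray, y: np.ndarray, idx: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Refine discrete extremum locations with a three-point parabola."""
    times, values = [], []
    dt = t[1] - t[0]
    for i in idx:
        if i == 0 or i == len(y) - 1:
            times.append(t[i])
            values.append(y[i])
            continue
        a, b, c = y[i - 1], y[i], y[i + 1]
        denom = a - 2.0 * b + c
        if denom == 0.0:
            delta = 0.0
        else:
            delta = 0.5 * (a - c) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        times.append(t[i] + delta * dt)
        values.append(b - 0.25 * (a - c) * delta)
    return np.asarray(times), np.asarray(values)


def peak_times_values(
    times: np.ndarray, series: np.ndarray, *, troughs: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated times and values of the cycle peaks (or troughs).

    Peaks are required to be separated by at least a third of the record's
    dominant spacing heuristic (6 h) and to rise above the mid-range, which
    suppresses sampling ripple on flat series.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(series, dtype=float)
    if troughs:
        y = -y
    lo, hi = np.min(y), np.max(y)
    if hi == lo:
        return np.array([]), np.array([])
    dt = times[1] - times[0]
    distance = max(int(round(6.0 / dt)), 1)
    prominence = 0.1 * (hi - lo)
    idx, _ = find_peaks(y, distance=distance, prominence=prominence)
    pt, pv = _parabolic(times, y, idx)
    if troughs:
        pv = -pv
    return pt, pv


def estimate_period(series: np.ndarray, times: np.ndarray) -> float:
    """Mean peak-to-peak interval (h); nan if fewer than two peaks."""
    pt, _ = peak_times_values(times, series)
    if len(pt) < 2:
        return math.nan
    return float(np.mean(np.diff(pt)))


def phase_CT(
    series: np.ndarray, times: np.ndarray, ca_series: np.ndarray
) -> float:
    """Circadian-time phase of the series' peak, anchored to Ca at CT 1.5.

    Both series must share the time grid and be rhythmic with a common
    period; returns nan for arrhythmic input.
    """
    period = estimate_period(np.asarray(ca_series), times)
    if not math.isfinite(period):
        return math.nan
    var_peaks, _ = peak_times_values(times, series)
    ca_peaks, _ = peak_times_values(times, ca_series)
    if len(var_peaks) < 2 or len(ca_peaks) < 2:
        return math.nan
    # circular mean of (1.5 + 24 * dt/period) over all variable peaks that
    # have a preceding calcium peak
    angles = []
    for tp in var_peaks:
        prev = ca_peaks[ca_peaks <= tp]
        if len(prev) == 0:
            continue
        dt_peak = tp - prev[-1]
        ct = (1.5 + 24.0 * dt_peak / period) % 24.0
        angles.append(2.0 * math.pi * ct / 24.0)
    if not angles:
        return math.nan
    mean_angle = math.atan2(
        float(np.mean(np.sin(angles))), float(np.mean(np.cos(angles))))
    return (24.0 * mean_angle / (2.0 * math.pi)) % 24.0


def percent_change(control: float, perturbed: float) -> float:
    """Signed percent change of a metric relative to control."""
    if control == 0:
        raise ZeroDivisionError("control metric is zero")
    return 100.0 * (perturbed - control) / control


def analyze_series(
    name: str,
    times: np.ndarray,
    series: np.ndarray,
    ca_series: np.ndarray | None = None,
    threshold: float = RHYTHM_THRESHOLD,
) -> RhythmMetrics:
    """Full rhythm summary for one observable.

    Peak and trough are the means of the per-cycle interpolated extrema;
    amplitude is half the peak-to-trough range.  The rhythmicity test
    compares the amplitude with ``threshold`` times the absolute mean
    (falling back to the range itself for near-zero-mean series).
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    pt, pv = peak_times_values(times, series)
    tt, tv = peak_times_values(times, series, troughs=True)
    if len(pv) >= 2 and len(tv) >= 2:
        peak, trough = float(np.mean(pv)), float(np.mean(tv))
    else:
        peak, trough = float(np.max(series)), float(np.min(series))
    amplitude = 0.5 * (peak - trough)
    scale = abs(float(np.mean(series)))
    rhythmic = (
        len(pt) >= 2
        and amplitude > threshold * (scale if scale > 0 else 1.0)
    )
    period = estimate_period(series, times) if rhythmic else math.nan
    if rhythmic and ca_series is not None:
        ct = phase_CT(series, times, ca_series)
    else:
        ct = math.nan
    return RhythmMetrics(
        variable=name, period_h=period, peak_CT=ct,
        peak=peak, trough=trough, amplitude=amplitude,
        is_rhythmic=bool(rhythmic),
    )
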
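"""Locomotor-activity summaries: daily weighted centre, nighttime activity,
and pre/post comparisons of daily centres.

Activity is 30-s binned accelerometer counts.  The daily weighted centre is
the count-weighted mean clock time of activity within a midnight-anchored
24-h window; a circular variant is available for phase-wrapped profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ActivitySeries",
    "daily_weighted_center",
    "daily_centers",
    "compare_daily_centers",
    "nighttime_activity",
    "normalized_locomotor_activity",
]

BIN_S = 30.0
BINS_PER_DAY = int(24 * 3600 / BIN_S)


@dataclass
class ActivitySeries:
    """30-s binned activity counts with the housing light schedule."""

    times: pd.DatetimeIndex
    counts: np.ndarray
    lights_on: float = 7.0
    lights_off: float = 19.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if len(self.times) != c.size:
            raise ValueError("times and counts must have equal length")
        if c.size and np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if c.size > 1:
            deltas = np.diff(self.times.view(np.int64))
            if not np.all(deltas == int(BIN_S * 1e9)):
                raise ValueError("bins must be equally spaced at 30 s")
        self.counts = c

    def day_slice(self, day) -> tuple[pd.DatetimeIndex, np.ndarray]:
        day = pd.Timestamp(day).normalize()
        m = (self.times >= day) & (self.times < day + pd.Timedelta(days=1))
        return self.times[m], self.counts[m]

    def days(self) -> list[pd.Timestamp]:
        return sorted(set(self.times.normalize()))


def _bin_mid_hours(times: pd.DatetimeIndex) -> np.ndarray:
    return (times.hour + times.minute / 60.0
            + (times.second + BIN_S / 2.0) / 3600.0).to_numpy(dtype=float)


def daily_weighted_center(series: ActivitySeries, day, circular: bool = False) -> float:
    """Count-weighted mean clock hour of activity for one complete day.

    Bin times are taken at bin midpoints (bin start + 15 s).  Returns NaN for
    a day with zero total counts; raises for a day without full 24-h coverage.
    With ``circular=True``, the circular mean over the 24-h cycle is used
    instead of the midnight-anchored linear mean.
    """
    times, counts = series.day_slice(day)
    if len(times) != BINS_PER_DAY:
        raise ValueError(f"day {day} lacks full 24-h coverage "
                         f"({len(times)}/{BINS_PER_DAY} bins)")
    total = counts.sum()
    if total == 0:
        return float("nan")
    h = _bin_mid_hours(times)
    if circular:
        ang = h / 24.0 * 2.0 * np.pi
        mean = np.angle(np.sum(counts * np.exp(1j * ang)))
        return float(np.mod(mean / (2.0 * np.pi) * 24.0, 24.0))
    return float(np.sum(h * counts) / total)


def daily_centers(series: ActivitySeries, circular: bool = False) -> pd.Series:
    """Weighted centre for every complete day in the series."""
    out = {}
    for day in series.days():
        times, _ = series.day_slice(day)
        if len(times) == BINS_PER_DAY:
            out[day] = daily_weighted_center(series, day, circular=circular)
    return pd.Series(out, dtype=float)


def compare_daily_centers(pre_centers, post_centers, method: str = "asymptotic"):
    """Two-sided Mann-Whitney U between pre and post daily centres.

    Returns ``(U, p, direction)`` with direction "later"/"earlier"/"none" by
    the sign of the median difference.  Requires >= 3 valid days per period.
    """
    from scipy import stats

    pre = np.asarray(pd.Series(pre_centers).dropna(), dtype=float)
    post = np.asarray(pd.Series(post_centers).dropna(), dtype=float)
    if pre.size < 3 or post.size < 3:
        raise ValueError("need at least 3 valid daily centres per period")
    res = stats.mannwhitneyu(pre, post, alternative="two-sided", method=method)
    diff = np.median(post) - np.median(pre)
    direction = "later" if diff > 0 else ("earlier" if diff < 0 else "none")
    return float(res.statistic), float(res.pvalue), direction


def nighttime_activity(series: ActivitySeries, hours_after_dark: float = 3.0) -> pd.Series:
    """Summed counts in [lights_off, lights_off + hours) for each night.

    Nights whose window is not fully covered are skipped with a warning.
    """
    n_bins = int(round(hours_after_dark * 3600 / BIN_S))
    start_h = series.lights_off
    out = {}
    for day in series.days():
        t0 = pd.Timestamp(day) + pd.Timedelta(hours=start_h)
        t1 = t0 + pd.Timedelta(hours=hours_after_dark)
        m = (series.times >= t0) & (series.times < t1)
        if int(m.sum()) != n_bins:
            warnings.warn(f"skipping night of {day.date()}: incomplete window",
                          stacklevel=2)
            continue
        out[day] = int(series.counts[m].sum())
    return pd.Series(out, dtype=float)


def _weekday_daily_totals(series: ActivitySeries) -> pd.Series:
    """Total counts of each complete weekday (Mon-Fri) in the series."""
    out = {}
    for day in series.days():
        times, counts = series.day_slice(day)
        if len(times) == BINS_PER_DAY and day.weekday() < 5:
            out[day] = float(counts.sum())
    return pd.Series(out, dtype=float)


def normalized_locomotor_activity(pre_series: ActivitySeries,
                                  post_series: ActivitySeries) -> float:
    """Daily activity of the first 3 post weekdays over the last 3 pre weekdays.

    Both sums run over complete calendar weekdays; returns NaN when the
    pre-period sum is zero.
    """
    pre = _weekday_daily_totals(pre_series)
    post = _weekday_daily_totals(post_series)
    if len(pre) < 3 or len(post) < 3:
        raise ValueError("need >= 3 complete weekdays in each period")
    pre_sum = pre.iloc[-3:].sum()
    post_sum = post.iloc[:3].sum()
    if pre_sum == 0:
        return float("nan")
    return float(post_sum / pre_sum)
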
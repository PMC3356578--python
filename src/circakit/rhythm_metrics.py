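"""Nonparametric rhythm statistics and the χ² periodogram.

The battery quantifies four aspects of an entrained activity rhythm:

* **light-phase activity** — the share of total counts emitted while the
  lights are on (nocturnal animals keep this near zero);
* **interdaily stability (IS)** — day-to-day reproducibility of the 24-h
  profile, the ratio of the variance of the mean daily profile to the total
  variance: ``IS = (N Σ_h (x̄_h − x̄)²) / (p Σ_i (x_i − x̄)²)``, in [0, 1];
* **intradaily variability (IV)** — fragmentation, the normalized
  first-difference mean square:
  ``IV = (N Σ_{i≥2} (x_i − x_{i−1})²) / ((N−1) Σ_i (x_i − x̄)²)``,
  ≈0 for smooth rhythms, →2 for white noise, up to 4 for strict alternation;
* **χ² periodogram** — the Sokolove–Bushell statistic.  For a candidate
  period of K bins using m complete cycles (N = mK epochs, partial trailing
  cycle discarded), ``Qp = m N Σ_h (x̄_h − x̄)² / Σ_i (x_i − x̄)²``, referred
  to a χ² distribution with K − 1 degrees of freedom.  The *amplitude* is
  Qp minus the significance line at the peak period, the convention used by
  common actigraphy software.

IS and IV follow the standard actigraphy convention of 1-h bins
(``bins_per_day=24``); the binning is exposed because conventions differ.
Gap-masked epochs are excluded from all sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError, ZeroVarianceError
from .io_formats import ActivitySeries, rebin
from .schedule import LightSchedule

__all__ = [
    "PeriodogramResult",
    "Bout",
    "light_phase_activity_pct",
    "interdaily_stability",
    "intradaily_variability",
    "detect_bouts",
    "bouts_per_day",
    "chi_square_periodogram",
]


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    qp: np.ndarray
    df: np.ndarray
    sig_line: np.ndarray
    alpha: float

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.qp))

    @property
    def peak_period_h(self) -> float:
        return float(self.periods_h[self.peak_index])

    @property
    def amplitude(self) -> float:
        """Qp minus the significance line at the peak; negative = no rhythm."""
        i = self.peak_index
        return float(self.qp[i] - self.sig_line[i])


@dataclass(frozen=True)
class Bout:
    """A consolidated activity episode."""

    start_h: float
    end_h: float
    total_counts: float

    @property
    def duration_min(self) -> float:
        return (self.end_h - self.start_h) * 60.0


# ---------------------------------------------------------------------- #


def _complete_day_slice(series: ActivitySeries) -> tuple[np.ndarray, np.ndarray, int]:
    """Counts and epoch starts restricted to whole days from the first
    day boundary at or after the series start."""
    per_day = int(round(1440.0 / series.epoch_min))
    starts = series.epoch_starts_h()
    first_boundary_h = np.ceil(series.start_h / 24.0 - 1e-9) * 24.0
    first = int(round((first_boundary_h - series.start_h) / series.epoch_h))
    n_days = (len(series) - first) // per_day
    if n_days < 1:
        raise InsufficientDataError("needs at least one complete day")
    sl = slice(first, first + n_days * per_day)
    return series.counts[sl], starts[sl], n_days


def light_phase_activity_pct(series: ActivitySeries, schedule: LightSchedule) -> float:
    """Percent of total counts emitted during scheduled light, whole days only."""
    counts, starts, n_days = _complete_day_slice(series)
    day0 = int(starts[0] // 24)
    for d in range(day0, day0 + n_days):
        if not schedule.segment_for_day(d).is_ld:
            raise ValidationError("light-phase activity requires LD days")
    total = counts.sum()
    if total <= 0:
        raise ZeroVarianceError("no activity: light-phase share undefined")
    light = np.array([schedule.is_scheduled_light(t) for t in starts])
    return 100.0 * counts[light].sum() / total


def _binned_whole_days(
    series: ActivitySeries, bins_per_day: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rebin to the statistic's bin width and keep whole days.

    Returns (values, valid) with gap-contaminated bins flagged invalid.
    """
    if 1440 % bins_per_day:
        raise ValidationError("bins_per_day must divide 1440")
    series = rebin(series, 1440.0 / bins_per_day)
    n_days = len(series) // bins_per_day
    if n_days < 2:
        raise InsufficientDataError("needs at least two complete days")
    n = n_days * bins_per_day
    return series.counts[:n], series.valid_mask()[:n]


def interdaily_stability(series: ActivitySeries, bins_per_day: int = 24) -> float:
    x, valid = _binned_whole_days(series, bins_per_day)
    xv = x[valid]
    n = xv.size
    xbar = xv.mean()
    denom = ((xv - xbar) ** 2).sum()
    if denom <= 0:
        raise ZeroVarianceError("constant series: IS undefined")
    hour = np.arange(x.size) % bins_per_day
    num = 0.0
    for h in range(bins_per_day):
        sel = (hour == h) & valid
        if sel.any():
            num += sel.sum() * (x[sel].mean() - xbar) ** 2
    # equals N·Σ_h(x̄_h−x̄)²/(p·Σ(x−x̄)²) for gap-free data, since each of the
    # p bins then carries weight N/p; gap-aware weights generalize that
    del n
    return float(num / denom)


def intradaily_variability(series: ActivitySeries, bins_per_day: int = 24) -> float:
    x, valid = _binned_whole_days(series, bins_per_day)
    ok_pair = valid[1:] & valid[:-1]
    xv = x[valid]
    n = xv.size
    xbar = xv.mean()
    denom = ((xv - xbar) ** 2).sum()
    if denom <= 0:
        raise ZeroVarianceError("constant series: IV undefined")
    diffs = (x[1:] - x[:-1])[ok_pair]
    return float(n * (diffs**2).sum() / ((diffs.size) * denom)) if diffs.size else 0.0


def detect_bouts(
    series: ActivitySeries,
    count_threshold: float = 1.0,
    min_bout_min: float = 10.0,
    max_gap_min: float = 30.0,
) -> list[Bout]:
    """Consolidated activity episodes.

    A bout is a maximal run of epochs with count ≥ ``count_threshold``;
    sub-threshold gaps no longer than ``max_gap_min`` are merged into the
    surrounding bout, and merged episodes shorter than ``min_bout_min``
    are discarded.
    """
    if count_threshold < 0 or min_bout_min < 0 or max_gap_min < 0:
        raise ValidationError("bout parameters must be non-negative")
    above = series.counts >= count_threshold
    starts_h = series.epoch_starts_h()
    eh = series.epoch_h
    max_gap_epochs = int(max_gap_min // series.epoch_min)

    runs: list[tuple[int, int]] = []  # [start, end) epoch indices of raw runs
    i = 0
    n = len(series)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= max_gap_epochs:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    bouts = []
    for a, b in merged:
        if (b - a) * series.epoch_min >= min_bout_min:
            bouts.append(
                Bout(
                    start_h=float(starts_h[a]),
                    end_h=float(starts_h[b - 1] + eh),
                    total_counts=float(series.counts[a:b].sum()),
                )
            )
    return bouts


def bouts_per_day(
    series: ActivitySeries,
    count_threshold: float = 1.0,
    min_bout_min: float = 10.0,
    max_gap_min: float = 30.0,
) -> float:
    """Mean number of bouts per complete day."""
    counts, starts, n_days = _complete_day_slice(series)
    sub = ActivitySeries(
        counts=counts, epoch_min=series.epoch_min, start_h=float(starts[0])
    )
    total = 0
    per_day = int(round(1440.0 / series.epoch_min))
    for d in range(n_days):
        day = ActivitySeries(
            counts=sub.counts[d * per_day : (d + 1) * per_day],
            epoch_min=series.epoch_min,
            start_h=float(starts[d * per_day]),
        )
        total += len(detect_bouts(day, count_threshold, min_bout_min, max_gap_min))
    return total / n_days


def chi_square_periodogram(
    series: ActivitySeries,
    period_min_h: float = 20.0,
    period_max_h: float = 28.0,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Sokolove–Bushell χ² periodogram over a grid of candidate periods.

    The grid step is one epoch; for each candidate period only the largest
    whole number of complete cycles is used.  The significance line is the
    (1 − α) χ² quantile with K − 1 degrees of freedom (K bins per period).
    """
    if period_max_h * 2.0 > series.duration_h:
        raise InsufficientDataError("series must span at least 2× period_max")
    x_all = series.counts
    valid = series.valid_mask()
    eh = series.epoch_h
    k_min = int(np.ceil(period_min_h / eh - 1e-9))
    k_max = int(np.floor(period_max_h / eh + 1e-9))
    if k_max < k_min or k_min < 2:
        raise ValidationError("empty or degenerate period grid")
    if np.var(x_all[valid]) <= 0:
        raise ZeroVarianceError("constant series: periodogram undefined")

    ks = np.arange(k_min, k_max + 1)
    qp = np.empty(ks.size)
    gap_free = bool(valid.all())
    for j, k in enumerate(ks):
        m = len(series) // k
        n = m * k
        x = x_all[:n]
        if gap_free:
            xbar = x.mean()
            denom = ((x - xbar) ** 2).sum()
            col_means = x.reshape(m, k).mean(axis=0)
            num = m * ((col_means - xbar) ** 2).sum()
            qp[j] = n * num / denom if denom > 0 else 0.0
            continue
        ok = valid[:n]
        xv = x[ok]
        xbar = xv.mean()
        denom = ((xv - xbar) ** 2).sum()
        col = np.arange(n) % k
        num = 0.0
        for h in range(k):
            sel = (col == h) & ok
            c = sel.sum()
            if c:
                num += c * (x[sel].mean() - xbar) ** 2
        # num is Σ_i (x̄_{h(i)} − x̄)² over usable epochs; Qp = N·num/denom
        qp[j] = xv.size * num / denom if denom > 0 else 0.0
    df = ks - 1
    sig = stats.chi2.ppf(1.0 - alpha, df)
    return PeriodogramResult(
        periods_h=ks * eh, qp=qp, df=df.astype(float), sig_line=sig, alpha=alpha
    )
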
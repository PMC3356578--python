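"""Onset-based phase estimation.

All phase statistics here are computed from detected *activity onsets* —
the field's default reference point for nocturnal rodents:

* **phase angle of entrainment ψ** — signed minutes between onset and
  lights-off; positive means the onset precedes lights-off (advanced).
  The advance-positive sign convention holds package-wide.
* **free-running period τ** — 24 h plus the slope of a least-squares fit of
  unwrapped onset time against cycle index under constant conditions.
* **phase-shift magnitude** — separate onset-vs-day regressions before and
  after a shift event (discarding post-shift transient days), differenced at
  the event day; positive = advance.
* **re-entrainment time** — days from the shift until the phase angle stays
  within a criterion of its new steady state.
* **masking index** — percent suppression of activity during a light pulse
  relative to the same clock-time window on baseline days.

The onset detector is a template heuristic (the quiet-then-active rule):
an onset is the first epoch that is itself active, preceded by a quiet
window and followed by a sustained active window, all thresholded against
the day's mean nonzero epoch rate.  Every parameter is surfaced because no
single convention is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError, ZeroVarianceError
from .io_formats import ActivitySeries
from .schedule import LightSchedule

__all__ = [
    "OnsetSeries",
    "PhaseAngleResult",
    "FreeRunResult",
    "detect_onsets",
    "phase_angle_entrainment",
    "estimate_tau",
    "phase_shift_magnitude",
    "reentrainment_time",
    "masking_index",
    "NOT_REENTRAINED",
]

NOT_REENTRAINED = -1
"""Sentinel returned by :func:`reentrainment_time` when the record ends
before the re-entrainment criterion is met."""


@dataclass
class OnsetSeries:
    """Detected activity onsets, at most one per day.

    ``onset_min[i]`` is minutes after midnight of calendar day ``days[i]``;
    ``flagged_days`` lists days where no qualifying onset was found.
    """

    days: np.ndarray
    onset_min: np.ndarray
    flagged_days: list[int] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.onset_min = np.asarray(self.onset_min, dtype=float)
        if self.days.size != self.onset_min.size:
            raise ValidationError("days and onset_min must align")

    def __len__(self) -> int:
        return self.days.size

    @property
    def onset_abs_min(self) -> np.ndarray:
        """Absolute onset times in minutes from hour 0 of day 0."""
        return self.days * 1440.0 + self.onset_min

    def onset_on(self, day: int) -> Optional[float]:
        idx = np.nonzero(self.days == day)[0]
        return float(self.onset_min[idx[0]]) if idx.size else None

    def window(self, day_lo: int, day_hi: int) -> "OnsetSeries":
        """Onsets with day in [day_lo, day_hi)."""
        sel = (self.days >= day_lo) & (self.days < day_hi)
        return OnsetSeries(
            days=self.days[sel],
            onset_min=self.onset_min[sel],
            flagged_days=[d for d in self.flagged_days if day_lo <= d < day_hi],
            params=self.params,
        )


@dataclass(frozen=True)
class PhaseAngleResult:
    """Mean phase angle of entrainment; positive = onset before lights-off."""

    psi_min: float
    sd_min: float
    n_days: int


@dataclass(frozen=True)
class FreeRunResult:
    tau_h: float
    ci_95: tuple[float, float]
    method: str
    n_days: int


# ---------------------------------------------------------------------- #
# onset detection


def detect_onsets(
    series: ActivitySeries,
    quiet_h: float = 4.0,
    active_h: float = 1.0,
    frac_threshold: float = 0.5,
) -> OnsetSeries:
    """Detect one activity onset per circadian cycle.

    An epoch qualifies when (a) its own count exceeds the threshold, (b) the
    preceding ``quiet_h`` window has mean activity below the threshold and
    (c) the following ``active_h`` window has mean activity above it, where
    the threshold is ``frac_threshold`` times the surrounding day's mean
    nonzero epoch count.  After each accepted onset the search skips 16 h,
    so drifting (free-running) onsets are followed across day boundaries.
    """
    if len(series) == 0:
        raise InsufficientDataError("empty series")
    if quiet_h <= 0 or active_h <= 0 or frac_threshold <= 0:
        raise ValidationError("detector parameters must be positive")
    counts = series.counts
    starts = series.epoch_starts_h()
    n = len(series)
    eh = series.epoch_h
    q = max(int(round(quiet_h / eh)), 1)
    a = max(int(round(active_h / eh)), 1)

    # reference rate: mean of the series' nonzero epochs (robust to the
    # large all-zero fraction outside the active band)
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    nonzero = counts[counts > 0]
    thr = frac_threshold * (nonzero.mean() if nonzero.size else 0.0)

    days: list[int] = []
    onset_min: list[float] = []
    i = q
    skip = int(round(16.0 / eh))
    while i < n - a:
        if thr > 0 and counts[i] > thr:
            quiet_mean = (csum[i] - csum[i - q]) / q
            active_mean = (csum[i + a] - csum[i]) / a
            if quiet_mean < thr and active_mean > thr:
                t = starts[i]
                days.append(int(t // 24.0))
                onset_min.append((t % 24.0) * 60.0)
                i += skip
                continue
        i += 1

    found = set(days)
    first_day = int(series.start_h // 24.0)
    last_day = int((series.end_h - 1e-9) // 24.0)
    flagged = [d for d in range(first_day, last_day + 1) if d not in found]
    return OnsetSeries(
        days=np.array(days, dtype=int),
        onset_min=np.array(onset_min),
        flagged_days=flagged,
        params={
            "quiet_h": quiet_h,
            "active_h": active_h,
            "frac_threshold": frac_threshold,
        },
    )


# ---------------------------------------------------------------------- #
# phase angle of entrainment


def phase_angle_entrainment(
    onsets: OnsetSeries, schedule: LightSchedule
) -> PhaseAngleResult:
    """Mean signed minutes from onset to lights-off over entrained days."""
    psis = []
    for day, om in zip(onsets.days, onsets.onset_min):
        seg = schedule.segment_for_day(int(day))
        if not seg.is_ld:
            raise ValidationError("phase angle requires LD days only")
        off_min = schedule.lights_off_time(int(day)) * 60.0
        psis.append(off_min - (day * 1440.0 + om))
    if len(psis) < 3:
        raise InsufficientDataError("phase angle needs >= 3 onsets")
    psis = np.array(psis)
    return PhaseAngleResult(
        psi_min=float(psis.mean()),
        sd_min=float(psis.std(ddof=1)),
        n_days=len(psis),
    )


# ---------------------------------------------------------------------- #
# free-running period


def _unwrap_cycles(onsets: OnsetSeries) -> tuple[np.ndarray, np.ndarray]:
    """(cycle index, unwrapped onset minutes-of-day) for regression.

    Successive onsets are assumed one circadian cycle apart (two if a cycle
    was missed, etc.): the cycle count between detections is the nearest
    integer to their absolute separation over 24 h, valid for τ ∈ (20, 28)
    with at most occasional missed cycles.
    """
    order = np.argsort(onsets.onset_abs_min)
    abs_min = onsets.onset_abs_min[order]
    k = np.zeros(abs_min.size, dtype=int)
    for i in range(1, abs_min.size):
        k[i] = k[i - 1] + max(int(round((abs_min[i] - abs_min[i - 1]) / 1440.0)), 1)
    unwrapped = abs_min - k * 1440.0
    return k.astype(float), unwrapped


def estimate_tau(
    onsets: OnsetSeries,
    method: str = "onset_regression",
    series: Optional[ActivitySeries] = None,
) -> FreeRunResult:
    """Free-running period from onsets (regression) or the periodogram peak.

    ``onset_regression``: τ = 24 h + slope of unwrapped onset time versus
    cycle index (min/cycle → hours), with a 95% CI from the slope's
    standard error.  ``periodogram`` delegates to the χ² periodogram peak
    of ``series`` (no CI).
    """
    if method == "periodogram":
        if series is None:
            raise ValidationError("periodogram method needs the activity series")
        from .rhythm_metrics import chi_square_periodogram

        pg = chi_square_periodogram(series)
        return FreeRunResult(
            tau_h=pg.peak_period_h,
            ci_95=(float("nan"), float("nan")),
            method="periodogram",
            n_days=int(series.duration_h // 24),
        )
    if method != "onset_regression":
        raise ValidationError(f"unknown method {method!r}")
    if len(onsets) < 5:
        raise InsufficientDataError("tau regression needs >= 5 onsets")
    k, y = _unwrap_cycles(onsets)
    fit = stats.linregress(k, y)
    tau = 24.0 + fit.slope / 60.0
    tcrit = stats.t.ppf(0.975, len(onsets) - 2)
    half = tcrit * fit.stderr / 60.0
    return FreeRunResult(
        tau_h=float(tau),
        ci_95=(float(tau - half), float(tau + half)),
        method="onset_regression",
        n_days=len(onsets),
    )


# ---------------------------------------------------------------------- #
# phase shifts and re-entrainment


def _fit_line(days: np.ndarray, abs_min: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) of onset absolute minutes vs day; tolerates a
    single day (zero slope)."""
    if days.size == 0:
        raise InsufficientDataError("no onsets in window")
    if days.size == 1 or np.ptp(days) == 0:
        return float(abs_min.mean() - 1440.0 * days.mean()), 1440.0
    slope, intercept = np.polyfit(days, abs_min, 1)
    return float(intercept), float(slope)


def phase_shift_magnitude(
    onsets: OnsetSeries,
    event_day: int,
    pre_window_days: int = 7,
    post_window_days: int = 7,
    transient_days: int = 5,
) -> float:
    """Steady-state phase shift in signed minutes; positive = advance.

    Fits onset-vs-day lines to ``pre_window_days`` before the event and to
    ``post_window_days`` after discarding ``transient_days`` of transients,
    then evaluates both at ``event_day``.  An advance makes post-shift
    onsets earlier, so the shift is the pre line minus the post line.
    """
    pre = onsets.window(event_day - pre_window_days, event_day)
    post = onsets.window(
        event_day + transient_days, event_day + transient_days + post_window_days
    )
    if len(pre) < 2 or len(post) < 2:
        raise InsufficientDataError("need >= 2 steady-state onsets on each side")
    b0_pre, b1_pre = _fit_line(pre.days, pre.onset_abs_min)
    b0_post, b1_post = _fit_line(post.days, post.onset_abs_min)
    pre_at = b0_pre + b1_pre * event_day
    post_at = b0_post + b1_post * event_day
    return float(pre_at - post_at)


def reentrainment_time(
    onsets: OnsetSeries,
    schedule: LightSchedule,
    criterion_min: float = 30.0,
    consecutive_days: int = 3,
    shift_index: int = 0,
) -> int:
    """Days taken to re-entrain after a schedule shift.

    Returns the smallest ``d`` (days counted from the shift, with ``d = 0``
    the last pre-shift day) from which the absolute deviation of the daily
    phase angle from its new steady state stays below ``criterion_min`` for
    ``consecutive_days`` running, or :data:`NOT_REENTRAINED`.
    """
    if not schedule.shifts:
        raise ValidationError("schedule has no shift event")
    shift_day = schedule.shifts[shift_index].day
    # steady-state phase angle: mean over the last third of post-shift days
    post_days = sorted(d for d in onsets.days if d >= shift_day)
    if not post_days:
        raise InsufficientDataError("no post-shift onsets")
    tail_from = post_days[max(len(post_days) - max(len(post_days) // 3, 3), 0)]
    tail = [
        schedule.lights_off_time(int(d)) * 60.0 - (d * 1440.0 + om)
        for d, om in zip(onsets.days, onsets.onset_min)
        if d >= tail_from
    ]
    psi_ss = float(np.mean(tail))

    run = 0
    result: Optional[int] = None
    for d in range(shift_day - 1, int(onsets.days.max()) + 1):
        om = onsets.onset_on(d)
        if om is None:
            run = 0
            result = None
            continue
        seg = schedule.segment_for_day(d)
        if not seg.is_ld:
            raise ValidationError("re-entrainment tracking requires LD days")
        # phase relative to the *post-shift* cycle, also for pre-shift days
        off_min = (
            24.0 * d
            + seg.lights_on
            - schedule.cumulative_advance_h(max(d, shift_day))
            + seg.photoperiod_h
        ) * 60.0
        psi_d = off_min - (d * 1440.0 + om)
        if abs(psi_d - psi_ss) < criterion_min:
            run += 1
            if result is None:
                result = d - (shift_day - 1)
            if run >= consecutive_days:
                return result
        else:
            run = 0
            result = None
    return NOT_REENTRAINED


# ---------------------------------------------------------------------- #
# masking


def masking_index(
    series: ActivitySeries,
    schedule: LightSchedule,
    pulse_index: int = 0,
    baseline_days: Optional[list[int]] = None,
) -> float:
    """Percent suppression of activity during a light pulse.

    100·(1 − A_pulse / Ā_baseline), where A is the total count inside the
    pulse window and the baseline is the mean over the same clock-time
    window on ``baseline_days`` (default: all other complete days).
    Clipped above at 100; negative values indicate positive masking.
    """
    try:
        pulse = schedule.pulses[pulse_index]
    except IndexError:
        raise ValidationError(f"no pulse with index {pulse_index}") from None
    starts = series.epoch_starts_h()
    t0, t1 = pulse.start_h, pulse.end_h
    tod0, tod1 = t0 % 24.0, t0 % 24.0 + (t1 - t0)
    pulse_day = int(t0 // 24.0)

    def window_total(day: int) -> float:
        sel = (starts >= day * 24.0 + tod0) & (starts < day * 24.0 + tod1)
        return float(series.counts[sel].sum())

    if baseline_days is None:
        first = int(np.ceil(series.start_h / 24.0 - 1e-9))
        last = int(series.end_h // 24.0)
        baseline_days = [d for d in range(first, last) if d != pulse_day]
    if not baseline_days:
        raise InsufficientDataError("no baseline days")
    a_pulse = window_total(pulse_day)
    a_base = float(np.mean([window_total(d) for d in baseline_days]))
    if a_base <= 0:
        raise ZeroVarianceError("zero baseline activity in the pulse window")
    return min(100.0 * (1.0 - a_pulse / a_base), 100.0)
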
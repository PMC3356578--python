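"""Activity-series container, file I/O, rebinning, folding and actograms.

Wheel-running data arrive as uniformly binned activity counts per epoch
(typically 10-min bins).  Two plain-text dialects are supported:

``long_csv``
    Header ``subject_id,timestamp,counts``; ISO-8601 timestamps with uniform
    spacing per subject.  The first sample defines t = 0 of its subject's
    timeline (elapsed-hours convention of :mod:`circakit.schedule`, with the
    midnight preceding the first sample as day 0 / hour 0).

``awd``
    Actiwatch-style text: seven header lines (ID, start date DD-MMM-YYYY,
    start time HH:MM, epoch code, age, serial, sex) followed by one count
    per line.

Missing epochs in ``long_csv`` are zero-filled and recorded in a gap mask so
downstream statistics can exclude them from denominators.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError
from .schedule import LightSchedule

__all__ = [
    "ActivitySeries",
    "DailyMatrix",
    "read_activity_table",
    "write_activity_table",
    "rebin",
    "fold_daily",
    "render_actogram",
]

# nominal calendar origin for writing elapsed times as ISO timestamps
_ORIGIN = _dt.datetime(2000, 1, 1, 0, 0, 0)

# Actiwatch epoch codes (seconds per epoch is 15 * 2**code in the common
# convention; code 4 = 4 min is the wheel-cage default we emit)
_AWD_EPOCH_MIN = {"1": 0.25, "2": 0.5, "4": 1.0, "8": 2.0, "20": 5.0, "40": 10.0, "81": 15.0}


@dataclass
class ActivitySeries:
    """Uniformly binned non-negative activity counts for one subject.

    ``start_h`` is the elapsed-hours offset of the first epoch's start from
    hour 0 of day 0.  ``gap_mask`` marks epochs that were absent in the
    source file (zero-filled); metrics exclude them from denominators.
    """

    counts: np.ndarray
    epoch_min: float
    start_h: float = 0.0
    subject_id: str = ""
    group: str = ""
    gap_mask: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValidationError("counts must be a non-empty 1-D sequence")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.epoch_min <= 0:
            raise ValidationError("epoch_min must be positive")
        if self.gap_mask is not None:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.shape != self.counts.shape:
                raise ValidationError("gap_mask must match counts in length")

    def __len__(self) -> int:
        return self.counts.size

    @property
    def epoch_h(self) -> float:
        return self.epoch_min / 60.0

    @property
    def duration_h(self) -> float:
        return len(self) * self.epoch_h

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h

    def epoch_starts_h(self) -> np.ndarray:
        """Absolute start time (hours) of every epoch."""
        return self.start_h + np.arange(len(self)) * self.epoch_h

    def valid_mask(self) -> np.ndarray:
        if self.gap_mask is None:
            return np.ones(len(self), dtype=bool)
        return ~self.gap_mask

    def slice_hours(self, t0_h: float, t1_h: float) -> "ActivitySeries":
        """Epochs whose start lies in [t0, t1)."""
        starts = self.epoch_starts_h()
        sel = (starts >= t0_h) & (starts < t1_h)
        idx = np.nonzero(sel)[0]
        if idx.size == 0:
            raise InsufficientDataError("empty slice")
        return ActivitySeries(
            counts=self.counts[idx],
            epoch_min=self.epoch_min,
            start_h=starts[idx[0]],
            subject_id=self.subject_id,
            group=self.group,
            gap_mask=None if self.gap_mask is None else self.gap_mask[idx],
        )


@dataclass
class DailyMatrix:
    """Counts folded at a fixed period: one row per complete cycle."""

    values: np.ndarray  # (n_cycles, bins_per_cycle)
    fold_period_h: float
    epoch_min: float

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0]

    @property
    def bins_per_cycle(self) -> int:
        return self.values.shape[1]

    def column_means(self) -> np.ndarray:
        """Across-cycle mean profile (the x̄_h of the rhythm statistics)."""
        return self.values.mean(axis=0)


# ---------------------------------------------------------------------- #
# file I/O


def _parse_long_csv(path: Path) -> list[ActivitySeries]:
    df = pd.read_csv(path)
    required = {"subject_id", "timestamp", "counts"}
    if not required.issubset(df.columns):
        raise FormatError(f"long_csv requires columns {sorted(required)}")
    if (df["counts"] < 0).any():
        raise FormatError("negative counts in input")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out: list[ActivitySeries] = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("timestamp")
        ts = sub["timestamp"].to_numpy()
        if len(ts) < 2:
            epoch_min = 10.0
        else:
            deltas = np.diff(ts).astype("timedelta64[s]").astype(float) / 60.0
            epoch_min = float(np.min(deltas))
            # uniform grid up to 1-s tolerance; integer multiples are gaps
            ratio = deltas / epoch_min
            if np.any(np.abs(ratio - np.round(ratio)) * epoch_min * 60.0 > 1.0):
                raise FormatError(f"non-uniform timestamps for subject {sid}")
        t0 = pd.Timestamp(ts[0])
        midnight = t0.normalize()
        start_h = (t0 - midnight).total_seconds() / 3600.0
        offsets = (
            np.array([(pd.Timestamp(t) - t0).total_seconds() for t in ts]) / 60.0
        )
        idx = np.round(offsets / epoch_min).astype(int)
        n = idx[-1] + 1
        counts = np.zeros(n)
        gaps = np.ones(n, dtype=bool)
        counts[idx] = sub["counts"].to_numpy(dtype=float)
        gaps[idx] = False
        group = str(sub["group"].iloc[0]) if "group" in sub.columns else ""
        out.append(
            ActivitySeries(
                counts=counts,
                epoch_min=epoch_min,
                start_h=start_h,
                subject_id=str(sid),
                group=group,
                gap_mask=gaps if gaps.any() else None,
            )
        )
    return out


def _parse_awd(path: Path) -> list[ActivitySeries]:
    lines = path.read_text().splitlines()
    if len(lines) < 8:
        raise FormatError("awd file needs a 7-line header plus data")
    sid = lines[0].strip()
    try:
        start_date = _dt.datetime.strptime(lines[1].strip(), "%d-%b-%Y")
        start_time = _dt.datetime.strptime(lines[2].strip(), "%H:%M").time()
    except ValueError as e:
        raise FormatError(f"bad awd header: {e}") from e
    code = lines[3].strip()
    if code not in _AWD_EPOCH_MIN:
        raise FormatError(f"unknown awd epoch code {code!r}")
    epoch_min = _AWD_EPOCH_MIN[code]
    counts = []
    for ln in lines[7:]:
        ln = ln.strip()
        if not ln:
            continue
        # activity field may be followed by a marker column
        val = float(ln.split()[0])
        if val < 0:
            raise FormatError("negative counts in awd file")
        counts.append(val)
    start_h = start_time.hour + start_time.minute / 60.0
    del start_date  # calendar date irrelevant under elapsed-time convention
    return [
        ActivitySeries(
            counts=np.array(counts), epoch_min=epoch_min, start_h=start_h, subject_id=sid
        )
    ]


def read_activity_table(path: str | Path, dialect: str = "long_csv") -> list[ActivitySeries]:
    """Read one or more activity series from a text file."""
    path = Path(path)
    if dialect == "long_csv":
        return _parse_long_csv(path)
    if dialect == "awd":
        return _parse_awd(path)
    raise ValidationError(f"unknown dialect {dialect!r}")


def write_activity_table(series: Sequence[ActivitySeries], path: str | Path) -> None:
    """Write series to a ``long_csv`` table (gap epochs omitted)."""
    rows = []
    for s in series:
        starts = s.epoch_starts_h()
        valid = s.valid_mask()
        for t, c, ok in zip(starts, s.counts, valid):
            if not ok:
                continue
            ts = _ORIGIN + _dt.timedelta(hours=float(t))
            rows.append(
                {
                    "subject_id": s.subject_id or "subj",
                    "timestamp": ts.isoformat(),
                    "counts": c,
                    "group": s.group,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------- #
# rebin / fold


def rebin(series: ActivitySeries, new_epoch_min: float) -> ActivitySeries:
    """Sum counts into coarser bins; trailing partial bin is dropped."""
    factor = new_epoch_min / series.epoch_min
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValidationError(
            f"new epoch {new_epoch_min} must be a positive integer multiple "
            f"of {series.epoch_min}"
        )
    k = int(round(factor))
    if k == 1:
        return series
    n = (len(series) // k) * k
    counts = series.counts[:n].reshape(-1, k).sum(axis=1)
    gaps = None
    if series.gap_mask is not None:
        gaps = series.gap_mask[:n].reshape(-1, k).any(axis=1)
    return ActivitySeries(
        counts=counts,
        epoch_min=new_epoch_min,
        start_h=series.start_h,
        subject_id=series.subject_id,
        group=series.group,
        gap_mask=gaps,
    )


def fold_daily(series: ActivitySeries, fold_period_h: float = 24.0) -> DailyMatrix:
    """Fold counts at a fixed period; incomplete trailing cycle excluded."""
    bins = fold_period_h * 60.0 / series.epoch_min
    if abs(bins - round(bins)) > 1e-9:
        raise ValidationError("fold period must be a whole number of epochs")
    bins = int(round(bins))
    n_cycles = len(series) // bins
    if n_cycles < 1:
        raise InsufficientDataError("series shorter than one fold period")
    values = series.counts[: n_cycles * bins].reshape(n_cycles, bins)
    return DailyMatrix(values=values, fold_period_h=fold_period_h, epoch_min=series.epoch_min)


# ---------------------------------------------------------------------- #
# actogram rendering


def render_actogram(
    series: ActivitySeries,
    schedule: Optional[LightSchedule] = None,
    path: str | Path = "actogram.png",
    double_plot: bool = True,
) -> Path:
    """Day-per-row activity raster, optionally double-plotted over 48 h.

    Scheduled light is shaded; purely presentational.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if series.duration_h < 24.0:
        raise InsufficientDataError("actogram needs at least one full day")
    mat = fold_daily(series, 24.0).values
    n_days, bins = mat.shape
    width_days = 2 if double_plot else 1
    fig, ax = plt.subplots(figsize=(8, max(2, 0.35 * n_days)))
    peak = mat.max() or 1.0
    hours = np.arange(bins) * series.epoch_h
    for d in range(n_days):
        rows = [mat[d]]
        if double_plot:
            rows.append(mat[d + 1] if d + 1 < n_days else np.zeros(bins))
        row = np.concatenate(rows)
        x = np.concatenate([hours + 24.0 * i for i in range(width_days)])
        base = n_days - 1 - d
        ax.bar(x, row / peak * 0.9, bottom=base, width=series.epoch_h,
               align="edge", color="black", linewidth=0)
        if schedule is not None:
            for i in range(width_days):
                day = d + i
                if schedule.end_day is not None and day >= schedule.end_day:
                    continue
                win = schedule.light_window(day)
                if win is None:
                    continue
                a = max(win[0] - 24.0 * day, 0.0) + 24.0 * i
                b = min(win[1] - 24.0 * day, 24.0) + 24.0 * i
                ax.axhspan(base, base + 1, xmin=a / (24 * width_days),
                           xmax=b / (24 * width_days), color="gold", alpha=0.25,
                           linewidth=0)
    ax.set_xlim(0, 24 * width_days)
    ax.set_ylim(0, n_days)
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("day")
    ax.set_yticks(np.arange(n_days) + 0.5)
    ax.set_yticklabels(np.arange(n_days)[::-1])
    ax.set_title(series.subject_id or "actogram")
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
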
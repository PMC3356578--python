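"""Lighting protocols and the Zeitgeber Time (ZT) convention.

All times in this package are timezone-free elapsed hours from the start of
the experiment; day ``d`` spans ``[24*d, 24*(d+1))`` hours and day 0 is the
first recorded day.  A :class:`LightSchedule` is a piecewise protocol made of
contiguous segments (each an LD, dim-LD, DD or LL block), optional discrete
light pulses, and optional phase-shift events ("jet lag") that move the whole
light cycle earlier (advance, positive) or later (delay, negative).

Conventions:

* ``photoperiod_h == 0`` encodes constant darkness (DD), ``24`` constant
  light (LL); anything in between is an LD cycle.
* ZT0 is lights-on; ZT12 is lights-off under a 12:12 cycle.
* Under DD/LL, ZT is *projected* from the phase of the last preceding LD
  segment, mirroring how sampling times are reported for animals released
  into constant conditions.
* An epoch straddling a light transition takes the state at its start, so
  all queries here are instantaneous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import OutOfRangeError, UndefinedZTError, ValidationError

__all__ = ["Segment", "Pulse", "ShiftEvent", "LightSchedule"]


@dataclass(frozen=True)
class Segment:
    """A block of days sharing one lighting regime.

    Parameters
    ----------
    start_day:
        First day (inclusive) governed by this segment.
    n_days:
        Number of days, or ``None`` for an open-ended final segment.
    lights_on:
        Clock time of lights-on in hours of day, e.g. ``7.0`` for 07:00.
        Retained (but unused for light state) in DD/LL segments, where it
        serves as the nominal phase reference.
    photoperiod_h:
        Hours of light per day; 0 = DD, 24 = LL.
    lux:
        Free-text intensity label, e.g. ``"150 lux"``, ``"30 lux"``, ``"DD"``.
    """

    start_day: int
    n_days: Optional[int]
    lights_on: float
    photoperiod_h: float
    lux: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.photoperiod_h <= 24.0:
            raise ValidationError(
                f"photoperiod_h must lie in [0, 24], got {self.photoperiod_h}"
            )
        if self.n_days is not None and self.n_days < 1:
            raise ValidationError("segment n_days must be >= 1 or None")

    @property
    def is_ld(self) -> bool:
        return 0.0 < self.photoperiod_h < 24.0

    @property
    def end_day(self) -> Optional[int]:
        """First day *not* covered, or None if open-ended."""
        return None if self.n_days is None else self.start_day + self.n_days


@dataclass(frozen=True)
class Pulse:
    """A discrete light pulse at an absolute time (hours from start)."""

    start_h: float
    duration_min: float
    lux: str = ""

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValidationError("pulse duration must be positive")

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_min / 60.0


@dataclass(frozen=True)
class ShiftEvent:
    """A permanent phase shift of the light cycle from ``day`` onward.

    ``advance_h`` is signed: positive advances the cycle (lights-on and
    lights-off become earlier), negative delays it.
    """

    day: int
    advance_h: float


@dataclass
class LightSchedule:
    segments: list[Segment] = field(default_factory=list)
    pulses: list[Pulse] = field(default_factory=list)
    shifts: list[ShiftEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("schedule needs at least one segment")
        segs = sorted(self.segments, key=lambda s: s.start_day)
        if segs[0].start_day != 0:
            raise ValidationError("first segment must start at day 0")
        for a, b in zip(segs, segs[1:]):
            if a.end_day is None:
                raise ValidationError("only the last segment may be open-ended")
            if a.end_day != b.start_day:
                raise ValidationError(
                    "segments must be contiguous and non-overlapping: "
                    f"day {a.end_day} != day {b.start_day}"
                )
        self.segments = segs

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def ld(
        cls,
        lights_on: float = 7.0,
        photoperiod_h: float = 12.0,
        n_days: Optional[int] = None,
        lux: str = "150 lux",
    ) -> "LightSchedule":
        """A single uniform LD (or DD/LL) schedule."""
        return cls(segments=[Segment(0, n_days, lights_on, photoperiod_h, lux)])

    # ------------------------------------------------------------------ #
    # coverage

    @property
    def end_day(self) -> Optional[int]:
        return self.segments[-1].end_day

    def _check_covered(self, t_h: float) -> None:
        if t_h < 0:
            raise OutOfRangeError(f"t={t_h} h precedes the experiment start")
        end = self.end_day
        if end is not None and t_h >= 24.0 * end:
            raise OutOfRangeError(f"t={t_h} h is beyond day {end}")

    def segment_for_day(self, day: int) -> Segment:
        if day < 0:
            raise OutOfRangeError(f"day {day} precedes the experiment start")
        for seg in self.segments:
            if seg.start_day <= day and (seg.end_day is None or day < seg.end_day):
                return seg
        raise OutOfRangeError(f"day {day} is beyond the schedule")

    # ------------------------------------------------------------------ #
    # phase bookkeeping

    def cumulative_advance_h(self, day: int) -> float:
        """Total signed advance applied to the cycle on ``day``."""
        return sum(s.advance_h for s in self.shifts if s.day <= day)

    def effective_lights_on(self, day: int) -> float:
        """Lights-on time-of-day for ``day``, after any shift events.

        May fall outside [0, 24) after large shifts; callers using absolute
        times (``24*day + value``) remain consistent.
        """
        seg = self.segment_for_day(day)
        return seg.lights_on - self.cumulative_advance_h(day)

    def light_window(self, day: int) -> Optional[tuple[float, float]]:
        """Absolute [start, end) hours of the scheduled light on ``day``.

        Returns None for DD days; the full day for LL days.
        """
        seg = self.segment_for_day(day)
        if seg.photoperiod_h == 0.0:
            return None
        if seg.photoperiod_h == 24.0:
            return (24.0 * day, 24.0 * (day + 1))
        on = 24.0 * day + self.effective_lights_on(day)
        return (on, on + seg.photoperiod_h)

    # ------------------------------------------------------------------ #
    # queries

    def in_pulse(self, t_h: float) -> bool:
        """True if ``t`` falls inside a discrete light pulse."""
        return any(p.start_h <= t_h < p.end_h for p in self.pulses)

    def is_scheduled_light(self, t_h: float) -> bool:
        """True if the segment protocol (ignoring pulses) has lights on."""
        self._check_covered(t_h)
        day = int(t_h // 24.0)
        for d in (day - 1, day, day + 1):
            if d < 0:
                continue
            end = self.end_day
            if end is not None and d >= end:
                continue
            win = self.light_window(d)
            if win is not None and win[0] <= t_h < win[1]:
                return True
        return False

    def is_light(self, t_h: float) -> bool:
        """True iff lights are on at ``t`` (scheduled light or a pulse)."""
        self._check_covered(t_h)
        return self.is_scheduled_light(t_h) or self.in_pulse(t_h)

    def _zt_reference_day(self, t_h: float) -> int:
        """Day whose LD phase defines ZT at ``t`` (possibly projected)."""
        self._check_covered(t_h)
        day = int(t_h // 24.0)
        seg = self.segment_for_day(day)
        if seg.is_ld:
            return day
        # project from the last LD day before this segment
        for d in range(seg.start_day - 1, -1, -1):
            if self.segment_for_day(d).is_ld:
                return d
        raise UndefinedZTError(
            "ZT undefined: constant conditions with no preceding LD segment"
        )

    def zt_of(self, t_h: float) -> float:
        """Zeitgeber Time of ``t`` in hours, in [0, 24); ZT0 = lights-on."""
        ref_day = self._zt_reference_day(t_h)
        on_abs = 24.0 * ref_day + self.effective_lights_on(ref_day)
        return (t_h - on_abs) % 24.0

    def zt_is_projected(self, t_h: float) -> bool:
        """True if ZT at ``t`` is projected from an earlier LD segment."""
        ref_day = self._zt_reference_day(t_h)
        return ref_day != int(t_h // 24.0)

    def lights_off_time(self, day: int) -> float:
        """Absolute hours of lights-off on ``day`` (LD days only)."""
        seg = self.segment_for_day(day)
        if not seg.is_ld:
            raise UndefinedZTError(f"day {day} is {seg.lux or 'DD/LL'}: no lights-off")
        return 24.0 * day + self.effective_lights_on(day) + seg.photoperiod_h

    # ------------------------------------------------------------------ #
    # serialization (bit-exact round trip via plain dicts)

    def to_dict(self) -> dict:
        d: dict = {
            "segments": [
                {
                    "start_day": s.start_day,
                    "n_days": s.n_days,
                    "lights_on": s.lights_on,
                    "photoperiod_h": s.photoperiod_h,
                    "lux": s.lux,
                }
                for s in self.segments
            ]
        }
        if self.pulses:
            d["pulses"] = [
                {"start_h": p.start_h, "duration_min": p.duration_min, "lux": p.lux}
                for p in self.pulses
            ]
        if self.shifts:
            d["shifts"] = [
                {"day": s.day, "advance_h": s.advance_h} for s in self.shifts
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LightSchedule":
        return cls(
            segments=[Segment(**s) for s in d["segments"]],
            pulses=[Pulse(**p) for p in d.get("pulses", [])],
            shifts=[ShiftEvent(**s) for s in d.get("shifts", [])],
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "LightSchedule":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
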
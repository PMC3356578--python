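"""Synthetic wheel-running and 24-h biomarker-profile generator.

The activity model is a descriptive, phenomenological generator — a banded
alternating-renewal process, not a limit-cycle oscillator — so that every
ground-truth parameter maps one-to-one onto the estimator that is supposed
to recover it:

* the nightly activity band starts at an *onset* that sits ``psi_min``
  minutes before lights-off under entrainment (phase angle ψ, positive =
  advanced) with day-to-day Gaussian jitter,
* under constant conditions onsets free-run, drifting ``tau_h − 24`` hours
  per cycle,
* after a schedule phase shift, onsets approach the new steady state
  geometrically: the residual deviation on the d-th day counted from the
  shift is ``shift · (1 − r)^d`` with ``r = reentrain_rate_frac_per_day``,
* inside the band, activity alternates between bouts and gaps with
  exponential durations (fragmentation), and counts per epoch are drawn
  from a Poisson or negative-binomial model (or equal their expectation,
  ``count_model="deterministic"``, for noise-free constructions),
* a ``light_leak_frac`` share of each day's expected counts is relocated
  uniformly into the scheduled light phase (leak relocates, never adds),
* activity during *unscheduled* light (a pulse) is multiplied by
  ``1 − masking_coeff`` (negative masking).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .io_formats import ActivitySeries
from .schedule import LightSchedule

__all__ = [
    "SimulationConfig",
    "ProfileSample",
    "simulate_activity",
    "simulate_cohort",
    "simulate_profile",
    "expected_onsets",
    "wildtype_like",
    "bdr_like",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated animal.

    Units: hours for periods/durations of phase quantities, minutes for
    onset-level quantities, counts per epoch for intensity.
    """

    tau_h: float = 23.8
    psi_min: float = 0.0
    onset_jitter_sd_min: float = 8.0
    active_phase_h: float = 10.0
    counts_per_active_epoch: float = 20.0
    count_model: str = "poisson"  # "poisson" | "negbin" | "deterministic"
    negbin_dispersion: float = 2.0
    bout_mean_min: float = 60.0
    gap_mean_min: float = 0.0  # 0 = unfragmented solid band
    light_leak_frac: float = 0.0
    masking_coeff: float = 0.9
    reentrain_rate_frac_per_day: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 20.0 <= self.tau_h <= 28.0:
            raise ValidationError(f"tau_h must lie in [20, 28], got {self.tau_h}")
        for name in ("light_leak_frac", "masking_coeff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.reentrain_rate_frac_per_day <= 1.0:
            raise ValidationError("reentrain_rate_frac_per_day must lie in (0, 1]")
        if not 0.0 < self.active_phase_h < 24.0:
            raise ValidationError("active_phase_h must lie in (0, 24)")
        for name in (
            "onset_jitter_sd_min",
            "counts_per_active_epoch",
            "bout_mean_min",
            "gap_mean_min",
            "negbin_dispersion",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.count_model not in ("poisson", "negbin", "deterministic"):
            raise ValidationError(f"unknown count_model {self.count_model!r}")
        if self.bout_mean_min <= 0 and self.gap_mean_min > 0:
            raise ValidationError("bout_mean_min must be positive when gaps exist")


@dataclass
class ProfileSample:
    """Sparsely sampled 24-h biomarker profile for one group."""

    group: str
    zt_h: np.ndarray
    values: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.zt_h = np.asarray(self.zt_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (self.zt_h.size == self.values.size == self.replicate.size):
            raise ValidationError("zt_h, values, replicate must align")
        if self.zt_h.size == 0:
            raise ValidationError("profile has no samples")
        if np.any((self.zt_h < 0) | (self.zt_h >= 24)):
            raise ValidationError("zt_h must lie in [0, 24)")


# ---------------------------------------------------------------------- #
# onset ground truth


def _reentrain_deviation_h(schedule: LightSchedule, day: int, rate: float) -> float:
    """Residual onset deviation (hours, toward the old phase) on ``day``."""
    dev = 0.0
    for sh in schedule.shifts:
        if day >= sh.day:
            dev += sh.advance_h * (1.0 - rate) ** (day - sh.day + 1)
    return dev


def expected_onsets(
    config: SimulationConfig, schedule: LightSchedule, n_days: int
) -> np.ndarray:
    """Noiseless onset times (absolute hours), one per day/cycle.

    Under LD the onset for day ``d`` is ``lights_off(d) − ψ`` plus any
    residual re-entrainment deviation; under DD/LL onsets free-run at τ
    from the last entrained onset (or from a nominal lights-off at
    ``lights_on + 12 − ψ`` if the record never had an LD segment).
    """
    psi_h = config.psi_min / 60.0
    onsets = np.empty(n_days)
    anchor_day: Optional[int] = None
    anchor_onset: Optional[float] = None
    for d in range(n_days):
        seg = schedule.segment_for_day(d)
        if seg.is_ld:
            onsets[d] = (
                schedule.lights_off_time(d)
                - psi_h
                + _reentrain_deviation_h(schedule, d, config.reentrain_rate_frac_per_day)
            )
            anchor_day, anchor_onset = d, schedule.lights_off_time(d) - psi_h
        else:
            if anchor_onset is None:
                # nominal phase reference for a record that starts in DD/LL
                anchor_day = d - 1
                anchor_onset = (
                    24.0 * (d - 1) + seg.lights_on + 12.0 - psi_h
                )
            onsets[d] = anchor_onset + config.tau_h * (d - anchor_day)
    return onsets


# ---------------------------------------------------------------------- #
# activity simulation


def _bout_active_mask(
    rng: np.random.Generator,
    band_starts_h: np.ndarray,
    onset_h: float,
    band_h: float,
    bout_mean_min: float,
    gap_mean_min: float,
) -> np.ndarray:
    """Boolean mask over band epochs: inside a bout of the renewal process."""
    if gap_mean_min <= 0:
        return np.ones(band_starts_h.size, dtype=bool)
    edges = [0.0]
    t = 0.0
    while t < band_h:
        t += rng.exponential(bout_mean_min / 60.0)  # bout ends
        edges.append(min(t, band_h))
        t += rng.exponential(gap_mean_min / 60.0)  # gap ends
        edges.append(min(t, band_h))
    rel = band_starts_h - onset_h
    # edges alternate bout-end, gap-end, ...; epoch active if its start lies
    # inside a bout interval [gap_end, bout_end)
    idx = np.searchsorted(np.asarray(edges), rel, side="right")
    return idx % 2 == 1


def simulate_activity(
    config: SimulationConfig,
    schedule: LightSchedule,
    n_days: int,
    epoch_min: float = 10.0,
    subject_id: str = "sim",
    group: str = "",
) -> ActivitySeries:
    """Simulate one animal's activity series; deterministic given the seed."""
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    per_day = 1440.0 / epoch_min
    if abs(per_day - round(per_day)) > 1e-9:
        raise ValidationError("epoch_min must divide 1440")
    per_day = int(round(per_day))
    n_epochs = per_day * n_days
    epoch_h = epoch_min / 60.0
    starts = np.arange(n_epochs) * epoch_h

    rng = np.random.default_rng(config.seed)
    jitter_h = (
        rng.normal(0.0, config.onset_jitter_sd_min / 60.0, size=n_days)
        if config.onset_jitter_sd_min > 0
        else np.zeros(n_days)
    )
    onsets = expected_onsets(config, schedule, n_days) + jitter_h

    lam = np.zeros(n_epochs)
    for onset in onsets:
        band_end = onset + config.active_phase_h
        lo = int(np.floor((onset - starts[0]) / epoch_h + 1e-9))
        hi = int(np.ceil((band_end - starts[0]) / epoch_h - 1e-9))
        lo, hi = max(lo, 0), min(hi, n_epochs)
        if hi <= lo:
            continue
        active = _bout_active_mask(
            rng,
            starts[lo:hi],
            onset,
            config.active_phase_h,
            config.bout_mean_min,
            config.gap_mean_min,
        )
        # edge epochs carry the fraction of the epoch covered by the band,
        # so an off-grid onset is not quantized a whole epoch late
        overlap = (
            np.minimum(starts[lo:hi] + epoch_h, band_end)
            - np.maximum(starts[lo:hi], onset)
        ) / epoch_h
        weight = np.clip(overlap, 0.0, 1.0)
        lam[lo:hi] += np.where(active, config.counts_per_active_epoch * weight, 0.0)

    # relocate a fixed share of each day's expected counts into the light phase
    if config.light_leak_frac > 0:
        light = np.array(
            [schedule.is_scheduled_light(min(t, 24.0 * n_days - 1e-9)) for t in starts]
        )
        day_idx = (starts // 24.0).astype(int)
        for d in range(n_days):
            sel = day_idx == d
            lit = sel & light
            n_lit = int(lit.sum())
            if n_lit == 0:
                continue  # DD day: nothing to relocate into
            e_day = lam[sel].sum()
            lam[sel] *= 1.0 - config.light_leak_frac
            lam[lit] += config.light_leak_frac * e_day / n_lit

    # negative masking during unscheduled light (pulses falling in the dark)
    if config.masking_coeff > 0 and schedule.pulses:
        pulsed = np.array(
            [
                schedule.in_pulse(t) and not schedule.is_scheduled_light(t)
                for t in starts
            ]
        )
        lam[pulsed] *= 1.0 - config.masking_coeff

    if config.count_model == "deterministic":
        counts = lam
    elif config.count_model == "poisson":
        counts = rng.poisson(lam).astype(float)
    else:  # negbin via gamma-Poisson mixture
        theta = config.negbin_dispersion
        shape = np.where(lam > 0, theta, 1.0)
        mean = rng.gamma(shape, lam / shape)
        counts = rng.poisson(mean).astype(float)

    return ActivitySeries(
        counts=counts,
        epoch_min=epoch_min,
        start_h=0.0,
        subject_id=subject_id,
        group=group,
    )


def cohort_seed(base_seed: int, group: str, index: int) -> int:
    """Deterministic per-animal seed derived from the cohort base seed."""
    ss = np.random.SeedSequence(
        entropy=base_seed, spawn_key=(zlib.crc32(group.encode()), index)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    config_control: SimulationConfig,
    config_mutant: SimulationConfig,
    n_per_group: int,
    schedule: LightSchedule,
    n_days: int,
    base_seed: int = 0,
    epoch_min: float = 10.0,
    labels: tuple[str, str] = ("control", "mutant"),
) -> list[ActivitySeries]:
    """Two labelled groups of independent animals with derived seeds."""
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    out: list[ActivitySeries] = []
    for label, cfg in zip(labels, (config_control, config_mutant)):
        for i in range(n_per_group):
            cfg_i = replace(cfg, seed=cohort_seed(base_seed, label, i))
            out.append(
                simulate_activity(
                    cfg_i,
                    schedule,
                    n_days,
                    epoch_min,
                    subject_id=f"{label}_{i:02d}",
                    group=label,
                )
            )
    return out


# ---------------------------------------------------------------------- #
# biomarker profiles


def simulate_profile(
    acrophase_h: float,
    mesor: float,
    amplitude: float,
    sample_zts: list[float],
    n_reps: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
    group: str = "",
) -> ProfileSample:
    """Sinusoidal 24-h profile sampled at sparse ZTs with replicates.

    value = mesor + amplitude·cos(2π(zt − acrophase)/24) + N(0, noise_sd²).
    """
    if amplitude < 0:
        raise ValidationError("amplitude must be >= 0")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if len(sample_zts) == 0:
        raise InsufficientDataError("sample_zts is empty")
    rng = np.random.default_rng(seed)
    zts = np.repeat(np.asarray(sample_zts, dtype=float), n_reps)
    reps = np.tile(np.arange(n_reps), len(sample_zts))
    mean = mesor + amplitude * np.cos(2.0 * np.pi * (zts - acrophase_h) / 24.0)
    vals = mean + (rng.normal(0.0, noise_sd, size=zts.size) if noise_sd > 0 else 0.0)
    return ProfileSample(group=group, zt_h=zts % 24.0, values=vals, replicate=reps)


# ---------------------------------------------------------------------- #
# phenotype presets


def wildtype_like(seed: int = 0) -> SimulationConfig:
    """Consolidated nocturnal phenotype: onset at lights-off, long bouts."""
    return SimulationConfig(
        tau_h=23.8,
        psi_min=0.0,
        onset_jitter_sd_min=8.0,
        active_phase_h=10.0,
        counts_per_active_epoch=20.0,
        count_model="poisson",
        bout_mean_min=60.0,
        gap_mean_min=10.0,
        light_leak_frac=0.02,
        masking_coeff=0.9,
        reentrain_rate_frac_per_day=0.5,
        seed=seed,
    )


def bdr_like(seed: int = 0) -> SimulationConfig:
    """Fragmented, phase-advanced phenotype: advanced onset (ψ ≈ +21.5 min),
    short frequent bouts, substantial light-phase activity leak, same τ."""
    return SimulationConfig(
        tau_h=23.8,
        psi_min=21.54,
        onset_jitter_sd_min=16.0,
        active_phase_h=10.0,
        counts_per_active_epoch=14.0,
        count_model="poisson",
        bout_mean_min=20.0,
        gap_mean_min=20.0,
        light_leak_frac=0.19,
        masking_coeff=0.9,
        reentrain_rate_frac_per_day=0.5,
        seed=seed,
    )
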
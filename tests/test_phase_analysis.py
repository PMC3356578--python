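import dataclasses

import numpy as np
import pytest

import circakit as ck
from circakit.phase_analysis import OnsetSeries


def onset_series(days, minutes):
    return OnsetSeries(days=np.array(days), onset_min=np.array(minutes, float))


class TestDetectOnsets:
    def test_noiseless_recovery_each_day(self, ld_schedule, noiseless_config):
        s = ck.simulate_activity(noiseless_config, ld_schedule, 7)
        on = ck.detect_onsets(s)
        assert len(on) == 7
        # onsets injected at lights-off 19:00
        assert np.allclose(on.onset_min, 19 * 60.0)
        assert on.flagged_days == []

    def test_all_zero_day_flagged(self, ld_schedule, noiseless_config):
        s = ck.simulate_activity(noiseless_config, ld_schedule, 7)
        counts = s.counts.copy()
        day3 = slice(3 * 144, 4 * 144)
        counts[day3] = 0.0
        # also silence the previous night's tail spilling into day 3
        counts[3 * 144 : 3 * 144 + 30] = 0.0
        s2 = ck.ActivitySeries(counts=counts, epoch_min=10.0)
        on = ck.detect_onsets(s2)
        assert 3 in on.flagged_days

    def test_jitter_recovered_within_factor_two(self, ld_schedule):
        cfg = ck.SimulationConfig(
            onset_jitter_sd_min=8.0, gap_mean_min=0.0, seed=21
        )
        s = ck.simulate_activity(cfg, ld_schedule, 14)
        on = ck.detect_onsets(s)
        detected_sd = np.std(on.onset_min, ddof=1)
        assert detected_sd < 2 * 8.0

    def test_empty_series_errors(self):
        with pytest.raises(ck.ValidationError):
            ck.detect_onsets(
                ck.ActivitySeries(counts=np.ones(10), epoch_min=10.0), quiet_h=0
            )


class TestPhaseAngle:
    def test_onset_at_lights_off_gives_zero(self, ld_schedule):
        on = onset_series(range(5), [19 * 60.0] * 5)
        res = ck.phase_angle_entrainment(on, ld_schedule)
        assert res.psi_min == pytest.approx(0.0)

    def test_advanced_onset_positive_twenty(self, ld_schedule):
        on = onset_series(range(5), [18 * 60 + 40.0] * 5)
        res = ck.phase_angle_entrainment(on, ld_schedule)
        assert res.psi_min == pytest.approx(20.0)

    def test_dd_days_error(self, dd_schedule):
        on = onset_series(range(5), [19 * 60.0] * 5)
        with pytest.raises(ck.ValidationError):
            ck.phase_angle_entrainment(on, dd_schedule)

    def test_too_few_onsets_error(self, ld_schedule):
        with pytest.raises(ck.InsufficientDataError):
            ck.phase_angle_entrainment(onset_series([0, 1], [1140, 1140]), ld_schedule)

    def test_translation_equivariance(self, ld_schedule):
        on = onset_series(range(6), [19 * 60.0] * 6)
        shifted = onset_series(range(6), [19 * 60.0 + 25.0] * 6)
        a = ck.phase_angle_entrainment(on, ld_schedule).psi_min
        b = ck.phase_angle_entrainment(shifted, ld_schedule).psi_min
        assert a - b == pytest.approx(25.0)


class TestEstimateTau:
    @pytest.mark.parametrize("tau", [23.0, 25.0, 25.5])
    def test_noiseless_recovery(self, tau, dd_schedule, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, tau_h=tau)
        s = ck.simulate_activity(cfg, dd_schedule, 14)
        res = ck.estimate_tau(ck.detect_onsets(s))
        assert abs(res.tau_h - tau) * 60.0 <= s.epoch_min

    def test_constant_onsets_give_exactly_24(self):
        on = onset_series(range(6), [1140.0] * 6)
        assert ck.estimate_tau(on).tau_h == pytest.approx(24.0)

    def test_periodogram_method_agrees_noiseless(self, dd_schedule, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, tau_h=25.0)
        s = ck.simulate_activity(cfg, dd_schedule, 14)
        on = ck.detect_onsets(s)
        t_reg = ck.estimate_tau(on).tau_h
        t_pg = ck.estimate_tau(on, method="periodogram", series=s).tau_h
        assert abs(t_reg - t_pg) * 60.0 <= s.epoch_min

    def test_too_few_onsets_error(self):
        with pytest.raises(ck.InsufficientDataError):
            ck.estimate_tau(onset_series(range(4), [1140.0] * 4))

    def test_rescaling_counts_leaves_tau_and_psi(self, dd_schedule, ld_schedule,
                                                 noiseless_config):
        cfg = dataclasses.replace(noiseless_config, tau_h=25.0)
        s = ck.simulate_activity(cfg, dd_schedule, 14)
        s2 = ck.ActivitySeries(counts=5.0 * s.counts, epoch_min=s.epoch_min)
        assert ck.estimate_tau(ck.detect_onsets(s)).tau_h == pytest.approx(
            ck.estimate_tau(ck.detect_onsets(s2)).tau_h
        )

    def test_ci_coverage_with_jitter(self, dd_schedule):
        hits = 0
        for r in range(100):
            cfg = ck.SimulationConfig(
                tau_h=23.6, onset_jitter_sd_min=8.0, gap_mean_min=0.0, seed=5000 + r
            )
            s = ck.simulate_activity(cfg, dd_schedule, 14)
            lo, hi = ck.estimate_tau(ck.detect_onsets(s)).ci_95
            hits += lo <= 23.6 <= hi
        assert hits >= 90


class TestPhaseShift:
    def _jetlag_series(self, advance_h=6.0, rate=0.5, n_days=24):
        sched = ck.LightSchedule(
            segments=[ck.Segment(0, None, 7.0, 12.0)],
            shifts=[ck.ShiftEvent(10, advance_h)],
        )
        cfg = ck.SimulationConfig(
            count_model="deterministic",
            onset_jitter_sd_min=0.0,
            gap_mean_min=0.0,
            reentrain_rate_frac_per_day=rate,
        )
        return ck.simulate_activity(cfg, sched, n_days), sched

    def test_six_hour_advance_recovered(self):
        s, _ = self._jetlag_series()
        on = ck.detect_onsets(s)
        shift = ck.phase_shift_magnitude(
            on, 10, pre_window_days=8, post_window_days=6, transient_days=8
        )
        assert shift == pytest.approx(360.0, abs=s.epoch_min)

    def test_sham_is_zero(self, ld_schedule, noiseless_config):
        s = ck.simulate_activity(noiseless_config, ld_schedule, 20)
        on = ck.detect_onsets(s)
        shift = ck.phase_shift_magnitude(on, 10, 7, 7, 3)
        assert abs(shift) <= s.epoch_min

    def test_injected_onset_translation_recovered(self, ld_schedule):
        # +40 min advance injected as a pure onset translation from day 10
        on = onset_series(
            range(20), [1140.0] * 10 + [1100.0] * 10
        )
        shift = ck.phase_shift_magnitude(on, 10, 8, 8, 2)
        assert shift == pytest.approx(40.0, abs=5.0)

    def test_insufficient_days_error(self):
        on = onset_series(range(3), [1140.0] * 3)
        with pytest.raises(ck.InsufficientDataError):
            ck.phase_shift_magnitude(on, 2, 5, 5, 3)


class TestReentrainment:
    def _run(self, rate, criterion=30.0, epoch_min=1.0):
        sched = ck.LightSchedule(
            segments=[ck.Segment(0, None, 7.0, 12.0)],
            shifts=[ck.ShiftEvent(10, 6.0)],
        )
        cfg = ck.SimulationConfig(
            count_model="deterministic",
            onset_jitter_sd_min=0.0,
            gap_mean_min=0.0,
            reentrain_rate_frac_per_day=rate,
        )
        s = ck.simulate_activity(cfg, sched, 24, epoch_min=epoch_min)
        return ck.reentrainment_time(
            ck.detect_onsets(s), sched, criterion_min=criterion
        )

    def test_geometric_decay_four_days(self):
        # 360 · 0.5^d < 30 first at d = 4
        assert self._run(rate=0.5) == 4

    def test_instant_reentrainment_one_day(self):
        assert self._run(rate=1.0) == 1

    def test_zero_shift_zero_days(self):
        sched = ck.LightSchedule(
            segments=[ck.Segment(0, None, 7.0, 12.0)],
            shifts=[ck.ShiftEvent(10, 0.0)],
        )
        cfg = ck.SimulationConfig(
            count_model="deterministic", onset_jitter_sd_min=0.0, gap_mean_min=0.0
        )
        s = ck.simulate_activity(cfg, sched, 20, epoch_min=1.0)
        assert ck.reentrainment_time(ck.detect_onsets(s), sched) == 0

    def test_never_reentrains_sentinel(self):
        sched = ck.LightSchedule(
            segments=[ck.Segment(0, None, 7.0, 12.0)],
            shifts=[ck.ShiftEvent(10, 6.0)],
        )
        # onsets still shifting 10 min/day at the end of the record: the
        # phase never settles within a 5-min criterion
        mins = [1140.0] * 10 + [1140.0 - 10.0 * (d - 9) for d in range(10, 24)]
        on = onset_series(range(24), mins)
        assert (
            ck.reentrainment_time(on, sched, criterion_min=5.0)
            == ck.NOT_REENTRAINED
        )


class TestMaskingIndex:
    def _pulse_setup(self, masking, seed=0, deterministic=False):
        sched = ck.LightSchedule(
            segments=[ck.Segment(0, None, 7.0, 12.0)],
            pulses=[ck.Pulse(5 * 24 + 21.0, 60.0)],
        )
        cfg = ck.SimulationConfig(
            masking_coeff=masking,
            gap_mean_min=0.0,
            onset_jitter_sd_min=0.0,
            count_model="deterministic" if deterministic else "poisson",
            seed=seed,
        )
        return ck.simulate_activity(cfg, sched, 8), sched

    def test_full_suppression_is_100(self):
        s, sched = self._pulse_setup(1.0, deterministic=True)
        assert ck.masking_index(s, sched) == pytest.approx(100.0)

    def test_no_suppression_is_0(self):
        s, sched = self._pulse_setup(0.0, deterministic=True)
        assert ck.masking_index(s, sched) == pytest.approx(0.0, abs=1e-9)

    def test_injected_coefficient_recovered(self):
        vals = [
            ck.masking_index(*self._pulse_setup(0.7, seed=100 + i)) for i in range(20)
        ]
        assert np.mean(vals) == pytest.approx(70.0, abs=10.0)

    def test_zero_baseline_errors(self, ld_schedule):
        sched = ck.LightSchedule(
            segments=[ck.Segment(0, None, 7.0, 12.0)],
            pulses=[ck.Pulse(2 * 24 + 12.0, 30.0)],  # pulse in the rest phase
        )
        cfg = ck.SimulationConfig(
            count_model="deterministic", onset_jitter_sd_min=0.0, gap_mean_min=0.0
        )
        s = ck.simulate_activity(cfg, sched, 5)
        with pytest.raises(ck.ZeroVarianceError):
            ck.masking_index(s, sched)
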
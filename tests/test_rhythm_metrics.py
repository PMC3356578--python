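import dataclasses

import numpy as np
import pytest

import circakit as ck
from circakit.io_formats import ActivitySeries


def series(counts, epoch_min=60.0, **kw):
    return ActivitySeries(counts=np.asarray(counts, float), epoch_min=epoch_min, **kw)


# ---------------------------------------------------------------------- #
# independent brute-force oracles


def is_oracle(x, p):
    """Double-loop interdaily stability on gap-free whole-day data."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    hourly = [np.mean([x[i] for i in range(n) if i % p == h]) for h in range(p)]
    num = n * sum((m - xbar) ** 2 for m in hourly)
    den = p * sum((v - xbar) ** 2 for v in x)
    return num / den


def iv_oracle(x):
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = n * sum((x[i] - x[i - 1]) ** 2 for i in range(1, n))
    den = (n - 1) * sum((v - xbar) ** 2 for v in x)
    return num / den


def qp_oracle(x, k):
    """m · (between-column SS) / (total SS / N), the χ² periodogram statistic."""
    x = np.asarray(x, float)
    m = len(x) // k
    x = x[: m * k]
    n = m * k
    xbar = x.mean()
    cols = x.reshape(m, k)
    between = sum(m * (cols[:, h].mean() - xbar) ** 2 for h in range(k))
    return between / (((x - xbar) ** 2).sum() / n)


def bouts_oracle(counts, epoch_min, thr, min_bout, max_gap):
    """Exhaustive scan: threshold runs, merge short gaps, drop short bouts."""
    above = [c >= thr for c in counts]
    runs = []
    i = 0
    while i < len(counts):
        if above[i]:
            j = i
            while j < len(counts) and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) * epoch_min <= max_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [(a, b) for a, b in merged if (b - a) * epoch_min >= min_bout]


# ---------------------------------------------------------------------- #


class TestLightPhaseActivity:
    def test_nocturnal_noiseless_is_zero(self, ld_schedule, noiseless_config):
        s = ck.simulate_activity(noiseless_config, ld_schedule, 5)
        assert ck.light_phase_activity_pct(s, ld_schedule) == pytest.approx(0.0)

    def test_uniform_activity_is_fifty_percent(self, ld_schedule):
        s = series(np.ones(5 * 144), epoch_min=10.0)
        assert ck.light_phase_activity_pct(s, ld_schedule) == pytest.approx(50.0)

    def test_injected_leak_is_recovered_exactly(self, ld_schedule, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, light_leak_frac=0.19)
        s = ck.simulate_activity(cfg, ld_schedule, 5)
        assert ck.light_phase_activity_pct(s, ld_schedule) == pytest.approx(19.0)

    def test_no_activity_is_error(self, ld_schedule):
        s = series(np.zeros(3 * 144) + 1e-12 * 0, epoch_min=10.0)
        with pytest.raises(ck.ZeroVarianceError):
            ck.light_phase_activity_pct(s, ld_schedule)

    def test_dd_schedule_is_error(self, dd_schedule):
        s = series(np.ones(3 * 144), epoch_min=10.0)
        with pytest.raises(ck.ValidationError):
            ck.light_phase_activity_pct(s, dd_schedule)


class TestInterdailyStability:
    def test_periodic_signal_is_one(self):
        day = np.sin(np.arange(24) * 2 * np.pi / 24) + 2.0
        s = series(np.tile(day, 6))
        assert ck.interdaily_stability(s) == pytest.approx(1.0)

    def test_white_noise_is_small(self, rng):
        s = series(rng.poisson(20, 30 * 24))
        assert ck.interdaily_stability(s) < 0.1

    def test_matches_double_loop_oracle(self, rng):
        # 6 days × 4 bins-per-day fixture
        x = np.array(
            [0, 0, 10, 10, 0, 0, 10, 10, 0, 2, 8, 10,
             1, 0, 9, 11, 0, 1, 10, 9, 2, 0, 12, 8], dtype=float
        )
        s = series(x, epoch_min=360.0)
        assert ck.interdaily_stability(s, bins_per_day=4) == pytest.approx(
            is_oracle(x, 4)
        )

    def test_random_fixture_matches_oracle(self, rng):
        x = rng.poisson(8, 8 * 24).astype(float)
        s = series(x)
        assert ck.interdaily_stability(s) == pytest.approx(is_oracle(x, 24))

    def test_constant_series_errors(self):
        with pytest.raises(ck.ZeroVarianceError):
            ck.interdaily_stability(series(np.ones(48)))

    def test_scale_invariance_and_bounds(self, rng):
        x = rng.poisson(10, 5 * 24).astype(float)
        s1, s2 = series(x), series(7.5 * x)
        v1 = ck.interdaily_stability(s1)
        assert v1 == pytest.approx(ck.interdaily_stability(s2))
        assert 0.0 <= v1 <= 1.0


class TestIntradailyVariability:
    def test_sinusoid_closed_form(self):
        t = np.arange(10 * 24)
        x = 10 + 5 * np.cos(2 * np.pi * t / 24)
        s = series(x)
        v = ck.intradaily_variability(s)
        assert v == pytest.approx(iv_oracle(x))
        assert v == pytest.approx(2 * (1 - np.cos(2 * np.pi / 24)), abs=0.005)

    def test_strict_alternation_is_four(self):
        x = np.tile([0.0, 5.0], 5 * 12)
        assert ck.intradaily_variability(series(x)) == pytest.approx(4.0)

    def test_white_noise_approaches_two(self):
        rng = np.random.default_rng(4320)
        x = rng.poisson(50, 4320)
        assert ck.intradaily_variability(series(x)) == pytest.approx(2.0, abs=0.1)

    def test_matches_oracle_on_random_fixture(self, rng):
        x = rng.poisson(6, 4 * 24).astype(float)
        assert ck.intradaily_variability(series(x)) == pytest.approx(iv_oracle(x))

    def test_shift_invariance(self, rng):
        x = rng.poisson(6, 4 * 24).astype(float)
        assert ck.intradaily_variability(series(x)) == pytest.approx(
            ck.intradaily_variability(series(x + 100.0))
        )


class TestDetectBouts:
    def test_single_block(self):
        x = np.zeros(144)
        x[60:72] = 9  # one 2-h block
        bouts = ck.detect_bouts(series(x, epoch_min=10.0))
        assert len(bouts) == 1
        assert bouts[0].duration_min == pytest.approx(120.0)
        assert bouts[0].total_counts == pytest.approx(9.0 * 12)

    @pytest.mark.parametrize("gap_epochs,expected", [(4, 1), (2, 1), (5, 2)])
    def test_gap_merging_boundary(self, gap_epochs, expected):
        # max_gap 30 min with 10-min epochs merges gaps of ≤3 epochs...
        x = np.zeros(60)
        x[10:16] = 5
        x[16 + gap_epochs : 26 + gap_epochs] = 5
        bouts = ck.detect_bouts(series(x, epoch_min=10.0), max_gap_min=45.0)
        # ...here max_gap 45 min merges gaps of ≤4 epochs
        assert len(bouts) == expected

    def test_matches_exhaustive_oracle(self, rng):
        x = (rng.random(200) < 0.4) * rng.poisson(5, 200)
        s = series(x.astype(float), epoch_min=10.0)
        got = ck.detect_bouts(s, count_threshold=1, min_bout_min=20, max_gap_min=30)
        want = bouts_oracle(x, 10.0, 1, 20, 30)
        assert len(got) == len(want)
        for b, (a, bb) in zip(got, want):
            assert b.start_h == pytest.approx(a * 10 / 60)
            assert b.end_h == pytest.approx(bb * 10 / 60)


class TestBoutsPerDay:
    def test_one_bout_per_day(self):
        day = np.zeros(144)
        day[60:90] = 8  # one consolidated 5-h block per day
        s = series(np.tile(day, 7), epoch_min=10.0)
        assert ck.bouts_per_day(s) == pytest.approx(1.0)

    def test_manual_three_day_fixture(self):
        day = np.zeros(144)
        day[30:42] = 5
        day[80:90] = 4
        x = np.concatenate([day, day, np.zeros(144)])
        x[2 * 144 + 10 : 2 * 144 + 20] = 6
        s = series(x, epoch_min=10.0)
        # days 1–2 have 2 bouts each, day 3 has 1 (gaps > 30 min)
        assert ck.bouts_per_day(s) == pytest.approx((2 + 2 + 1) / 3)

    def test_less_than_a_day_errors(self):
        with pytest.raises(ck.InsufficientDataError):
            ck.bouts_per_day(series(np.ones(100), epoch_min=10.0))


class TestChiSquarePeriodogram:
    def test_square_wave_peak_at_24h(self):
        day = np.zeros(144)
        day[110:] = 20
        s = series(np.tile(day, 10), epoch_min=10.0)
        pg = ck.chi_square_periodogram(s, 20, 28)
        assert pg.peak_period_h == pytest.approx(24.0)
        assert pg.amplitude > 0

    def test_matches_statistic_oracle(self, rng):
        x = rng.poisson(10, 8 * 24).astype(float)
        x[::24] += 30  # seed a 24-h component
        s = series(x)
        pg = ck.chi_square_periodogram(s, 20, 28)
        for period, qp in zip(pg.periods_h, pg.qp):
            assert qp == pytest.approx(qp_oracle(x, int(round(period))))

    @pytest.mark.parametrize("tau", [23.0, 24.0, 25.5])
    def test_peak_recovers_injected_period(self, tau, dd_schedule, ld_schedule,
                                           noiseless_config):
        cfg = dataclasses.replace(noiseless_config, tau_h=tau)
        sched = ld_schedule if tau == 24.0 else dd_schedule
        if tau == 24.0:
            cfg = dataclasses.replace(cfg, tau_h=24.0)
        s = ck.simulate_activity(cfg, sched, 12)
        pg = ck.chi_square_periodogram(s, 20, 28)
        assert abs(pg.peak_period_h - tau) <= s.epoch_h + 1e-9

    def test_fragmented_amplitude_below_consolidated(self, ld_schedule):
        amp = {}
        for name, cfg in (("wt", ck.wildtype_like(3)), ("mut", ck.bdr_like(3))):
            s = ck.simulate_activity(cfg, ld_schedule, 10)
            amp[name] = ck.chi_square_periodogram(s, 20, 28).amplitude
        assert amp["mut"] < amp["wt"]

    def test_zero_variance_errors(self):
        with pytest.raises(ck.ZeroVarianceError):
            ck.chi_square_periodogram(series(np.ones(10 * 24)), 20, 28)

    def test_too_short_series_errors(self):
        with pytest.raises(ck.InsufficientDataError):
            ck.chi_square_periodogram(series(np.arange(30.0)), 20, 28)

    def test_gap_mask_excluded_from_statistic(self, rng):
        x = rng.poisson(10, 6 * 24).astype(float)
        x[::24] += 25
        corrupted = x.copy()
        corrupted[50:55] = 999.0
        mask = np.zeros_like(x, dtype=bool)
        mask[50:55] = True
        pg_masked = ck.chi_square_periodogram(
            ActivitySeries(counts=corrupted, epoch_min=60.0, gap_mask=mask), 22, 26
        )
        # masked statistic should be close to the clean-series statistic
        pg_clean = ck.chi_square_periodogram(series(x), 22, 26)
        i = pg_clean.peak_index
        assert pg_masked.peak_period_h == pg_clean.peak_period_h
        assert pg_masked.qp[i] == pytest.approx(pg_clean.qp[i], rel=0.15)
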
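# circakit

Circadian actigraphy and 24-h-profile analysis for rodent wheel-running
studies, with a synthetic-data generator that makes every estimator
verifiable by parameter recovery.

Mouse models of neuropsychiatric disease are routinely phenotyped by
wheel-running actigraphy: counts per 10-min epoch, recorded for weeks under
light/dark (LD), constant-dark (DD) or constant-light (LL) protocols, with
jet-lag shifts and acute light pulses probing the clock's light input.
Disease models often show a characteristic constellation — activity leaking
into the light phase, fragmented bouts, reduced day-to-day stability, an
advanced phase of entrainment — while the core pacemaker (free-running
period, phase shifting, masking) is spared and downstream outputs such as
SCN neuropeptide and serum hormone rhythms are phase advanced. `circakit`
implements the complete analysis battery needed to characterize such a
phenotype, plus a simulator that injects each effect with known ground truth
so the whole pipeline can be validated without animal data.

## What it computes

For an activity series *x₁…x_N* (counts per epoch, *p* bins per day,
*x̄_h* the across-days mean of bin *h*):

- **Light-phase activity** — 100 · (counts in lit epochs)/(total counts),
  over complete LD days.
- **Interdaily stability** —
  IS = N·Σ_h (x̄_h − x̄)² / (p·Σ_i (x_i − x̄)²) ∈ [0, 1].
- **Intradaily variability** —
  IV = N·Σ_{i≥2} (x_i − x_{i−1})² / ((N−1)·Σ_i (x_i − x̄)²);
  ≈0 smooth, →2 white noise, ≤4 strict alternation.
- **Activity bouts** — threshold runs with gap merging; bouts/day.
- **χ² periodogram** (Sokolove–Bushell) — for a candidate period of K bins
  with m complete cycles, Q_P = m·N·Σ_h (x̄_h − x̄)² / Σ_i (x_i − x̄)²,
  referred to χ²_{K−1}; *amplitude* = Q_P − significance line at the peak.
- **Phase angle of entrainment ψ** — signed minutes from activity onset to
  lights-off (advance positive), from a parameterized onset detector.
- **Free-running period τ** — 24 h + slope of unwrapped onset time vs cycle
  index under DD/LL, with a 95% CI; or the periodogram peak.
- **Phase-shift magnitude and re-entrainment time** after a schedule
  advance; **masking index** (% suppression during a light pulse).
- **Cosinor** fit y = M + A·cos(2π(t − φ)/24) of sparse 24-h biomarker
  profiles (mesor M, amplitude A, acrophase φ, zero-amplitude F test), a
  model-free **peak bin**, and circular group phase differences.

The simulator (`simulate_activity`, `simulate_cohort`, `simulate_profile`)
is a banded renewal-process generator with one knob per estimator: ψ, τ,
onset jitter, bout/gap structure, light-leak fraction, masking coefficient,
geometric re-entrainment rate, Poisson/negative-binomial counts, and
sinusoidal profiles with an injectable acrophase. `wildtype_like()` and
`bdr_like()` presets encode a consolidated versus a fragmented,
phase-advanced phenotype.

## Worked example

```sh
python examples/04_jetlag_and_masking.py
```

prints

```
steady-state phase shift: +5.97 h (advance positive)
re-entrained to within 30 min after 4 days
masking index: 67.9% suppression (injected coefficient 0.7 -> ~70%)
```

A 6-h advance of the LD cycle was injected on day 10 with a re-entrainment
rate of 0.5/day: the onset regression recovers the full +6 h shift, the
residual deviation 360·0.5^d min first drops below the 30-min criterion on
day 4, and a 70% masking coefficient is recovered from the activity
suppressed during a nocturnal light pulse. The other examples
(`examples/01…05`) cover simulation/actograms, the nonparametric metrics,
ψ/τ estimation, and biomarker-profile analysis; each states the numbers it
prints and what they mean.

There is also a thin CLI:

```sh
circakit demo --n 6 --days 10 --seed 0 --out scratch/demo
```

writes per-subject metrics, periodograms, phase estimates, profile fits,
actograms and a group-comparison summary, all embedding the config hash and
seed for exact reproducibility.

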
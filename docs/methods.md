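# Methods

## Time and lighting conventions

All times are timezone-free elapsed hours from experiment start; day *d*
spans [24·d, 24·(d+1)) and lights-on defaults to 07:00 (configurable — real
protocols rarely publish the clock time). A `LightSchedule` is a contiguous
sequence of segments (photoperiod 0 h = DD, 24 h = LL, anything between =
LD), plus discrete light pulses and signed phase-shift events; a shift of
+a h makes lights-on and lights-off *earlier* by a h for every subsequent
day (advance positive, the package-wide sign convention). Zeitgeber Time is
ZT0 = lights-on; under DD/LL it is projected from the phase of the last
preceding LD segment and flagged as projected, because constant-condition
sampling is conventionally reported on the projected ZT axis. An epoch that
straddles a light transition takes the state at its start — deterministic
and consistent with binned data.

## The synthetic generator

The activity model is deliberately phenomenological — a banded
alternating-renewal process, not a limit-cycle oscillator — so each
ground-truth parameter maps one-to-one onto the estimator it validates:

- **Onsets.** Under LD the day-*d* onset is lights-off(d) − ψ plus Gaussian
  day-to-day jitter (`psi_min`, `onset_jitter_sd_min`). Under DD/LL onsets
  free-run from the last entrained onset at τ per cycle, so the drift is
  exactly (τ − 24) h/cycle. A record that starts in constant conditions
  anchors its first onset at a nominal lights-off (segment `lights_on` +
  12 h − ψ). After a schedule shift of magnitude s, the onset's residual
  deviation from the new steady state on the d-th day counted from the
  shift is s·(1 − r)^d (geometric approach at rate
  `reentrain_rate_frac_per_day`); d = 0 labels the last pre-shift day, so a
  null shift re-entrains in 0 days and an instantaneous rate in 1.
- **Band structure.** Activity occupies [onset, onset + `active_phase_h`).
  Inside the band, bouts and gaps alternate with exponential durations
  (`bout_mean_min`, `gap_mean_min`; a zero gap mean encodes a solid,
  unfragmented band). Band-edge epochs carry the fractional overlap of
  epoch and band, so an off-grid onset is not quantized a whole epoch late
  — this keeps noiseless phase estimates unbiased at the epoch scale.
- **Counts.** Per-epoch counts are Poisson or negative-binomial
  (gamma–Poisson, dispersion θ) around the band intensity, or exactly equal
  to it (`count_model="deterministic"`) for noise-free constructions where
  the injected value must be realized exactly.
- **Light leak.** A fraction `light_leak_frac` of each day's expected
  counts is relocated uniformly into that day's scheduled-light epochs —
  relocation, never addition, so the injected fraction is exactly the
  light-phase activity share when ψ = 0 and the expected daily total is
  leak-invariant.
- **Masking.** Epochs falling inside a light pulse (unscheduled light) have
  their intensity multiplied by (1 − `masking_coeff`); a coefficient of 1
  silences the pulse window exactly.
- **Cohorts.** Per-animal seeds derive from the base seed via a
  `SeedSequence` keyed on (CRC32 of group label, index): reproducible,
  independent streams.
- **Profiles.** `simulate_profile` draws
  mesor + amplitude·cos(2π(zt − acrophase)/24) + N(0, σ²) at the requested
  ZTs and replicate count.

What the generator does **not** emulate: ultradian rhythmicity beyond the
bout process, activity-level dependence on light intensity, aftereffects of
entrainment on τ, individual differences in active-phase duration, and
wheel-specific artifacts (coasting counts, wheel jams). Passing recovery
tests therefore shows the estimators are correct for banded, entrained or
free-running count data with these noise sources — not that they are robust
to every pathology of real recordings.

### Preset phenotypes

`wildtype_like`: ψ = 0, jitter 8 min, solid-ish band (bouts 60 min, gaps
10 min), 2% light leak. `bdr_like`: ψ = +21.54 min (advanced), doubled
jitter (16 min), short frequent bouts (20/20 min), 19% light leak, lower
intensity; τ equal in both (23.8 h, a typical mouse value) because the
phenotype being modelled spares the free-running period. Quantitative
fragmentation parameters for the mutant-like preset are directional choices
— the published record gives directions, not bout-length distributions.

## Estimators and numerical choices

- **IS/IV** use the standard actigraphy formulas on 1-h rebinned whole days
  (`bins_per_day` exposed; conventions differ). Gap-masked epochs are
  excluded from every sum and denominator, since silent zero-fill biases
  both statistics. A constant series raises a zero-variance error rather
  than returning 0/0.
- **χ² periodogram.** For each candidate period (grid step = one epoch)
  only the largest whole number of complete cycles is used (the truncation
  convention, avoiding partial-cycle bias). The statistic is
  Q_P = m·N·Σ_h(x̄_h − x̄)²/Σ_i(x_i − x̄)² (m complete cycles of K bins,
  N = mK), i.e. the between-column sum of squares over the ML variance,
  which is χ²_{K−1} under the i.i.d. null — verified by Monte-Carlo
  calibration in the tests (60-day series give m large enough for the
  asymptotic to hold at the ±2·SE level over 1000 replicates).
  "Amplitude" is Q_P minus the (1 − α) χ² quantile at the peak, the
  convention of widespread commercial actigraphy software; it is not
  universal, so α and the definition are surfaced in the result object.
- **Bout detection** is a threshold-run scan with gap merging (defaults:
  1 count per 10-min epoch, 30-min max gap, 10-min minimum bout), all
  parameterized because no published rule is canonical. Note that with a
  thin uniform light leak the default 1-count threshold counts isolated
  leak epochs as micro-bouts; bout comparisons are therefore meaningful
  between configurations differing in band structure, not in leak.
- **Onset detector.** An onset is the first epoch that (a) itself exceeds
  the threshold, (b) follows a `quiet_h` = 4 h window whose mean is below
  it, and (c) precedes an `active_h` = 1 h window whose mean is above it;
  the threshold is `frac_threshold` = 0.5 × the series' mean nonzero epoch
  count (nonzero-mean, because the rest phase is mostly zeros). After an
  accepted onset the search skips 16 h, which follows drifting onsets
  across calendar-day boundaries for any τ in (20, 28). Days without a
  qualifying epoch are flagged, never fabricated.
- **τ regression** unwraps onsets against *cycle index* — the nearest
  integer to the separation of successive onsets over 24 h — rather than
  calendar day: regressing time-of-day on calendar date biases τ̂ by 24/τ
  whenever onsets drift across midnight. τ = 24 h + slope; the 95% CI is
  the t-based slope CI. At least 5 onsets are required.
- **Phase-shift magnitude** fits separate onset-vs-day lines to a pre-shift
  window and a post-shift window (after discarding transient days) and
  differences them at the event day, pre − post, so an advance (earlier
  onsets) is positive.
- **Re-entrainment time** measures each day's phase angle against the
  *post-shift* cycle, estimates the new steady state from the last third of
  post-shift days, and returns the first day (counted from the shift,
  pre-shift day = 0) from which the deviation stays below the criterion for
  3 consecutive days; a record that ends first returns a sentinel.
- **Masking index** is 100·(1 − A_pulse/Ā_baseline) over the pulse's
  clock-time window, baseline defaulting to all other complete days;
  clipped at 100, negative values = positive masking.
- **Cosinor** is the exact linear least-squares solution of
  y = M + β cos ωt + γ sin ωt (ω = 2π/P, P fixed, default 24 h), with
  A = √(β² + γ²), φ = (P/2π)·atan2(γ, β) mod P, and a 2-df F test of
  β = γ = 0. A constant profile yields amplitude 0 with the acrophase
  flagged undefined. `peak_bin` is the across-replicate-mean argmax with
  ties resolved to the earliest ZT and flagged. Replicates are treated as
  independent cross-sectional observations (the sampling designs emulated
  here are n = 3–5 per ZT, cross-sectional). Group phase differences are
  wrapped to (−P/2, P/2] with a 1e-9 h epsilon so exact antiphase reports
  +P/2.
- **Group comparisons** are Welch's t by default; "anova_planned" is the
  pooled-variance t test, identical to the planned pairwise contrast of a
  one-way ANOVA for two groups. The pipeline summary reports raw p-values
  per metric, with Holm correction available behind a flag.

## Problem sizes

Simulated validation uses 7–24-day records at 10-min epochs (1-min epochs
where sub-epoch resolution matters, e.g. re-entrainment-day counting),
cohorts of 5–12 per group, 100-replicate CI-coverage checks, 20-replicate
masking recovery, and a 1000-replicate periodogram null calibration — sizes
chosen to match the emulated study designs while keeping each check
statistically decisive.

## Known limitations

- The onset detector is a single-template heuristic; heavily arrhythmic
  records (no consolidated quiet phase) yield flagged days rather than
  onsets, and ψ/τ estimates then fail loudly with insufficient-data errors.
- Cycle-index unwrapping assumes at most occasional missed onsets; a
  detector miss rate above ~⅓ can misnumber cycles for extreme τ.
- The periodogram significance line treats epochs as exchangeable under the
  null; autocorrelated noise (common in real wheel data) inflates the
  false-positive rate, as it does for every χ² periodogram.
- ZT projection under DD/LL uses the last LD phase without correcting for
  free-running drift accumulated since release.
- The AWD reader covers the common single-column Actiwatch text layout
  only; calendar dates are discarded in favour of the elapsed-time
  convention.
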
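"""Simulate a wild-type-like and a mutant-like animal and render actograms.

The simulator injects known ground truth: the mutant-like preset has an
activity onset advanced ~21.5 min before lights-off, 19% of its daily counts
leaking into the light phase, and short fragmented activity bouts.
"""

from pathlib import Path

import circakit as ck

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

schedule = ck.LightSchedule.ld(lights_on=7.0, photoperiod_h=12.0, lux="150 lux")

for preset in (ck.wildtype_like(seed=1), ck.bdr_like(seed=1)):
    label = "wildtype_like" if preset.psi_min == 0 else "bdr_like"
    series = ck.simulate_activity(preset, schedule, n_days=14, epoch_min=10.0,
                                  subject_id=label, group=label)
    path = ck.render_actogram(series, schedule, out / f"actogram_{label}.png")
    pct = ck.light_phase_activity_pct(series, schedule)
    print(f"{label}: {len(series)} epochs, "
          f"{pct:.1f}% of counts in the light phase -> {path}")

# Expected output (seeded): the wild-type-like animal emits ~2% of its
# activity in the light; the mutant-like animal ~20%+ (the injected 19% leak
# plus a little extra because its advanced onset starts before lights-off).
# The two PNG actograms show a consolidated versus a fragmented nocturnal band.
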
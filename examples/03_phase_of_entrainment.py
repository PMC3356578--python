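"""Phase angle of entrainment (psi) and free-running period (tau).

psi is the signed interval from activity onset to lights-off (positive =
onset earlier, i.e. phase advanced).  tau is estimated in constant darkness
from the drift of onsets across cycles.
"""

import numpy as np

import circakit as ck

ld = ck.LightSchedule.ld()
psis = {}
for label, cfg in (("wildtype_like", ck.wildtype_like()),
                   ("bdr_like", ck.bdr_like())):
    vals = []
    for i in range(8):
        cfg_i = type(cfg)(**{**cfg.__dict__, "seed": ck.cohort_seed(0, label, i)})
        s = ck.simulate_activity(cfg_i, ld, 14)
        onsets = ck.detect_onsets(s)
        vals.append(ck.phase_angle_entrainment(onsets, ld).psi_min)
    psis[label] = vals
    print(f"{label}: psi = {np.mean(vals):+.1f} +/- {np.std(vals, ddof=1):.1f} min")

cmp = ck.compare_groups(psis["bdr_like"], psis["wildtype_like"], design="t")
print(f"group difference: {cmp.estimate:+.1f} min (p = {cmp.p_value:.4f})")

dd = ck.LightSchedule.ld(photoperiod_h=0.0, lux="DD")
cfg = ck.SimulationConfig(tau_h=23.8, onset_jitter_sd_min=8.0, gap_mean_min=0.0, seed=4)
s = ck.simulate_activity(cfg, dd, 14)
tau = ck.estimate_tau(ck.detect_onsets(s))
print(f"DD free run: tau = {tau.tau_h:.2f} h, 95% CI {tau.ci_95[0]:.2f}-{tau.ci_95[1]:.2f}")

# The mutant-like onsets are advanced (psi > 0, injected +21.5 min) and far
# more variable day to day, while wild-type-like onsets track lights-off; the
# small-n group difference is positive and significant.  In constant darkness
# the injected tau of 23.8 h is recovered from the onset drift.
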
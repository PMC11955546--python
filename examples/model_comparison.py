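"""Why high temporal resolution matters: AATH vs S1TC by corrected AIC.

Frame-averages a noisy AATH-generated tissue curve to coarser intervals and
fits both the distributed (AATH, 5 parameters) and the standard one-tissue
compartment (S1TC, 4 parameters) model at each framing.  delta-AIC =
AIC(AATH) - AIC(S1TC): negative favours AATH.  Noise is drawn at the
residual level of measured regional curves, so the comparison mirrors fits
of real data.
"""

import numpy as np

import htrpet as hp
from htrpet.core import TimeSeriesCurve

schedule = hp.FrameSchedule.default_htr()
aif = hp.generate_aif(hp.AIFConfig(), schedule)
truth = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
clean = hp.generate_aath_tac(truth, aif, schedule)

noise = hp.NoiseModel(sc=4.8, isotope="18F", seed=0, convention="residual")
spec = hp.GridSpec(td_step=1.0, tc_step=1.0, n_k2=40)

rows = []
for row in hp.add_noise(clean, noise, 8):
    tac = TimeSeriesCurve(schedule, row, noisy=True)
    rows.append(hp.compare_models(tac, aif, spec, [1.0, 2.0, 5.0, 10.0]).set_index("interval_s")["delta_aic"])

mean = np.mean(np.vstack([r.to_numpy() for r in rows]), axis=0)
print("frame interval (s)   mean delta-AIC (AATH - S1TC) over 8 noise realizations")
for interval, d in zip([1.0, 2.0, 5.0, 10.0], mean):
    verdict = "AATH preferred" if d < 0 else "S1TC preferred"
    print(f"{interval:>14.0f}      {d:+8.1f}   {verdict}")
print()
print("At native 1-s framing the vascular transit phase is visible and the")
print("distributed model earns its extra parameter; as frame averaging")
print("erases the phase the simpler compartment model takes over.")
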
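"""Practical identifiability of AATH parameter estimates.

Adds independent time-varying count-noise realizations to a known tissue
curve and refits each one, summarizing the relative estimation error of
every parameter.  Bias is the mean error (% of the true value), SD the
spread; small values mean the single-scan joint CBF/K1 estimation is
reliable at that kinetic regime.  Uses 128 realizations here for speed —
the full protocol uses 1024 (see scripts/acceptance.py).
"""

import htrpet as hp
from htrpet.simulation import tracer_representative_params

schedule = hp.FrameSchedule.default_htr()
aif = hp.generate_aif(hp.AIFConfig(), schedule)
spec = hp.GridSpec.voxel()
basis = hp.precompute_bases(spec, aif, schedule, "aath")

for name, (params, isotope) in tracer_representative_params(spec).items():
    noise = hp.NoiseModel(sc=4.8, isotope=isotope, seed=1)
    rep = hp.run_identifiability(params, aif, spec, noise, n_realizations=128, basis=basis)
    print(f"--- {name} (E = {params.extraction:.2f}, {isotope}) ---")
    print(rep.to_frame().round(2))
    if rep.ps_indeterminate_count:
        print(f"PS indeterminate (E = 1) in {rep.ps_indeterminate_count}/128 realizations")
    print()

print("PS/K1/E/CBF errors stay within a few percent at low-to-moderate")
print("extraction; at near-complete extraction (E ~ 1) PS degenerates while")
print("K1, E and CBF remain well determined.")
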
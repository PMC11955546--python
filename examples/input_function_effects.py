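"""Input-function effects: dispersion and plasma metabolites.

Two studies of how arterial-input fidelity affects parameter recovery:

1. Dispersion — convolving the input with a mono-exponential kernel
   (kd = 30, 10, 5 per minute) emulates progressively slower injections;
   identifiability of CBF degrades as the bolus smears.
2. Metabolites — tissue curves generated with a metabolite-corrected
   (parent-fraction) plasma input but fitted with the uncorrected one show
   a small systematic overestimate of PS/K1/E.

Reduced realization counts keep this demo quick.
"""

import htrpet as hp

schedule = hp.FrameSchedule.default_htr()
aif = hp.generate_aif(hp.AIFConfig(), schedule)
spec = hp.GridSpec(td_step=0.5, tc_step=0.5, n_k2=60)
truth = hp.AATHParams(cbf=0.5, k1=0.165, k2=0.33, tc=7.0, td=2.0)
noise = hp.NoiseModel(sc=4.8, isotope="18F", seed=5)

print("== dispersion study (slower injections) ==")
reps = hp.run_dispersion_study(truth, aif, spec, noise, kd_levels=(30.0, 10.0, 5.0), n_realizations=64)
print(f"{'kd (1/min)':>10} {'CBF bias%':>10} {'CBF sd%':>8} {'PS bias%':>9} {'PS sd%':>7}")
for kd, rep in reps.items():
    print(
        f"{kd:>10.0f} {rep.bias_pct['cbf']:>10.2f} {rep.sd_pct['cbf']:>8.2f}"
        f" {rep.bias_pct['ps']:>9.2f} {rep.sd_pct['ps']:>7.2f}"
    )
print("smaller kd = heavier dispersion; CBF suffers most as the sharp first")
print("pass is lost.\n")

print("== metabolite study (parent fraction ~0.80 at 2 min) ==")
arms = hp.run_metabolite_study(truth, aif, spec, noise, n_realizations=64)
for arm, rep in arms.items():
    print(f"{arm:>12}: PS bias {rep.bias_pct['ps']:+.2f}%  K1 bias {rep.bias_pct['k1']:+.2f}%")
print("ignoring metabolites shifts PS/K1 systematically upward; the free k2")
print("absorbs most of the input mismatch, so the shift stays small.")
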
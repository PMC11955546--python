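# Methods

## Kinetic models

The adiabatic approximation to the tissue-homogeneity (AATH) model treats a
voxel as a spatially distributed intravascular space in series with a
well-mixed extravascular compartment. Its impulse response is piecewise
closed-form: a vascular phase of height CBF lasting the mean vascular
transit time T_c (the time for tracer to traverse the voxel's entire
intravascular volume — arteries through veins), then a tissue phase
K₁·exp(−k₂(t−T_c)) describing washout of the extracted fraction. The
boundary t = T_c belongs to the tissue phase. For an arterial input the
tissue curve expands into two cumulative whole-blood integrals (the
intravascular component, linear in CBF) plus an exponential convolution of
the parent plasma input (the extravascular component, linear in K₁); each
integral is zero before its lower limit, and a delay t_d shifts the input
to account for aorta-to-tissue arrival time. The standard one-tissue
compartment model (S1TC) is the T_c → 0 limit with CBF = v_b/T_c: a
v_b-weighted delta plus K₁·exp(−k₂t). Quantities derived from an AATH fit:
E = K₁/CBF, PS = −CBF·ln(1−E) (indeterminate at E = 1), v_b = CBF·T_c,
V_e = K₁/k₂.

Unit conventions: rates are per minute (ml/min/cm³ of *voxel* volume for
CBF/K₁/PS, min⁻¹ for k₂); times are seconds; activity is kBq/ml and assumed
decay-corrected. Internally everything runs in seconds; conversion happens
at the API boundary. Frame values are treated as frame averages on input;
model curves are evaluated at frame mid-times t_m (a frame-average option
exists for simulation realism). The whole-blood = plasma assumption (valid
early in a scan for tracers without fast metabolites) is the default; a
parent-fraction model multiplies plasma only, in the extravascular term.

## Estimation

Fitting minimizes Σ w_m (Q(t_m) − Q̂(t_m))² with w_m = 1 by default. The
nonlinear parameters are searched exhaustively: t_d ∈ [0, 16] s and
T_c ∈ [3, 16] s at 0.25 s steps (0.5 s for voxel-wise work), 100
log-spaced k₂ ∈ [0.006, 3] min⁻¹ — 344,500 nodes regionally, 89,100 at
voxel resolution, endpoints included, deterministic order (t_d outer, T_c,
k₂ inner; wrss ties resolve to the first node). At each node the model is
linear in (CBF, K₁), so the inner problem is solved in closed form: the
2×2 normal equations, with boundary candidates (K₁ = 0; CBF = 0; for AATH
also the E = 1 edge K₁ = CBF, since the physical model requires E ≤ 1)
evaluated wherever the unconstrained optimum is infeasible, keeping the
lowest-wrss feasible solution. This is the exact solution of the
inequality-constrained least squares, vectorized over all nodes.

Basis curves are a pure function of (node, input, schedule): the vascular
basis depends only on (t_d, T_c) and is stored per pair; the tissue basis
needs one exponential convolution per k₂ on the fine grid, sampled at
shifted mid-times. One basis cache serves every TAC, noise realization and
voxel against the same input — this is what makes 1024-realization studies
and volume mapping tractable on one CPU.

Numerics: curves are generated on a uniform fine grid (default 0.05 s; a
0.025 s run changes curves by < 0.2%). Fractional shifts use linear
interpolation with the input zero before t = 0. The exponential
convolution uses the integrator that is exact for piecewise-linear inputs,
so it remains accurate for arbitrarily fast kernels (dispersion rates).
Model selection uses the small-sample corrected AIC,
M·ln(wrss/M) + 2n + 2n(n+1)/(M−n−1), n = 5 (AATH) or 4 (S1TC); a perfect
fit maps to −∞ and M ≤ n+1 is a domain error. Frame rebinning merges only
whole frames (greedily, when the target interval would split a native
frame) and preserves the time integral exactly.

## Synthetic data

The input generator emulates a rapid 1–2 s hand bolus imaged in the
ascending aorta at 1-s frames. Indicator dilution pins the first-pass area
at injected dose / cardiac output (≈3700 kBq·s/ml for 370 MBq at
6 l/min); cardiopulmonary transit disperses the bolus to ≈6 s FWHM, giving
the default gamma-variate (peak ≈550 kBq/ml at 15 s, shape 35) plus a
delayed, exponentially dispersed recirculation shoulder (15% at +25 s) and
a 5% tail. Defaults were fixed from these physiological considerations
once; they are not fitted to data.

Noise is additive Gaussian with the count-statistics profile
σ_m = Sc·√(max(Q(t_m), ε)·e^{λt_m}/Δt_m) for activity in Bq/ml, ε = 1% of
the curve peak, λ the isotope decay constant (noise inflates late in the
scan because decay correction amplifies thinning counts; ¹⁸F λ = ln2/6586.2
s⁻¹, ¹¹C λ = ln2/1221.8 s⁻¹) and Sc = 4.8 dimensionless — about 0.5–0.8
kBq/ml per 1-s frame on a ~30 kBq/ml tissue curve, consistent with the
residual level of regional fits of measured data. An alternative
`'residual'` convention normalizes the same profile so its RMS equals Sc in
kBq/ml (≈4.8 kBq/ml typical); it emulates *measured* regional curves, whose
residuals include model misfit beyond pure counting noise, and is the
appropriate generator for the AIC model-comparison study (which in practice
is run on measured data). The choice matters: under count-level noise the
generating AATH model keeps winning the AIC comparison at any framing,
while under residual-level noise the preference flips to the simpler model
at 5–10 s intervals, reproducing the behaviour seen on real data. Seeds
are explicit; realization i uses seed + i, so studies are chunkable and
bit-reproducible.

The parent-fraction default is a Hill curve 1 − a·t³/(c³+t³) calibrated
once so that 80% of parent tracer remains at 2 min, with the cubic giving
the characteristic metabolism lag. Dispersion uses the unit-area kernel
k_d·e^{−k_d t} (study levels 30, 10, 5 min⁻¹). The digital phantom fills
concentric/blockwise regions (grey-matter shell, white-matter core,
cerebellum block, aorta tube carrying the input) with model curves plus
per-voxel noise.

What the generator does *not* emulate: reconstruction correlations between
voxels, scanner point-spread blurring, motion, attenuation/scatter residual
artifacts, and subject-specific input-function shapes. Passing tests
therefore demonstrate correctness of the estimator under the stated model
and realistic SNR, not robustness to all real-data failure modes.

## Identifiability and sensitivity studies

For a true parameter set the identifiability study generates the noiseless
curve, adds n (default 1024) independent noise realizations, refits each
against the cached bases, and reports mean and SD of the relative error of
CBF, K₁, k₂, T_c, t_d, E, PS and v_b, plus the Pearson correlation matrix
of the estimates. At near-complete extraction some realizations hit E = 1,
where PS is indeterminate; PS statistics are then conditional on the
determinate realizations with the indeterminate count reported — mirroring
the practice of not quantifying PS for freely diffusible tracers. Sweep
helpers cover E × T_c × CBF grids (t_d fixed at 2 s, k₂ = K₁/V_e with
V_e ∈ [0.25, 1] ml/cm³) and the fixed-PS experiment (PS = 0.15 ml/min/cm³,
t_d = 2 s, T_c = 5 s, k₂ = 0.25 min⁻¹ while CBF varies over 0.25/0.5/0.75).

Sensitivity analysis computes normalized sensitivities
Ŝ_k(t) = (∂Q/Q)/(∂θ_k/θ_k) by central differences with ±2.5% parameter
changes (the K₁ step is clipped at the E = 1 boundary, giving a one-sided
difference there), integrates pairwise products over the scan by the
trapezoid rule, and reports the normalized inverse of that matrix as the
parameter correlation matrix (Moore-Penrose pseudo-inverse, flagged, when
the condition number exceeds 10¹²).

## Voxel-wise mapping

Voxel fitting reuses one basis cache (0.5 s grid by default) across all
voxels inside the brain mask; all-zero voxels are flagged invalid. E ≤ 1
is enforced by the constrained solve, and PS maps clip E at 99.9% before
the Renkin-Crone inversion so freely diffusible voxels stay finite (clipped
voxels are flagged). Optional Gaussian smoothing of the dynamic image
stands in for kernel/nonlocal-means denoising, which depends on full-study
priors outside this package's scope. Voxels dominated by pure vasculature
pin T_c/t_d at grid bounds and are left flagged, not special-cased. Maps
are written one NIfTI per parameter with a JSON sidecar recording grid,
units and clip settings.

## Michaelis-Menten transporter kinetics

PS of a glucose-competitive tracer follows
PS = V_max/(K_m + (K_m/K_m,glc)·[Glc]) + K_d with K_d fixed at 0.022
ml/min/cm³ (clinical glucose ranges cannot identify it). Note the gauge
freedom: a common rescaling of (V_max, K_m, K_m/K_m,glc) leaves the model
invariant, so only V_max/K_m (zero-glucose saturable transport) and
K_m,glc are structurally identifiable. The fit uses Levenberg-Marquardt on
the raw parameters from the standard initializer (1.0, 5.0, 1.0), which
pins the reported scale near the initializer as in the reference
procedure; recovery tests assert the identifiable combinations. Glucose
converts as mg/dl ÷ 18.0182 → mmol/l.

## Problem sizes and defaults used in checks

The shipped test suite and acceptance script run the full 1024-realization
identifiability protocol on the 89,100-node voxel grid (about two minutes
on one CPU thanks to basis caching); model-comparison and sweep checks use
coarsened grids (1 s steps, 40 k₂) and 24–128 realizations, sizes at which
the qualitative conclusions are stable across seeds. Phantom demos use
16–32 voxel grids rather than full scanner matrices.

## Known limitations

- Two-tissue-compartment extensions, model-independent deconvolution and
  one-barrier distributed models are out of scope.
- The estimator's T_c lower bound (3 s) truncates the estimate
  distribution when the true T_c is near 3 s, producing a small negative
  CBF bias there.
- S1TC fits of nearly pure blood curves can push v_b toward 1; values
  above 1 violate the container invariant and surface as errors rather
  than being clipped.
- The AIC comparison on synthetic AATH data depends on the noise
  convention (see above); only the residual-level convention reproduces
  the coarse-framing preference for the simpler model.
- PS is not quantifiable at E ≈ 1; report K₁ and CBF there instead.
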
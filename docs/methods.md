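# Methods

## Models

**Two-tissue compartment model.** Tissue kinetics follow the standard
reversible 2TCM: free/non-specific compartment C1 exchanging with plasma
(K1, k2) and with a specifically bound compartment C2 (k3, k4). The
forward solution uses the analytic bi-exponential impulse response with
eigenvalues `a1,2 = ((k2+k3+k4) ∓ sqrt((k2+k3+k4)^2 - 4 k2 k4))/2`. The
repeated-root case (a1 = a2) lies on a measure-zero parameter set; it is
handled by nudging k4 by one part in 10^9, far below fit tolerance,
rather than with a dedicated limit formula. The measured frame value is
the time-average over the frame of `(1 - vB) C_T + vB C_WB`, with both
blood curves shifted later by the fitted delay (positive delay = blood
later than tissue; plasma and whole blood are shifted jointly, since the
data do not separate their delays).

**Convolution numerics.** All convolutions are computed on a uniform
dense grid as the *exact* convolution of a piecewise-linear input with a
decaying exponential, evaluated by an order-1 recurrence (implemented as
an IIR filter, O(n)). The 2TCM grid step is 1 s, which contains every
kink of the 1-s-sampled plasma curve, so the only error against an
ODE-integration oracle is the frame-averaging quadrature (< 0.1% of the
curve maximum in the acceptance checks). Reference models use a step of
1/96 min (0.625 s) because the piecewise-linear reference curve has its
kinks at frame midpoints (multiples of 0.125 min on quarter-minute
schedules); with kinks on grid nodes the convolution is exact for it.

**SRTM / SRTMv.** SRTM uses the operational equation with `k2a =
k2/(1+bp)`. Because the reference curve is only known at frame midpoints,
reference-model outputs are evaluated at frame midpoints rather than
frame-averaged; this also makes the R1 = 1, bp = 0 identity hold exactly
and keeps the fitted model consistent with how the reference TAC itself
was sampled. When the reference carries specific binding (cerebellum,
SVCA4 grey matter), the fitted bp is a pseudo binding potential and may
legitimately be negative; the lower bound is bp > -1. SRTMv corrects
both target and reference for vascular signal,
`C_ref,corr = (C_obs,R - vB_r C_b)/(1 - vB_r)`, with vB_t and vB_r fitted
jointly (vB_r can be fixed instead). With an all-zero blood curve the vB
terms only rescale the reference — a non-identifiable family — so the
fit falls back to plain SRTM with a warning. The image-derived blood
curve averages the full TACs of the 10 voxels with the highest
time-weighted mean activity over [0, 1] min (fractional-overlap weights
for a frame straddling t = 1 min; ties broken by voxel index and
flagged).

**Fitting.** Weighted nonlinear least squares with deterministic
multistart: starts are drawn log-uniformly within bounds for rate-like
parameters and uniformly for vB/delay/bp, screened on raw cost, and the
best few are polished with a bounded trust-region solver. Defaults:
bounds K1, k2, k3, k4 ∈ [1e-4, 2] min⁻¹ (physiologic), vB ∈ [0, 0.2],
delay ∈ [-1, 1] min, R1 ∈ [0.01, 10], bp ∈ [-0.99, 10]; 100 starts.
Weights default to `duration × e^{-λ·midpoint}` with λ = ln2/20.4 min⁻¹
(carbon-11), the count-proportional convention. The study pipeline uses
30 starts / 3 refinements for 2TCM and 100/8 for the reference models,
whose cost surface on noisy low-binding data is multimodal (near
pseudo-bp ≈ 0 the SRTM parameters become collinear; occasional fits end
on a bound and are flagged rather than suppressed — that instability is
itself a finding about these outcome measures).

**SVCA.** Voxel TACs are normalised to unit area (`Σ value·duration = 1`)
before NNLS decomposition onto unit-area class curves; the normalisation
is this package's stated convention (it makes weights scale-invariant)
since the upstream literature does not print one. The least-squares
objective weights frames by duration. Weights are rescaled to sum 1 per
voxel; voxels with non-positive activity or an all-zero solution get
zero rows and a flag. SVCA4 restricts a 6-class set to the four brain
classes inside the brain mask. Reference averaging uses the low-binding
GM weights as averaging coefficients over the voxels' *raw* TACs
(threshold 0 by default; configurable). Smoothing is a per-frame 3D
Gaussian, σ = FWHM/(2√(2 ln 2)) scaled per axis by voxel size, applied
before decomposition and skipped (with a warning) for datasets without
grid geometry.

## Reliability statistics

ICC is the one-way random-effects single-measure estimator
`(MSB - MSW)/(MSB + MSW)` for two sessions; negative estimates are
reported as-is. This variant was chosen because it is the one consistent
with published TSPO test-retest tables that print negative ICCs together
with `SEM = SD·sqrt(1 - ICC)` (a negative ICC then correctly yields
SEM > SD). AbsVar% divides the absolute test-retest difference by the
absolute pair mean (pairs with zero mean are excluded with a flag); the
absolute value matters for near-zero pseudo-bp outcomes. Summary means
and SDs pool all 2n subject-session values. MD uses the two-measurement
95% factor 1.96·√2. Validity matrices pool subject × session × region
points and report Pearson r and R².

The published-table checks in `pkquant.checks` recompute medians exactly
and check every SEM/MD% cell for *interval consistency*: since the
published inputs are rounded, the printed cell must lie within the range
of the formula over the half-ULP rounding intervals of its inputs, ± half
a ULP of the cell itself. Point recomputation would falsely flag rows
whose authors used unrounded intermediates.

## Synthetic data

The generator emulates the study design the statistics target: 6
subjects × 2 sessions, 63-min scans on a 24-frame schedule (4×0.25,
4×0.5, 4×1, 4×2, 4×4, 4×8 min — a configurable stand-in, since
acquisition schedules vary), 5 target regions plus cerebellum, and
TSPO-like kinetics with low specific binding everywhere including the
pseudo-reference regions.

* Plasma input: Feng-type `(A1 τ - A2 - A3)e^{l1 τ} + A2 e^{l2 τ} +
  A3 e^{l3 τ}` with defaults (A1 = 300 kBq/mL/min, A2 = 10, A3 = 8
  kBq/mL, l = -4, -0.5, -0.008 min⁻¹, t0 = 0.5 min) giving a ~38 kBq/mL
  peak near 1.3 min; with the l-ordering constraint the curve is provably
  nonnegative. Whole blood defaults to plasma × 1.0 (profile
  configurable).
* Population: log-normal parameter variation (positivity), defaults
  K1 = 0.10 mL·cm⁻³·min⁻¹, k2 = 0.375, k3 = 0.05, k4 = 0.03 min⁻¹,
  vB = 0.05 — i.e. V_T ≈ 0.71, V_S ≈ 0.44, BP_ND ≈ 1.67, the magnitude
  range a low-binding TSPO tracer shows. Between-subject log-SD 0.20;
  session effect multiplies K1 and k3 (delivery and binding channels)
  with log-SD 0.13; session-level blood-amplitude, delay and dose
  variation are separate channels so the "no within-session variance ⇒
  ICC = 1" limit is exact. Small multiplicative region effects spread
  BP_ND over ≈ 1.4–2.0 across regions.
* Noise: zero-mean Gaussian with `var ∝ value/(duration · e^{-λ·mid})`
  (decay-corrected count statistics), scale sc = 0.05 ≈ 2–6% frame CoV.
* Kinetic classes: generated from the package's own 2TCM forward model
  (high-/low-binding GM at k3 = 0.08/0.04, white matter, whole blood,
  optionally soft tissue and bone, optionally a leading 30-s background
  frame). Published population class sets are not distributed, so these
  are synthetic stand-ins with identical structure; external sets load
  from CSV. Tissue classes carry a physiologic blood volume (5% GM) —
  without it the reference would lack the vascular spike present in
  every real tissue TAC and reference-model fits would be biased into a
  degenerate branch. Voxel datasets scale each voxel by a log-normal
  amplitude around its class's absolute curve area, and group same-class
  voxels contiguously on the grid by default (tissue is spatially
  contiguous; with i.i.d. labels the 4-mm smoothing would blend every
  class into every voxel).

What the generator does **not** emulate: image reconstruction effects
(correlated noise, partial volume beyond Gaussian smoothing, scatter),
metabolite-correction error in the AIF, subject motion, and anatomically
realistic class geometry. Passing tests therefore demonstrate the
correctness and internal calibration of the estimators under the stated
noise model, not their behaviour on scanner data.

## Study pipeline and problem sizes

`run_study` (seeded, byte-reproducible) simulates the cohort, fits all
pathways and writes inputs/fits/outcomes/reliability/figures plus a
manifest with a config hash. Voxel anatomy is drawn per subject and only
frame noise per session. Default problem sizes — 6 subjects, 216 voxels
per subject on a 6³ grid, 30/100 multistarts — complete in about a
minute on one CPU and were chosen so that the full pipeline, test suite
and acceptance script all run comfortably on a laptop-class machine;
every size is a config field.

## Known limitations

* SRTM/SRTMv on noisy data with pseudo-bp near zero is ill-conditioned;
  some fits legitimately terminate on parameter bounds (flagged). This
  mirrors the instability of these outcome measures rather than an
  optimizer defect.
* The SUV scale follows the standard `C/(dose/weight)` convention
  (g/mL). Published TSPO SUV tables sometimes print values an order of
  magnitude larger, suggesting a different normalisation; a constant
  factor affects neither ICC nor correlations, so no attempt is made to
  match it.
* The 50-min-scan path truncates the schedule and computes windowed SUVs
  over the covered portion with a short-scan flag; fits simply use fewer
  late frames.
* ICC variants other than one-way random (two-way agreement/consistency)
  are not implemented; the one-way choice is pinned by the SEM identity
  above.
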
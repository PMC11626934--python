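# Methods

This note documents the models, conventions and numerical choices behind
`glucoflow`. It covers the dynamic glucose-enhanced CEST quantification,
the pCASL perfusion and activation analysis, the cohort statistics, and
the synthetic scanner used to validate all of them.

## Dynamic CEST quantification

### Acquisition model

A session consists of four identical 20.7-min segments. Each segment opens
and closes with a reference scan at 667 ppm (far enough off resonance to be
effectively unsaturated) and contains 12 repetitions of a three-offset
block at 1.2, 2.0 and 2.9 ppm — 48 acquisitions per offset over the
session. The first segment is the pre-injection baseline; the time axis
puts t = 0 at the onset of the 2DG infusion, so the baseline segment spans
roughly [-20.7, 0] min and the three post-injection segments cover about an
hour. Frames are placed at the centers of equal acquisition slots inside
each segment; the exact frame table is stored in the JSON sidecar of each
session, in minutes.

### Drift correction

Scanner drift and S0 normalization are handled in one step: a straight line
is fitted voxelwise through the two reference values of each segment,
evaluated at every sample time, and each frame is divided by it. Two points
determine the line, so any per-segment linear multiplicative drift is in
the model class and is removed to machine precision (the acceptance suite
checks < 1e-12 relative residual). No additional detrending within offsets
is applied. Voxels whose interpolated reference is not strictly positive at
any sample are flagged invalid and propagate as invalid through all
downstream maps and ROI means rather than producing spurious ratios.

### MTR, ΔMTR and AUC

MTR = 1 − S/S0 per voxel, offset and time; ΔMTR subtracts the per-voxel,
per-offset mean MTR over the baseline window (default: all pre-injection
samples), so baseline samples of the output average to zero exactly.
Glucose uptake is summarized as the trapezoidal integral of ΔMTR over
[0, 60] min post-injection and over the three 20-min phases (initial,
peak, washout — fixed windows matching the segment structure; "peak" is
the second post-injection segment by convention, not max-detected). Window
edges are snapped to the nearest sample time identically for the phase and
total integrals, which makes the three phase AUCs an exact partition of
the total. ΔMTR is dimensionless and time is in minutes, so AUC carries
units of ΔMTR·min; this scale is recorded in output metadata. Cross-group
comparisons (fold ratios, percent changes) are scale-invariant. The
headline offset is 2.9 ppm, the probed frequency farthest from water; the
other offsets are computed and stored alongside.

## pCASL quantification

### Resting CBF

The standard single-compartment, single post-labeling-delay closed form is
used, with the 6000 factor converting ml/g/s into ml/100g/min:

CBF = 6000 · λ · (ΔM/M0) · R1a · exp(w·R1a) / (2α · (1 − exp(−τ·R1a)))

Defaults: λ = 0.9 mL/g, R1a = 0.45 s⁻¹, α = 0.85, τ = 2 s, w = 0.35 s.
R1a is treated as a rate in s⁻¹ (blood T1 ≈ 2.2 s at 7 T). ΔM is the
pairwise control − label difference and M0 the mean control image over the
4-min pre-stimulation baseline. Fractional differences above 0.2 violate
the small-signal assumption and are flagged invalid, as are non-finite
values arising from non-positive M0.

### Stimulation paradigm and activation mapping

The default design is 4 min of baseline followed by three cycles of 2-min
stimulation + 4-min rest: 22 min = 264 label/control pairs at TR 2.5 s per
image. This is the only block arrangement consistent with the stated pair
count; it is configurable.

The perfusion-weighted signal (running control − label differences at pair
midpoints) is normalized by its voxelwise baseline mean and fitted by
ordinary least squares on three regressors: intercept, centered linear
drift, and an unconvolved boxcar aligned to the stimulation blocks. The
boxcar is not convolved with a hemodynamic response because the CBF
response over 2-min blocks is sustained and block-shaped at this time
resolution; the regressor set (drift order 1, no response basis) is a
documented convention of this package, not a reproduction claim of any
particular scanner software. The stimulus coefficient is then directly the
fractional perfusion change; two-sided t and p come from the residual
degrees of freedom (264 − 3).

Before the GLM the series can be smoothed with a plain Gaussian kernel at
a fixed FWHM (default 0.55 mm on 0.32-mm voxels, σ = FWHM/2√(2 ln 2)).
A fixed-width kernel is used rather than an iterative smooth-to-target
algorithm; for spatially white noise the two coincide to first order,
which is the regime the synthetic data occupies.

Thresholding is Benjamini–Hochberg FDR at q = 0.05 over the analysis mask,
followed by removal of connected components smaller than 4 voxels under
4-connectivity (the stricter standard choice; 8-connectivity is available).
The activation summary reports area_fraction = significant voxels /
analysis-mask voxels (the "area of activation" values near 0.1–0.4 are
read as fractions of the analysis mask, and labeled as such) and
response_pct = 100 × mean fractional effect over significant voxels,
reported as missing (NaN) when nothing survives.

## Cohort statistics

Per-animal metrics are analyzed with a linear mixed-effects model
(REML, statsmodels MixedLM): treatment-coded fixed effects of diet
(reference CHOW), genotype (reference nTg), sex (reference M), optionally
age as a numeric covariate and named interactions, with a per-rat random
intercept. Wald p-values are reported; non-convergence is surfaced through
a flag, never silently. Age can be included or excluded at call time since
both designs are legitimate readings of the intended model.

Each contrast passes a Shapiro–Wilk gate at α = 0.05: normal-looking
contrasts are tested with all-pairs Tukey HSD on the raw cell means (the
link between the LMM and the pairwise tests is left as this documented
convention; model-adjusted means are not used), non-normal ones with the
two-sided Mann–Whitney U test (exact null distribution for small untied
samples, normal approximation with tie correction otherwise). No
correction is applied across different outcome metrics, matching the
analysis this package mirrors.

Percent changes are reported as 100·(comparison − reference)/reference
rounded to the nearest integer percent; fold ratios as
comparison/|reference|. Weight gain relative to the age/sex-matched
CHOW-fed non-transgenic mean is classified into half-open bands:
normal < 14%, overweight [14, 38), obese class 1 [38, 62),
obese class 2 [62, 84), above_range ≥ 84%.

## Synthetic scanner

The simulator generates data the quantification chain can be validated
against, with known ground truth.

* **CEST sessions.** Reference frames carry S0·(1 + drift·t); offset
  frames carry the same drifting S0 times (1 − MTR(t)), with
  MTR(t) = baseline MTR + ΔMTR_true(t). ΔMTR_true is a gamma-variate
  (amplitude, onset, rise and decay rates) — it reproduces the
  rise-then-washout shape of measured uptake curves without asserting a
  mechanistic uptake model. Defaults: amplitude 0.01 (1% of S0, a typical
  glucoCEST effect size), onset 1 min, rise 0.06/min, decay 0.05/min
  (peak ≈ 25 min post-injection, inside the second segment), drift
  −0.0005/min, noise SD 0.002·S0, baseline MTR 0.05.
* **ASL sessions.** Controls are M0 + noise; labels subtract the ΔM that
  inverts the closed-form CBF model at the true CBF (default
  150 ml/100g/min, a typical anesthetized-rat cortical value), scaled by
  (1 + response) inside stimulation blocks for active voxels (default
  response 0.20). Noise SD defaults to 0.01·M0.
* **Cohorts.** Balanced diet × genotype × sex tables with cell means from
  indicator-coded effect specifications, per-rat Gaussian intercepts and
  residual noise.

Noise is additive i.i.d. Gaussian on image intensities — adequate for
magnitude MRI at SNR where Rician ≈ Gaussian, which all defaults satisfy.
Because no per-voxel SNR is published for the acquisition this package
models, the simulator noise defaults are free parameters chosen at
plausible values, not claims about any measured data set. The simulator is
motion-free, field-map-free and spatially uniform: passing recovery tests
demonstrates correctness of the quantification algebra and of the
statistical control, not robustness to motion, B0/B1 inhomogeneity,
partial-volume effects or physiological noise, which real data contain.

All generators take explicit integer seeds and never touch global random
state; identical seeds give bitwise-identical outputs.

## Numerical and design choices

* Trapezoidal integration (numpy) for all AUCs; edges snapped to the
  sample grid so partition identities hold exactly.
* Drift correction is exact two-point interpolation, not least squares;
  with exactly two references per segment they coincide, and the two-point
  form guarantees machine-precision removal of in-class drift.
* SEM of a single-voxel ROI is 0 by convention; empty ROIs and empty
  analysis masks are errors.
* BH-FDR, Tukey HSD, Mann–Whitney, Shapiro–Wilk and the mixed model are
  delegated to statsmodels/scipy; tests validate them against independent
  oracles (hand step-up, exhaustive 252-labeling enumeration, OLS normal
  equations).
* Degenerate inputs fail loudly: missing reference frames, rank-deficient
  designs, single-level factors, empty windows and invalid configurations
  raise before any computation runs.

## Problem sizes used in validation

The validation suite runs the chain at reduced image grids (8×8 to 64×64
single slice) and moderate replication (100 seeds for CBF recovery, 500
null replicates for FDR and family-wise error control, cohorts of 50 rats
per cell for mixed-model recovery) — sizes chosen so the full suite
completes in minutes while keeping Monte-Carlo errors well below the
tolerances being checked.

## Known limitations

* Single-slice 2-D geometry only; no 3-D clustering.
* No motion correction, B0 correction beyond reference normalization, or
  partial-volume correction; the simulator does not generate these
  artifacts either.
* The absolute scale of uptake AUC depends on acquisition details that are
  not modeled; only ratios and contrasts are treated as reproducible.
* The GLM assumes i.i.d. residuals; autocorrelated physiological noise in
  real ASL data would make the nominal p-values optimistic.
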
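# glucoflow

Quantification pipeline for brain glucose uptake and hemodynamics in
small-animal MRI: dynamic glucose-enhanced CEST, pCASL perfusion with
stimulation-evoked functional hyperemia, and cohort-level mixed-effects
statistics — validated end to end against a synthetic scanner with known
ground truth.

## Who this is for

Preclinical imaging groups studying brain metabolism and neurovascular
function (e.g. in rat models of Alzheimer's disease under dietary
intervention) who need a tested, reproducible implementation of the
standard quantification chain rather than one-off analysis scripts.

## What it computes

**Glucose uptake (dynamic CEST).** After intravenous 2-deoxy-D-glucose,
the water signal S is probed at hydroxyl-proton offsets (1.2, 2.0,
2.9 ppm) with far-off-resonance reference scans (667 ppm) bracketing each
acquisition segment. The chain computes

- drift correction: voxelwise division by the line through each segment's
  two reference scans (removes linear scanner drift exactly),
- MTR = 1 − S/S₀ and ΔMTR = MTR − MTR_baseline,
- uptake AUC = ∫₀⁶⁰ ΔMTR dt (trapezoidal, ΔMTR·min) plus the three
  20-min phase AUCs (initial, peak, washout).

**Perfusion and functional hyperemia (pCASL).** From interleaved
label/control EPI pairs, resting CBF via the single-compartment closed
form

    CBF = 6000 λ (ΔM/M₀) R₁ₐ exp(w R₁ₐ) / (2α (1 − exp(−τ R₁ₐ)))

(λ = 0.9 mL/g, R₁ₐ = 0.45 s⁻¹, α = 0.85, τ = 2 s, w = 0.35 s), and
activation mapping of a block stimulation paradigm by voxelwise OLS on
[intercept, drift, boxcar], Benjamini–Hochberg FDR (q = 0.05) and a
minimum cluster extent of 4 voxels; summaries are the activated area
fraction and the mean % CBF response.

**Cohort statistics.** Shapiro–Wilk normality gate per contrast; linear
mixed-effects models (diet, genotype, sex, optionally age and
interactions; random intercept per rat; REML); Tukey HSD or Mann–Whitney U
pairwise contrasts; percent-change/fold-ratio reporting and weight-gain
classification.

**Synthetic scanner.** Generators for CEST sessions (gamma-variate uptake,
linear drift, Gaussian noise), pCASL sessions (inverse of the CBF model,
block responses in an active region) and balanced cohort tables — all
seeded, all carrying ground truth for recovery tests.

See `docs/methods.md` for models, assumptions and numerical conventions.

## Worked example

```python
import numpy as np
import glucoflow as gf

# --- glucose uptake from a synthetic CEST session ---------------------
truth = gf.CESTGroundTruth(uptake_amplitude=0.01, noise_sd=0.002)
series, _ = gf.simulate_cest_session(truth=truth, seed=1, grid_shape=(32, 32))
curve = gf.delta_mtr(gf.compute_mtr(gf.drift_correct(series)), offset=2.9)
mean, sem = gf.roi_timecourse(curve.values, np.ones((32, 32), bool))
roi = gf.UptakeCurve(mean, curve.times, 2.9, curve.baseline_window, sem=sem)
print(gf.phase_aucs(roi).as_dict())

# --- resting CBF and activation from a synthetic pCASL session --------
active = np.zeros((64, 64), bool); active[14:49, 14:49] = True
atruth = gf.ASLGroundTruth(cbf_true=150.0, response_pct=0.20,
                           active_mask=active, noise_sd=0.01)
asl, _ = gf.simulate_asl_session(truth=atruth, seed=1)
dm, m0 = gf.perfusion_difference(asl)
cbf = gf.resting_cbf(dm.mean(axis=-1) / m0)
act = gf.activation_summary(asl, np.ones((64, 64), bool),
                            fwhm_mm=0.55, voxel_size_mm=0.32)
print(round(cbf.cbf.mean(), 1), round(act.area_fraction, 3),
      round(act.response_pct, 1))
```

Output:

```
{'auc_total': 0.44258538704908196, 'auc_initial': 0.11407468113310218,
 'auc_peak': 0.19843468044778928, 'auc_washout': 0.13007602546819058}
149.9 0.328 18.0
```

The phase AUCs (ΔMTR·min) show the uptake peaking in the middle 20-min
phase, as generated; the recovered resting CBF is 149.9 ml/100g/min
against a ground truth of 150; the thresholded activation map covers 32.8%
of the slice (true active region: 30%) with a mean CBF response of 18.0%
(true: 20%, edge voxels diluted by smoothing).

There is also a CLI mirroring the library
(`glucoflow simulate-cest | simulate-asl | simulate-cohort | quantify-cest
| quantify-asl | group-stats | run-all`), with images as NIfTI + JSON
sidecars, tables as CSV and results as JSON.

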
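# hsretina

Hyperspectral retinal imaging analysis for brain-amyloid discrimination.

Retinal reflectance carries a faint short-wavelength (< 565 nm) spectral
signature associated with amyloid-beta, the protein that accumulates in the
Alzheimer's disease brain. The signal is buried under much larger
between-eye differences in ocular media (lens), macular pigment, melanin and
haemoglobin. `hsretina` implements the full analysis pipeline that recovers
it from hyperspectral fundus images — for imaging scientists and
biostatisticians who want a tested, reusable, fully synthetic-data-backed
implementation:

* **Preprocessing** — dark/white (Spectralon) reflectance calibration,
  integer-shift inter-frame registration, natural-log transform,
  Savitzky–Golay smoothing (order 5, window 13).
* **Systematic sampling** — a temporal-raphe-aligned template of six retinal
  regions (foveolar disc F1, parafoveal annulus F2, four 200 px squares
  S1/S2/I1/I2), with blood vessels excluded by a difference-of-Gaussians
  rule that flags the top 40 % of DoG response.
* **DROP-D discriminant** — Dimension Reduction by Orthogonal Projection
  for Discrimination, producing a per-subject hyperspectral (HS) score.
* **Mouse transfer** — whole-retina spectra, MAD outlier exclusion, session
  compensation, and recalibration of the human model to the mouse camera's
  450–680 nm range.
* **Statistics** — pooled/Welch t with CIs, chi-square with Woolf
  odds-ratio CIs, Pearson correlation with Fisher-z CIs, Mann–Whitney
  ROC/AUC with Hanley–McNeil CIs, Benjamini–Yekutieli FDR, and the
  repeated-measures group effect.
* **Synthetic data** — seeded generators for cohort spectra and full
  image cubes (vessel trees, fovea, optic nerve head) with stored ground
  truth, so every stage is testable end to end.

## The model

Spectra are analysed in log space, where reflectance factors combine
additively (Beer–Lambert). For a cohort matrix **X** (subjects ×
wavelengths) with class labels, DROP-D works in two steps:

1. **Within-class axis removal.** Centre each row by its class mean and take
   the top *k* right singular vectors **W** = [w₁ … w_k] of the result —
   the dominant spectral directions of within-group (nuisance) variability.
2. **Between-class axis.** Deflate the class-mean difference onto the
   orthogonal complement of span(**W**) and normalise:

   b ∝ (I − WWᵀ)(μ_case − μ_control),  ‖b‖ = 1,  Wᵀb = 0.

The HS score of a spectrum **x** is the inner product

   HS(x) = (x − μ) · b,

which by construction is invariant to any linear combination of the removed
axes — robust behaviour in the small-n, many-wavelengths regime. The number
of removed axes *k* is chosen by leave-one-out cross-validation, maximising
the AUC of held-out scores. The removed axes themselves decompose, by
ordinary least squares on parametric constituent curves, into known ocular
absorbers (media, macular pigment, melanin, haemoglobin) with sub-percent
residuals.

## Worked example

```python
import numpy as np
import hsretina as hs

train, truth = hs.simulate_cohort(hs.recovery_cohort_config(seed=0))
cv = hs.select_k_loocv(train, k_max=4)
model = hs.fit_dropd(train, cv.chosen_k)

test, _ = hs.simulate_cohort(hs.recovery_cohort_config(seed=999))
roc = hs.roc_auc(hs.score_matrix(model, test), test.labels)
print(cv.chosen_k, roc.auc)
```

Running `python examples/03_train_and_score.py` (this example with its
narrative output) prints:

```
LOO criterion (AUC) per k: [0.581 0.537 1.    1.    1.   ] -> chosen k = 2
|cos| between fitted axis and (deflated) planted signature: 0.943
held-out AUC 1.000 (95% CI 1.00-1.00) on 80 new subjects
removed axis w1: constituent-fit RMSE 0.06% (how fully known ocular constituents explain it)
removed axis w2: constituent-fit RMSE 0.11% (how fully known ocular constituents explain it)
```

Reading: cross-validation recovers the two planted nuisance axes (k = 2 is
where held-out discrimination jumps to 1.0); the fitted spectral model is
within 19° of the true planted amyloid axis after deflation; and the removed
axes are almost entirely explained by known ocular constituents — exactly
the behaviour the method is designed to have.

The other scripts in `examples/` each demonstrate one capability (cohort
simulation, cube rendering and ROI sampling, the mouse pipeline, the cohort
statistics, and the full three-cohort human study).

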
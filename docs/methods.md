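# Methods

This note records the modelling and numerical choices behind `hsretina`:
what each stage assumes, which parameters matter, what the synthetic data
do and do not emulate, and the known limitations.

## Spectral preprocessing

Raw camera counts are converted to reflectance as
`R(λ) = (counts(λ) − dark − stray(λ)) / (white(λ) − dark)`, with the white
reference from a Spectralon-lined model eye. Reflectance is clipped at zero
from below (detector noise) and not clipped above (specular structures can
exceed a diffuse standard). The stray-light (internal-reflection) term
defaults to zero: its estimation procedure is proprietary to the camera
vendor, and the term is kept as an explicit input so calibrated values can
be supplied.

Registration is translation-only with integer pixel shifts: each frame's
shift relative to its neighbour maximises the normalised cross-correlation
(searched within ±20 px by default), and shifts are accumulated along the
frame chain to the chosen reference. Pixels rolled in from outside the
frame are returned in a validity mask and excluded downstream. Rotational
and sub-pixel motion are out of scope; for the residual inter-frame motion
this stage models, integer translation is the dominant component.

Spectra are transformed with the natural log (the base only rescales every
downstream linear quantity; one base is fixed for reproducibility), after
flooring reflectance at 1e−6 to guard isolated shot-noise zeros — an
all-zero spectrum is treated as a calibration failure and raises.
Savitzky–Golay smoothing uses a 5th-order polynomial over a 13-sample
window (65 nm on the human grid), applied to ROI-mean spectra only, after
averaging — matching the stated order of operations (log, then average,
then smooth). Terminal half-windows are filled by evaluating the polynomial
fitted to the first/last full window.

## Sampling geometry

Image convention: row-major, origin top-left, 0-based `(row, col)`.
The temporal raphe angle is `atan2(Δrow, Δcol)` of the fovea→ONH vector
(0 = horizontal, +π/2 = downward). The template places:

* F1 — filled disc, 60 px diameter, at the fovea (pixels with centre
  distance ≤ 30 px);
* F2 — annulus, 100–200 px diameters (50 px < d ≤ 100 px);
* S1/I1 and S2/I2 — 200×200 px squares displaced perpendicular to the
  raphe from the fovea and ONH respectively, sides aligned with the raphe.
  Square membership uses half-open intervals `[−side/2, side/2)` so an
  axis-aligned square contains exactly side² pixels.

The perpendicular offsets (default 300 px for both) are not published
quantities; they are explicit `TemplateConfig` parameters so the geometry
is testable, and they scale down for small synthetic images.

Vessel exclusion: the DoG response is `G(σ_large)∗I − G(σ_small)∗I`, so
locally dark curvilinear structures score high. The published "variance
parameters 1 and 20" are interpreted as Gaussian σ in pixels — the common
convention in DoG practice — and are configurable. Exactly
`ceil(fraction · N)` pixels are flagged (default fraction 0.40), with ties
broken toward the lowest (row, col) position: the flagged count is
deterministic for every input, including constant images. The mouse variant
takes the maximum signed DoG over all (σ_s, σ_l) pairs with σ_s < σ_l from
σ_s ∈ {1.0, 1.2, …, 5.0} and σ_l ∈ {4, 5, …, 14} ("series of DoG" is read
as a max-combination, the standard multi-scale filter-bank rule; sum gives
nearly identical rankings on the phantoms tested), then applies the same
quantile rule; the quantile fraction for mice is unstated in the source
material and reuses 0.40, configurable. The optic nerve head is flagged as
a disc around its landmark when provided.

ROI spectra are means of log-transformed pixel spectra (log before mean)
over ROI ∧ ¬vessel ∧ valid pixels, then smoothed.

## The discriminant

`fit_dropd` removes within-class axes and takes the between-class principal
axis (see README for the equations). Choices that the summary description
leaves open, fixed here:

* The within-class axes are the top right singular vectors of the matrix
  formed by centring each class on its own mean and stacking — the
  canonical reading of "main spectral axes of within-class variability".
* For two classes the between-class principal axis is the deflated class-
  mean difference regardless of class-size weighting; weighting would only
  change reported eigenvalues, not the direction.
* Scores are computed as `(x − μ)·b` without deflating `x` — equivalent
  because `b ⊥ W`; the equivalence is asserted by a unit test rather than
  assumed.
* Sign conventions for bit-reproducibility: each `W` column's largest-
  magnitude entry is positive; `b` is oriented so the mean training case
  score exceeds the mean control score.
* LOO model-order selection scores every held-out subject with a model
  refit on the rest and uses the AUC of held-out scores as the criterion
  ("optimise discrimination"); ties break toward smaller k (parsimony).
  A flat criterion near 0.5 is flagged on the returned curve.

Constituent decomposition of an axis is OLS on selected basis columns plus
an intercept; `rmse_percent` is 100 × RMS residual of the unit-norm axis
fit, the normalisation under which sub-percent values are meaningful.

Recalibration to a narrower grid resamples the training spectra by linear
interpolation (no extrapolation allowed) and refits, optionally re-running
the LOO selection on the restricted grid.

## Mouse pipeline

Whole-retina mean spectra (vessels + ONH excluded) are log-transformed and
resampled to 450–680 nm in 5 nm steps (47 wavelengths). The outlier rule
uses the unscaled MAD (no 1.4826 consistency factor — none is stated for
the original rule): an animal is flagged at a wavelength if its value is
strictly below median − 3·MAD, and excluded if flagged at strictly more
than 50 % of wavelengths; both inequalities matter only at degenerate ties,
and the strict reading keeps identical cohorts intact (MAD = 0). Session
compensation subtracts, from every spectrum in a session, that session's
control-mean minus the pooled control mean, in log space (after the log
transform — equivalent to a multiplicative illumination correction in
reflectance space); within-session differences are exactly preserved.

## Statistics

* t tests: pooled variance by default — it reproduces the demographic
  table's MMSE CI exactly; Welch by flag. Effect size is the difference of
  means with its 95 % CI.
* 2×2 tables: Pearson chi-square without continuity correction (reproduces
  the table's p-values) and Woolf log-scale CI
  `exp(ln OR ± 1.96·√(Σ 1/cell))`; a zero cell makes the CI unavailable
  rather than silently continuity-corrected. Orientation (which category is
  the event, which group the numerator) is an explicit argument because
  published tables mix orientations between rows.
* Pearson correlation: Fisher-z CI, t-based two-tailed p. The CI formula is
  validated by a coverage simulation (bootstrap-percentile intervals differ
  systematically from Fisher-z at n = 30 and are not a valid equality
  oracle at tight tolerance).
* ROC/AUC: Mann–Whitney with ties counted ½; Hanley–McNeil CI; p versus
  0.5 from the exact null SE `√((n₁+n₀+1)/(12 n₁ n₀))` — the CI/p method
  of the original analysis is unstated, so a standard, documented choice
  is made.
* Benjamini–Yekutieli: `i* = max{i : p(i) ≤ i·q/(m·c(m))}`,
  `c(m) = Σ 1/j` — valid under arbitrary dependence, as required for
  correlated per-location tests.
* Repeated-measures group effect: two-way mixed design (group × location),
  `F = MS_group / MS_subjects-within-groups` with df (1, n−2). Missing
  cells raise; no imputation.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
retinal optics. A subject's log-spectrum is

`x = m + Σⱼ cⱼ Aⱼ + s · d · σ_noise · β + ε`,

with `m` a smooth fundus baseline, `Aⱼ` unit-norm parametric constituent
curves, `cⱼ ~ N(0, sdⱼ)`, `s` the case indicator, `β` the unit-norm
amyloid stand-in (logistic step, high below 565 nm, gone above 600 nm),
and `ε` i.i.d. `N(0, σ_noise)` per wavelength. The constituent curves are
parametric stand-ins preserving the features the analysis exploits
(short-wavelength signature; 542/577 nm haemoglobin bands; monotone
media/melanin decay); they are not digitised literature extinction spectra,
and the amyloid curve is a declared approximation, not a measured spectrum.

Defaults are the study conditions: 15 cases / 20 controls; nuisance SDs
0.30 (media), 0.30 (melanin), 0.03 (haemoglobin), 0.20 (macular pigment,
foveal locations only); σ_noise = 0.02. The effect size default d = 8
(planted shift 8 noise-SDs along β) is calibrated analytically: with 91
wavelengths, ~35 subjects and i.i.d. residual noise, what limits
discrimination is the estimation noise of the axis `b` (norm
≈ σ_noise·√(2p/n̄)), not the per-wavelength residual, and d = 8 puts the
estimated pipeline at the AUC ≈ 0.85–0.9 operating level the method is
designed for. The oracle score along the true β then separates groups
almost perfectly — a direct consequence of modelling the residual as
i.i.d. white noise; see Limitations.

Because constituent columns are unit-normalised on whatever grid they are
built, the same loading yields a smaller per-wavelength absorbance on a
denser grid. `mouse_cohort_config` therefore rescales loadings and effect
size by each curve's peak-value ratio between the human (91-point) and
mouse (361-point) grids, so a mouse simulation carries the same
per-wavelength contrast as the human study condition — the physically
meaningful statement of "the same effect", since a chromophore's contrast
does not depend on how finely the camera samples the spectrum.

`simulate_multisite_cohort` draws one set of subject loadings shared across
the six locations (fresh residual noise per location, macular pigment
expressed only foveally), reproducing the within-subject correlation of
location scores that makes the six-location average behave like real data
rather than like six independent replicates.

For parameter-recovery studies, `recovery_cohort_config` provides the
identifiable regime: two genuinely distinct dominant nuisance axes (media
and haemoglobin — the realistic media/melanin pair is nearly collinear,
cos ≈ 0.97, and spans only one strong direction), loading SD ten times the
signal amplitude, 40 subjects per group, and small residual noise
(d = 15, σ_noise = 0.002), chosen from the closed-form error budget
`cos∠(b, Pβ) = d‖Pβ‖ / √(d²‖Pβ‖² + 2p/n_g)` with ‖Pβ‖ ≈ 0.38 so the
planted order and axis are recoverable with margin.

Cube rendering adds, on top of a subject's cohort spectrum: a vessel tree
(random walks out of the optic disc, Gaussian cross-section, haemoglobin
absorbance), a Gaussian macular-pigment disc at the fovea, a bright
optic-nerve-head disc, and per-pixel noise; the true vessel mask and
landmarks are returned with the cube. Cubes are stored in float32.

## Problem sizes

The test suite and acceptance script run at desk scale by design: recovery
studies use 80-subject cohorts over 10 seeds; end-to-end human studies use
the study's 35/34/17-subject cohorts; mouse cubes are 48×48 px over the
full 361-wavelength mouse grid with 22 animals; null calibrations use 1000
(type-I error) and 300–500 (ANOVA, CI coverage) replicates. The complete
suite runs in well under a minute.

## Limitations

* Residual spectral noise is i.i.d. across wavelengths and subjects, and
  the case shift is deterministic (every case carries exactly the same
  amyloid amplitude). Real residuals are smooth and subject-heterogeneous,
  so at matched sample sizes the synthetic pipeline separates groups more
  cleanly than clinical data would; passing tests demonstrate correctness
  of the machinery, not clinical effect sizes.
* The constituent curves are qualitative stand-ins; coefficient values from
  `fit_constituents` are meaningful relative to this basis only.
* Registration is integer-shift translational; no rotation, scaling or
  sub-pixel refinement.
* The square-template offsets and the mouse DoG combination rule are
  explicit configuration, not published values.
* Only two-class discrimination is supported; the discriminant is built
  for separation, not for quantitative amyloid-load regression.
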
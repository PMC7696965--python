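# Methods

## Scope

`oralfusion` implements the analysis chain used in dual-modality ex vivo oral
cancer discrimination: quantitative autofluorescence ROI scoring, Raman
spectral preprocessing, PCA-based dimension reduction, linear/quadratic
Gaussian discriminants, principal-component-level fusion of the two
modalities, and cross-validated evaluation. The clinical dataset such studies
rest on (35 patients, paired tumor / adjacent-normal samples) is not public,
so the package includes a synthetic cohort generator that reproduces the
study *design* and the qualitative class contrasts; every empirical claim in
this note is computed by the test suite or `scripts/acceptance.py`.

## Synthetic cohort generator

**Design.** A cohort is `n_patients` (default 35) patients, each contributing
one tumor and one adjacent-normal sample. Each sample yields
`replicates_per_sample` (default 5) raw Raman spectra, so the default cohort
has 350 raw spectra averaging down to 70 sample spectra; each patient also
yields one 8-bit RGB image (default 128×128 px) with one normal and one tumor
circular ROI (default radius 20 px). One root seed drives per-patient child
streams (`numpy` `SeedSequence.spawn`), so cohorts are bit-reproducible and
stable under patient subsetting.

**Raman model.** A spectrum on the 600–1900 cm⁻¹ grid (1 cm⁻¹ step) is

```
I(ν) = B(ν) + Σ_i a_i · r_i(class) · m_i · exp(−(ν − c_i)²/2σ²) + ε(ν)
```

* `B`: degree-2 polynomial in the scaled coordinate, coefficients
  (2.5, −1.8, 0.5) — a broad fluorescence-like background 1.2–2.5 a.u.,
  several times the peak heights, as in fluorescence-dominated tissue Raman.
* Bands `c_i` = 1004, 1123, 1156, 1339, 1450, 1523, 1656 cm⁻¹, Gaussian with
  8 cm⁻¹ FWHM; normal-tissue amplitudes `a_i` = 1.0, 0.35, 0.7, 0.45, 0.8,
  0.55, 0.9 a.u. (a plausible protein/lipid fingerprint; the strong 1004
  phenylalanine band dominates).
* Tumor ratios `r_i` = 1.7, 1.0, 1.45, 1.3, 1.55, 1.35, 1.6: the six
  protein-associated bands are elevated (mean ratio ≈ 1.5), the lipid
  1123 cm⁻¹ band is not. The profile is deliberately *heterogeneous*: after
  per-spectrum min-max normalization a flat ratio cancels almost entirely
  (every peak and the maximum scale together), collapsing the class signal
  onto the single 1123 cm⁻¹ relative height and making cohort separability a
  near-step function of the jitter scale. Spreading the ratio over several
  bands gives a multi-band normalized-shape difference whose detectability
  varies smoothly with the nuisance parameters.
* `m_i`: multiplicative log-normal jitter, drawn per (patient, class) sample
  with σ = `sample_jitter_sd` = 0.10 (biological heterogeneity that survives
  replicate averaging) times a per-replicate factor with σ = 0.05
  (location-to-location variation); `ε`: iid N(0, 0.02²) noise.

**Autofluorescence model.** Images are green-dominant (background green 150
of 255, pixel noise SD 6; red/blue are 0.45× and 0.30× the green field plus
small noise). Each ROI disc is redrawn at level
`150 · exp(N(0, roi_level_jitter_sd)) · (1 − drop·[tumor])` with pixel SD
`6 · exp(N(0, roi_sd_jitter_sd)) · (gain·[tumor])`; defaults drop = 0.35
(loss of autofluorescence), gain = 1.8 (tumor heterogeneity), level jitter
0.24, SD jitter 0.25. The jitters are drawn identically for both classes, so
the null configuration (`drop = 0`, `gain = 1`) makes tumor and normal ROIs
exactly exchangeable — an additive drop jitter clipped at zero would bias the
null. Optional bright out-of-ROI blobs ("teeth") exercise the whole-image
normalization downstream.

**Calibration.** The jitter scales were chosen once so that single-modality
LOOCV accuracy on default 35-patient cohorts lands in the 80–90 % band
characteristic of this problem (10-seed means: Raman 83.6 %, autofluorescence
89.9 %, fused 95.6 %), and then frozen. They are nuisance knobs of a
phenomenological simulator, not claims about real tumor/normal intensity
ratios — no quantitative band ratios are published for this setting.

**What the generator does not emulate.** No Raman physics (no wavenumber
calibration error, cosmic rays, detector nonlinearity), no camera model
(vignetting, specular glare, white balance), no lesion morphology (ROIs are
perfect discs at fixed positions), no subsite or stage structure, and no
correlation between a patient's spectral and imaging effect sizes beyond
sharing a random stream. Passing tests therefore demonstrate the *analysis
chain* is correct and well-behaved under the assumed statistical structure —
not that the reported clinical accuracies would be attained on real tissue.

## Raman preprocessing

Fixed order: Savitzky–Golay smoothing → baseline subtraction →
crop/resample → normalization → replicate averaging → renormalization.

* **Savitzky–Golay**: order 3, window 11 points at 1 cm⁻¹ (preserves the
  ~8 cm⁻¹ bands while denoising), mirror padding so the axis length is kept;
  requires a uniform grid and raises otherwise, directing to resampling.
* **Baseline**: iterative polynomial fitting (order 5, 50 clamp-to-minimum
  iterations — "modpoly"): fit, clamp the working spectrum to min(spectrum,
  fit), refit. Standard for fluorescence-dominated backgrounds; one Vandermonde
  pseudoinverse is reused across iterations and across spectra, so whole-cohort
  preprocessing is a few matrix products. The batch path is tested to agree
  with the per-spectrum chain to 1e-10.
* **Crop/resample**: linear interpolation onto the canonical 700…1800 cm⁻¹
  inclusive grid (1101 points); missing coverage raises with the absent range
  named.
* **Normalization**: `minmax` default (Raman intensities are arbitrary
  units; normalized spectra span exactly [0, 1]); `unit_area` (trapezoidal)
  and `unit_norm` available. Constant/zero spectra raise a degenerate-input
  error rather than returning NaN.
* **Averaging**: pointwise mean over the 5 replicates, then renormalization.
  Normalize-then-average is the default because per-acquisition laser-power
  drift rescales replicates independently; average-then-normalize is exposed
  via `average_before_normalize` since neither order is canonical.

## Autofluorescence features

Pixels belong to a disc iff their (row, col) center is within the radius
(inclusive, 0-based coordinates). Per ROI, on the green channel by default
(the autofluorescence signal; `luminance` available):

* normalized intensity = ROI mean / whole-image mean,
* normalized heterogeneity = ROI population SD / whole-image mean.

Both are invariant under global linear rescaling by construction. The
denominator includes the ROI pixels by default (simple and stable; a switch
excludes them); bright off-lesion structures inflate the denominator and
lower both features for every ROI of that image alike, which is the intended
neutralization. Population (n-divisor) SD keeps 1-pixel ROIs defined.

## PCA, discriminants, fusion

* **PCA**: mean-centered SVD; components ordered by decreasing variance;
  deterministic sign (largest-|loading| entry positive); explained-variance
  ratios are `s²/Σs²` over all singular values. Zero total variance raises.
  `max_components(sizes) = ⌊(min sizes − 1)/2⌋` implements the guard that the
  component count stay below half the smallest class; the pipeline default is
  k = 2 per modality (the fused model then has 4 features), well under the
  guard's 17 for 35-per-class cohorts.
* **LDA/QDA**: class means; pooled within-class covariance with n−K divisor
  (LDA) or per-class n_c−1 covariances (QDA); empirical priors. A ridge of
  1e-8 × mean diagonal is added by default (near-singular 4-D covariances
  from 35 samples/class); ridge 0 with a singular covariance raises and
  recommends a positive ridge. Scores are full log joints
  `log N(x; μ_c, Σ_c) + log π_c` via Cholesky solves; prediction is argmax
  with ties to the lexicographically first class. Two classes with exactly
  identical moments (relabeled duplicates) raise as degenerate.
* **Fusion**: column concatenation of per-modality PC scores aligned by
  sample id (unmatched ids raise, listing them); raw scores by default — the
  discriminant's covariance handles scale — with a standardize-before-fusion
  switch for sensitivity analysis.

## Cross-validation

LOOCV and seeded stratified k-fold (default k = 10; class remainders rotate
across folds so fold sizes differ by ≤ 1). By default every training fold
refits the per-modality PCA and the discriminant, so the held-out sample
never touches the projection; `paper_mode` fits PCA once on all samples and
cross-validates only the classifier — the historically common but
leakage-prone chemometrics protocol — and both can be reported. The error
rate is the pooled misclassified fraction × 100; per-fold 0/1 losses are
retained.

`group_by_patient` holds a patient's tumor+normal pair out together
(leave-one-patient-out). This matters for null-data diagnostics: ungrouped
LOOCV on exactly exchangeable classes is biased *above* 50 % error because
removing one sample unbalances training to 34 vs 35 and the empirical-prior
discriminant systematically votes against the held-out class (measured
54–59 % mean over 20 null seeds, with single-cohort excursions to ~99 %).
Grouped LOOCV keeps training balanced and is centred on chance (50.1–51.9 %
mean). The chance-level test therefore uses grouped LOOCV and tests the mean
over 10 cohorts by a one-sample t-test (α = 0.01) — a single-cohort binomial
bound at n = 70 would be anti-conservative since all predictions of a cohort
share one fitted boundary.

Metrics use the tumor-positive convention throughout: sensitivity =
tp/(tp+fn) over tumors, specificity = tn/(tn+fp) over normals. Reference
results for the Raman analysis have circulated with these two numbers
swapped (the normal-positive reading of the same table); the stored
reference values in `oralfusion.reference` are convention-consistent, and
accuracy is unaffected.

## Problem sizes and runtime choices

Unit tests run on 4–12-patient cohorts; the statistical acceptance checks use
the full 35-patient design — 10 null cohorts for the chance-level test, one
10×-effect cohort for the separability test, and 50 default cohorts for the
fusion comparison (mean fused LOOCV accuracy must be within 1 percentage
point of, or above, each single modality). The whole suite completes in about
a minute on one CPU because preprocessing is batched and each LOOCV fold's
SVD is on a 69×1101 matrix.

## Known limitations

* The generator's effect sizes are calibrated conveniences; agreement of the
  synthetic cross-validated accuracies with any published clinical values is
  a designed-in property of the simulator, not evidence about real tissue.
* The baseline estimator is polynomial-family; backgrounds outside that
  family (e.g. sharp fluorescence edges) would leak into the corrected
  spectrum. The interface accepts a pluggable replacement.
* LDA/QDA assume Gaussian class conditionals; the normalized image features
  are ratios of positive quantities and mildly skewed, which the discriminant
  tolerates but does not model.
* No probability calibration, ROC analysis, confidence intervals, or
  premalignant (three-class) support; ROIs are given, never segmented.
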
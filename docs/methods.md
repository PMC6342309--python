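# Methods

## The measurement

Emphysema destroys lung parenchyma, which shows up on CT as regions of
abnormally low attenuation. The classical densitometric index, LAA%, counts
the fraction of lung pixels below a Hounsfield-unit (HU) threshold, but it is
blind to *how* those pixels are arranged. Homology-based emphysema
quantification (HEQ) adds that spatial information: threshold the lung into a
binary image (0 = lung pixel below the threshold, 1 = normal lung or outside
the lung) and compute the Betti numbers of the 0 set —

- **b0** — number of connected low-attenuation regions,
- **b1** — number of normal-lung islands completely surrounded by
  low-attenuation tissue.

Quantification uses three axial slices per patient (upper, middle, lower lung
fields) at three thresholds, −950, −910 and −880 HU. LAA% pools the pixel
counts of the three slices; per-patient b0 and b1 are the sums of the
per-slice values, by parallel construction with the LAA% formula. Summing is
equivalent to computing on a stacked composite, since slices cannot touch in
a per-slice 2-D computation.

### Slice selection

Which three slices were used is an anatomic choice we cannot reconstruct
exactly; we adopt a deterministic, mask-driven rule: slices at fractional
positions 0.25 / 0.50 / 0.75 of the cranio-caudal lung extent (first to last
slice containing any mask pixel), rounded half-up. On extents too short for
three distinct rounded indices the indices are spread outward so the three
are always distinct. The fractions are configuration, not constants.

### Topology conventions

- A pixel is low-attenuation iff it is inside the lung mask **and** HU is
  *strictly* below the threshold; ties count as normal lung. This makes the
  0 set monotone non-decreasing in the threshold, hence LAA% is non-decreasing
  from −950 to −880 HU for every patient — a property the test suite enforces.
- The 0 set uses 8-connectivity and the 1 set 4-connectivity. This dual
  pairing is the standard one under which b0 − b1 equals the Euler
  characteristic of the union of closed unit pixels; the pair is a
  configuration knob in case a different convention must be matched.
- b1 is computed as the number of 4-connected 1-components that touch no grid
  border. Outside-lung pixels are 1 and connect to the border, so the mask is
  not needed at topology time.
- The Euler characteristic is computed by explicit cell counting (distinct
  lattice vertices − distinct edges + pixel faces) for the 8-connected
  foreground, and by the Gray bit-quad formula for the 4-connected variant.
  The identity χ = b0 − b1 is asserted property-style against an independent
  BFS flood-fill oracle in the tests.

Connected-component labelling itself is delegated to `scipy.ndimage.label`;
the flood-fill oracle in the test suite is a separate, dependency-free
implementation.

## The risk models

Patients carry age (years), sex, smoking history (Brinkman index =
cigarettes/day × years), an optional malignant-tumor history, the
quantification metrics, and a binary outcome (lung cancer vs benign nodule).
The pipeline mirrors a conventional clinical-risk analysis:

1. **Screening.** Continuous covariates: two-sample t-test between outcome
   groups (Welch by default; Student available — published tables rarely say
   which was used). Categorical covariates: chi-squared with Yates continuity
   correction on the 2×2 table. A covariate constant in both groups reports
   p = 1 with a flag. No multiplicity correction is applied, matching the
   original analysis style.
2. **Threshold selection.** The working HU threshold minimizes the screening
   p-value of b1; ties fall back to the LAA% p-value, then to the higher HU.
3. **Models.** Four logistic regressions: `base` (sex + age + Brinkman),
   `laa` (+ LAA% at the selected threshold), `heq` (+ b1), and `heq_b`
   (+ b1 binarized at a cutoff, default 5100, strict `>`). Fits are maximum
   likelihood via IRLS (statsmodels GLM, binomial family, tolerance 1e-8,
   ≤50 iterations), intercept always included, covariates unstandardized.
   Wald standard errors come from the inverse observed information;
   AIC = 2k − 2·log L (asserted against a hand-computed log-likelihood in the
   tests). Non-convergence or separation raises an explicit error naming the
   suspect term. Odds ratios are exp(coef) with 95% Wald intervals.
4. **Discrimination.** AUC by the Mann–Whitney estimator with ties counted
   one half (checked against exhaustive pair counting). Correlated AUCs are
   compared with DeLong's test from placement values; this is hand-written
   (no installed Python package provides it) and cross-checked in the tests
   against R's `pROC::roc.test` to ~1e-9 and against a type-I-error
   simulation. Self-comparison returns z = 0, p = 1 by definition.
5. **Cross-validation.** Stratified-by-outcome k-fold (default k = 10) with a
   configurable seed; each fold's model is refit on the remaining folds and a
   *single pooled* ROC is built from the out-of-fold probabilities. Pooling
   yields patient-level predictions, which is what a DeLong comparison of
   cross-validated models needs. How the original folds were drawn is
   unknowable, so only stochastic agreement with published CV AUCs can be
   expected (±0.02 across seeds is the band we test).

The 5100 cutoff for `heq_b` is kept as an empirical configuration default; an
exploratory Youden-index grid search over b1 is provided
(`risk_models.find_b1_cutoff`) but is never used in reproduction runs.

## Synthetic data

**Phantoms** (`generate_phantom`) are three-slice images of two elliptical
"lungs" on a 128×128 grid. Normal parenchyma is N(−740, 25) HU and
emphysematous holes N(−1020, 25) HU, which puts each distribution more than
5 SD away from the −880 HU construction threshold; the generator validates a
≥3 SD separation. Topology is planted, not estimated: solid disks contribute
components, and annuli (a low ring around a normal core) contribute a
component plus one enclosed island, so per-slice ground truth is exactly
(b0, b1) = (n_components, n_enclosed). Shapes are rejection-sampled to be
pairwise non-adjacent (≥1 normal pixel apart, diagonals included) with a
capacity error after 1000 failed placements. After rendering, each slice is
re-thresholded and *exact* recovery of the planted 0 set is asserted; a
failing slice (probability ~1e-4 per slice) is regenerated from the next
noise substream and the event counted in the returned truth record.

**Cohorts** (`generate_cohort`) emulate the covariate structure of the target
study population: n = 576; age N(66.8, 12.4) clipped to [20, 100]; 55% male;
Brinkman index zero-inflated (35% never-smokers) lognormal(6.6, 0.8), overall
mean ≈650; emphysema metrics drawn around the published marginal means/SDs
with a shared latent severity factor (loading 0.6) to induce realistic
cross-threshold correlation; LAA% built from non-negative increments so
threshold monotonicity holds by construction. The outcome is
Bernoulli(expit(β₀ + β·x)) with default coefficients (sex −0.438, age 0.0260,
Brinkman 2.94e−4, b1@−880 1.04e−4) on the scale of the published fits; the
intercept is calibrated numerically (Brent root-finding) so the mean risk
equals the target prevalence of 283/576. The hidden truth record (intercept,
coefficients, per-patient linear predictor) supports parameter-recovery and
calibration tests.

What the phantoms deliberately do **not** model: CT texture, reconstruction
kernels, dose/noise structure, partial-volume effects, or anatomically
realistic lung shapes. Passing phantom tests therefore shows the topology and
bookkeeping are exact on clean geometry, not that the metrics are robust to
scanner physics. Likewise the cohort generator draws metrics from marginal
summaries, not from images, so it validates the statistical machinery rather
than the imaging chain.

## Numerical choices and edge cases

- HU values are validated against [−1100, 3100]; out-of-range values abort
  rather than silently clamping, since they usually indicate a missing DICOM
  rescale. DICOM inputs without RescaleSlope/Intercept are refused.
- Empty masks, single-class outcomes, and CV folds whose training split has
  one outcome class raise dedicated degenerate-input errors naming the stage.
- AUC and DeLong handle ties at one half; DeLong variance uses ddof = 1
  placement covariances; a variance below 1e-15 (identical scores) reports
  z = 0, p = 1.
- All randomness (phantoms, cohorts, CV folds) flows from explicit seeds via
  `numpy.random.SeedSequence`, so identical inputs and configuration produce
  bitwise-identical reports.

## Problem sizes in the test suite

The suite runs at desk scale: 200 random grids up to 64×64 against the
flood-fill oracle; a phantom matrix of 0–10 components × 0–5 enclosed
islands; parameter recovery at n = 5000; 1000 null replicates (n = 100) for
the DeLong type-I check; n = 50 000 for the bi-normal closed-form AUC check,
which is a small-effect approximation (AUC → Φ(βσ/√2)) and is therefore
evaluated at the study-scale effect σβ ≈ 0.25.

## Known limitations

- Lung segmentation is out of scope: masks are inputs. The phantom masks are
  analytic ellipses, not anatomic shapes.
- Only the three-slice protocol is implemented; there is no whole-volume
  quantification mode and no persistent-homology filtration across
  continuous thresholds.
- Reproduction of the original clinical numbers requires the study's
  per-patient raw table (see `data/s3_column_map.json`); the repository ships
  no clinical data, so the clinical-reproduction test reports the missing
  input until that file is supplied.
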
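# Methods

`lateromics` implements a radiomics pipeline for lateralizing temporal
lobe epilepsy (TLE) from FLAIR MRI: per-hemisphere hippocampal and
extrahippocampal-temporal regions of interest (ROIs) are summarized by
a 1,618-dimensional radiomic feature vector, discriminative features
are selected by univariate testing with false-discovery-rate control
followed by elastic-net penalization, and the resulting logistic score
is evaluated as a laterality classifier by ROC analysis. This note
documents the model, the defaults, and the design choices that were
genuinely open.

## Image preprocessing

**Grid.** All analysis happens on a single canonical isotropic grid
(1 mm default). Intensity volumes are resampled trilinearly, label maps
with nearest-neighbour interpolation, both to `ceil(extent / target)`
voxels with the origin preserved (tissue is never cropped). Whether
normalization precedes or follows resampling is not fixed by any
external constraint; this package resamples first and normalizes on the
canonical grid, so the stripe statistics describe the grid on which
features are extracted.

**White-stripe normalization.** Normal-appearing white matter is
anchored to a standard scale: the mode of the kernel-density-smoothed
in-brain intensity distribution is located (Scott plug-in bandwidth,
512-point grid; `largest_mode` for FLAIR, `last_mode` available for the
T1 convention), the stripe is the set of voxels between the empirical
quantiles `F(mode) ± tau` (default `tau = 0.05`, the originating
method's published default), and the volume is standardized voxelwise
as `(I − μ_ws) / σ_ws`. Because the stripe is defined through
quantiles, the transform is equivariant under positive affine intensity
changes — the property the test suite checks. A two-contrast hybrid
entry point intersects the stripe masks of two volumes; since only
FLAIR feeds feature extraction, the single-contrast FLAIR stripe is the
pipeline default. The brain mask defaults to the union of all
non-background parcellation labels when no explicit mask is supplied.

## The 1,618-feature vector

Per ROI, with default configuration:

| block | count |
|---|---|
| original image, first-order | 17 |
| original image, shape | 7 |
| original image, texture (GLCM + GLRLM) | 162 |
| 8 wavelet sub-bands × (17 first-order + 162 texture) | 1,432 |
| **total** | **1,618** |

Shape descriptors are geometric properties of the binary mask and are
only computed on the original grid, never on sub-bands — this is what
reconciles the 17 + 162 + 1,432 family arithmetic with the 1,618 total.

**Discretization.** Texture and histogram features use fixed-bin-number
quantization (default `N_g = 32`) over the ROI's own [min, max]:
`level(x) = min(N_g, floor(N_g (I − min)/(max − min)) + 1)`; a constant
ROI maps to level 1. Fixed bin number (rather than fixed bin width) is
the natural choice for inputs already on the stripe-standardized
z-like scale, and each wavelet sub-band is re-discretized
independently over its own range.

**First order (17).** Mean, median, min, max, range, population
variance, SD, skewness, kurtosis, energy, RMS, mean absolute deviation,
entropy (base-2 over the `N_g`-level histogram), uniformity, 10th/90th
percentiles, IQR. Kurtosis is the raw fourth standardized moment (not
excess); skewness/kurtosis of a constant ROI are defined as 0 so
degenerate ROIs never produce NaN. Percentiles interpolate linearly
between order statistics.

**Shape (7).** Voxel-count volume, face-count surface area (the boxy
exposed-face surface, deliberately not a marching-cubes mesh),
surface-to-volume ratio, sphericity, compactness, spherical
disproportion, and maximum 3D diameter (largest pairwise voxel-centre
distance; computed on the convex hull for large masks). Note the
face-count surface of a digitized ball exceeds the smooth sphere's
area by a constant factor, so sphericity of a ball plateaus below 1 —
a property of the estimator, not a bug.

**GLCM (23 features × 2 aggregations × 3 distances = 138).**
Co-occurrence matrices over the 13 unique 3D directions at integer
offsets `distance × direction`, distances 1–3 voxels, counting only
pairs wholly inside the mask, symmetrized and normalized. Features
follow the IBSI reference formulas. Two aggregations are reported:
`avg` (feature per direction, averaged) and `mrg` (directional counts
merged, renormalized, feature computed once). Degenerate matrices give
defined fallbacks (0 for entropy-like, 1 for energy-like quantities).

**GLRLM (12 features × 2 aggregations = 24).** Maximal same-level runs
wholly inside the mask, per direction. Merged aggregation sums run
counts over directions; merged run percentage divides by
`13 × N_voxels`. Totals: 138 + 24 = 162 texture features, matching the
three-distance, two-aggregation decomposition.

**Wavelet (8 × 179 = 1,432).** Single-level *undecimated* separable
decomposition: low/high-pass filter taps (coiflet-1 by default, from
PyWavelets) applied along each axis by centred circular correlation.
Band letter *k* is the filter along array axis *k*. Undecimated rather
than decimated, so masks carry over unchanged and no ill-defined
mask-halving step is needed; circular (periodic) boundary handling
makes the transform exactly shift-equivariant, which the tests
exploit. Each band re-enters the first-order and texture engines.

Feature names follow `<image>_<family>[_<dist>][_<agg>]_<feature>`
(e.g. `wavelet-LLH_glcm_d2_mrg_contrast`); model artifacts reference
features by name, so extraction-order changes cannot silently corrupt
predictions.

## Contrasts, filtering, and the laterality model

**Design.** Two contrasts mirror a 36-patient / 50-control
case-control design: `H_plus` (hippocampal ROI) and `H_minus`
(extrahippocampal temporal ROI). Positives are the affected-side ROI
rows of patients; negatives are the patients' unaffected-side rows plus
one hemisphere per control, chosen uniformly at random with a fixed,
logged seed. The pairing between a patient's two hemispheres is
ignored (independent two-sample *t*), which matches the 36-vs-86
construction; the resulting mild dependence among negatives is a known
statistical limitation.

**Filtering.** Pooled-variance two-sample Student *t* test per feature,
Benjamini–Hochberg step-up adjustment, pass at `q < 0.05`. If nothing
survives (e.g. a null cohort), training proceeds on all
finite-variance features so the pipeline still completes — typically
yielding an (almost) intercept-only model.

**Elastic net.** Penalized logistic regression on standardized
features (training-set statistics only, frozen into the model
artifact; zero-variance columns dropped and logged):

    −(1/n) Σ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)]
        + λ [ (1−α)/2 ‖β‖₂² + α ‖β‖₁ ],   p = σ(β₀ + βᵀz)

with an unpenalized intercept. Optimization is delegated to
scikit-learn's saga solver (`C = 1/(nλ)`, `l1_ratio = α`), followed by
a one-dimensional Newton polish of the intercept: when the penalty
dominates, saga's stopping rule can halt before the (unpenalized)
intercept reaches its optimum, and the polish restores the exact
fully-penalized limit `β = 0, β₀ = logit(ȳ)`.

**Tuning.** Stratified 10-fold cross-validation minimizing the mean
squared error between predicted probability and the 0/1 label
(probability-scale MSE, not deviance). The default search space is a
21-point α grid (0, 0.05, …, 1) with a 100-point λ path per α,
log-spaced four decades down from the glmnet-style `λ_max` (the
smallest penalty that zeroes all coefficients). Ties prefer larger λ,
then larger α (parsimony). The filter and the penalized fit run on the
same full training set — the two-step structure is not nested inside
CV, so training-set performance estimates carry optimistic bias;
honest evaluation uses independent held-out cohorts.

**Evaluation.** AUC is the Mann–Whitney pair-ordering probability
(ties ½). The operating threshold maximizes sensitivity + specificity
(Youden) over midpoints between adjacent distinct scores, lowest
maximizer on ties, positive call at score ≥ threshold. Confidence
intervals are stratified percentile bootstrap (2,000 replicates
default, seeded). Per-patient laterality is the hemisphere with the
larger model score; exact ties are "indeterminate".

## The phantom generator

The generator produces FLAIR-like cohorts with the statistical
structure the analysis assumes, not anatomically realistic brains:

* a brain ellipsoid of base intensity 100 with mirrored ellipsoidal
  "hippocampi" and shell-like "temporal" regions (base +5), labelled
  with FreeSurfer/Desikan-Killiany IDs so the shipped grouping table
  applies unchanged; remaining brain voxels carry a white-matter label
  and feed the stripe estimate;
* a Gaussian random field realized as kernel-smoothed white noise
  (kernel σ = correlation length ℓ, in mm; marginal SD `noise_sd = 5`
  intensity units, default ℓ_null = 1 mm) plus iid voxel noise
  (SD 1);
* in patients, the two affected-side ROIs receive an intensity shift
  `δ × noise_sd` (default δ = 2) and a field smoothed with
  ℓ_affected = 3 mm — a 3:1 correlation-length ratio that lowers
  voxel-level heterogeneity and moves entropy/co-occurrence features,
  the planted analogue of the textural laterality signal the models
  are built to detect.

Both correlation lengths smooth the *same* white-noise draw. This
matters: with an independent draw, the affected ROI's field is
discontinuous with its surroundings at the ROI boundary, and the
global wavelet convolution turns that seam into a class signal even at
δ = 0. Sharing the draw makes δ = 0 with equal correlation lengths an
*exact* voxelwise null (a "patient" is then generated identically to a
control), which is what the null-cohort acceptance check relies on.

What the phantom does **not** emulate: anatomy, partial-volume
effects, bias fields, scanner noise physics, inter-subject anatomical
variability (all subjects share one label map). Passing tests
therefore demonstrate the correctness and statistical sanity of the
machinery, not clinical performance on real FLAIR data.

## Problem sizes for the repeated studies

The default phantom grid is 64×64×48 at 1 mm (full pipeline on one
subject ≈ 1 s). The repeated end-to-end studies in
`lateromics.experiments` use a 40×40×28 grid (ROI geometry scales with
the grid), cohorts of 8 patients + 8 controls for training and an
independently seeded 8 + 8 cohort for evaluation, and a reduced CV
budget (α = 0.5, 10-point λ path over two decades) — sizes chosen so a
multi-seed study completes in minutes while leaving the planted effect
at δ = 2 overwhelming (held-out AUC ≈ 1). Under the null, a single
held-out design has 8 positives vs 24 negatives, so one AUC has
standard deviation ≈ 0.12 around ½; exchangeability is therefore
checked on the across-seed mean, whose standard error is ≈ 0.04.

## Known limitations

* The univariate filter is not nested inside cross-validation
  (training-set optimism; held-out cohorts are the honest estimate).
* Negatives mix a patient's unaffected hemisphere with control
  hemispheres and ignore within-patient pairing.
* The face-count surface area overestimates smooth surfaces by a
  shape-dependent factor; it is the documented contract, chosen for
  exactness on voxel geometry.
* Saga's convergence at very small λ on highly correlated feature
  blocks is approximate at the reduced tolerances used in repeated
  studies; the CV ranking is insensitive to this, and the tests that
  check optimizer contracts use tight tolerances.
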
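# Methods

## The prediction problem

Deciding whether a prostate-cancer patient harbours pelvic lymph node
metastases (PLNM) drives the choice between radical prostatectomy alone and
surgery with extended node dissection.  Conventional MRI criteria (node
short-axis thresholds) are specific but insensitive, which motivates
radiomics: high-dimensional quantitative descriptors of the primary lesion
on biparametric MRI (T2-weighted imaging plus the ADC map derived from
b = 100 and b = 1000 s/mm² diffusion acquisitions, ADC = ln(S₁₀₀/S₁₀₀₀)/900).

The package's central method is a **cross-tissue correlation filter**:
because nodal metastases derive from cells shed by the primary lesion, a
lesion feature whose values track the matching metastatic-node feature
across PLNM-positive patients is treated as carrying the metastatic
signature.  Two classifier arms make the idea testable — the *lesion* arm
(t test + LASSO selection only) and the *lesion-correlation* arm
(correlation filter first) — compared by a paired DeLong test on the same
validation cases.

## Feature extraction

One VOI yields 3748 features: per modality, 14 shape features (original
image only) plus, for each of 20 bank images, 18 first-order and 75 texture
features (24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM).  Settings and the
numerical conventions they entail:

* **Normalization** — whole-image z-score times 100 (region-based
  statistics available via the `mask` argument).  Applied before cropping so
  it cannot depend on the crop box.
* **Cropping** — features are computed on the mask's bounding box padded by
  10 voxels.  All per-voxel quantities that feed features are crop-invariant
  by construction: filter supports (LoG truncated at 4 sigma ≤ 6 voxels,
  wavelet/gradient/LBP radius 1) fit inside the pad, and the pointwise
  transforms take their shift/rescale constants from the masked voxels
  rather than the crop extrema.  A test asserts pad-10 and pad-16 crops give
  identical features.
* **Discretization** — fixed bin width 25 on the masked intensities;
  `level = floor((x − min)/25) + 1`, with a masked maximum on a bin edge
  opening a new top bin.  Invariant to adding a constant to the image.
* **Voxel-array shift 300** — added to intensities only inside Energy,
  TotalEnergy and RootMeanSquared, keeping those magnitude features positive
  for z-scored images; all other first-order features see raw intensities.
* **Filter bank** — LoG uses spacing-aware sigma in mm and is DC-corrected
  so constants map to exactly zero, then scale-normalized by sigma².  The
  wavelet is a single-level *stationary* (undecimated) Haar transform, so
  all eight sub-bands live on the original grid; odd extents are
  mirror-padded to even before the transform.  The pointwise transforms are
  monotone with range handling (shift to non-negative before log/sqrt,
  rescale to the input's maximum magnitude; constants map to constants).
  LBP-3D compares each voxel with its 26 sphere-sampled neighbours and
  summarises the binary pattern rotation-invariantly by its dipole (m1) and
  traceless-quadrupole (m2) energies plus a local-kurtosis map (k, sentinel
  0 on flat neighbourhoods); the three-map contract, determinism and
  invariances are the specification — numeric parity with any particular
  implementation is not.
* **Texture conventions** — GLCM and GLRLM use the 13 unique distance-1
  directions and average *feature values* over directions (not merged
  matrices); GLSZM zones are 26-connected; NGTDM/GLDM use the full
  26-neighbourhood; GLDM dependence is the count of neighbours within
  alpha = 0 gray levels, with dependence size j + 1 in the formulas so
  isolated voxels have size 1.  Degenerate single-level regions report
  Correlation = MCC = 1 (perfect dependence), NGTDM Coarseness saturates at
  10⁶, and first-order Skewness/Kurtosis are 0 at zero variance.  Every
  family is verified against an independent plain-loop enumeration oracle on
  random volumes (≤ 6³, ≤ 8 levels).
* **Shape** — marching-cubes mesh (level 0.5, physical spacing) for volume,
  area, sphericity and the maximum-diameter features; axis lengths are
  4·sqrt(eigenvalue) of the physical coordinate covariance.  Point-like
  masks report Elongation = Flatness = 1.
* **Multiple nodes** — a positive patient can have several metastatic
  nodes; the study does not state its aggregation rule.  Default: extract
  from the largest node by voxel volume; a `mean` policy (feature-wise
  average over nodes) is available.  Shape features are emitted per modality
  (duplicated values), which is what makes the per-modality count 1874.

## Selection and modelling

Standardization (train-set mean/sd; zero-variance features dropped) precedes
selection.  The correlation filter uses PLNM-positive training cases only —
nodes exist only there — and |r| rather than signed r, since anticorrelation
is equally informative; signed and "any node feature" pairing modes exist
because the study's wording fixes neither.  The t test defaults to Welch's
variant (robust to unequal variances; the equal-variance option reproduces
textbook values).  LASSO is an L1-penalized logistic model solved by
liblinear at tolerance 1e-7; the penalty grid is 25 log-spaced values and
the CV criterion is mean binomial deviance over 5-fold CV repeated 5 times,
ties broken toward the stronger penalty (sparser model).

The SVM is RBF-kernel with C ∈ {0.1, 1, 10, 100} and gamma = (scale
heuristic) × {0.1, 1, 10}; the kernel/grid are package choices, as the study
names neither.  SMOTE (synthetic minority oversampling: convex combinations
of a minority sample and one of its k = 5 nearest minority neighbours)
balances classes *inside each training fold*, never on validation folds —
oversampling before splitting would leak synthetic copies of validation
neighbours into training.  The decision threshold is Youden's J on the
training ROC.  A mutation test asserts no leakage end-to-end: perturbing
validation rows leaves the fitted model bit-identical.

## Evaluation

AUC is the Mann–Whitney estimator with midranks (ties count half).  CIs and
the paired test use DeLong structural components: per-positive V₁₀ and
per-negative V₀₁ computed via midranks, variance s₁₀/m + s₀₁/n, paired
z = (AUC_a − AUC_b)/sqrt(var_a + var_b − 2cov), two-sided normal p.  The CI
is on the AUC scale (no logit transform), truncated to [0, 1].  Correctness
checks: exhaustive tiny-case variance identities, a 10⁵-replicate stratified
case-resampling bootstrap oracle for the paired p (agreement within 0.02 at
n = 30), and ~95% empirical CI coverage over 1000 binormal simulations at
true AUC 0.8.

## Synthetic cohorts

The source cohorts are private two-hospital data, so generators emulate the
study's statistical structure; all headline numbers in this repository are
therefore *qualitative* reproductions (ordering and significance direction),
not re-derivations of the clinical values.

**Feature-table generator** (`simulate_feature_tables`) — study-shaped
splits (263 train with 93 positives, 74 internal, 57 external at the study
prevalences; labels assigned exactly, not sampled).  Of `n_features = 500`
columns, `n_informative = 20` form the planted signature: jointly Gaussian
with (a) a 0.8-SD mean shift in positives on the lesion side, (b)
cross-tissue correlation 0.95 between matching lesion/node columns across
positives (via shared latents, a Gaussian copula with normal marginals), and
(c) within-tissue equicorrelation 0.7 among signature features.  The last
reflects how radiomic signatures behave — their features measure one
underlying phenotype and typically correlate 0.6–0.8 within a cluster — and
keeps the benchmark classifiers in the mid-AUC regime (≈ 0.65–0.8) of the
clinical problem; twenty *independent* 0.8-SD features would drive both arms
to AUC ≈ 1 and erase the contrast the benchmark exists to measure.
Non-informative columns are independent noise in both tissues.

**Image-phantom generator** (`simulate_cohort`) — 48³ voxel grids at 1 mm
(64³ available via config): ellipsoidal lesions with Gaussian-random-field
texture on T2 and a ~400-unit ADC deficit; positive cases add 1–2
ellipsoidal nodes whose middle principal axis (the radiological short-axis
diameter) meets the ≥ 15 mm rule.  Positives draw lesion and node texture
amplitude/correlation-length from a shared case latent, so extracted
features correlate across tissues.  The phantoms exercise pipeline
mechanics — I/O, alignment, masking, the full feature space — not task
difficulty: at default settings the image-level classification task is
nearly separable, so end-to-end image runs saturate near AUC 1 and the
calibrated arm comparison is the feature-table benchmark.  What the phantoms
deliberately lack: anatomy, MR physics (bias fields, coils), registration
error, and segmentation variability; passing tests on them says nothing
about those failure modes on clinical data.

## Problem sizes and reproducibility

The test suite and acceptance script use desk-scale sizes chosen to finish
in minutes on one CPU: full-bank extraction on single 64³ phantom cases,
oracle checks on 100 random ≤ 6³ volumes, 20 simulation seeds for the
correlation-filter recovery and the two-arm benchmark, 1000 simulations for
CI coverage, 10⁵ bootstrap replicates for the DeLong oracle.  Every stochastic
component is seeded: a master seed fans out to per-stage seeds by fixed
offsets, and reruns of the pipeline are byte-identical (asserted in tests).

## Known limitations

* Registration is resampling-only (identity transform); estimating rigid or
  deformable transforms is out of scope.
* LBP-3D is a self-contained design honouring the three-map contract, not a
  numeric clone of any particular implementation.
* The LASSO 1-SE rule is off by default; the CV-minimum penalty is used.
* Model files are pickles plus JSON metadata; no cross-version model format.
* The study's reported internal-validation prevalence (26.7%) is
  inconsistent with its reported counts (19/74 = 25.7%); the package reports
  the recomputed value.
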
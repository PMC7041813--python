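# Methods

This note documents the models, conventions and numerical choices behind
`petrad`, in the order of the pipeline stages.

## Synthetic phantoms

The phantom generator stands in for PET scans of primary NSCLC tumours.
A lesion is a random ellipsoid (log-uniform semi-axis ratios, random
orientation) whose radius field is modulated by a smooth quadratic angular
perturbation; the iso-level is chosen by rank so the realized voxel support
matches the requested volume to within one voxel layer. Inside the lesion,
heterogeneity is a Gaussian random field — white noise convolved with a
Gaussian kernel whose sigma equals the requested correlation length — scaled
to the requested SUV standard deviation and added to the base uptake. The
lesion is blended into a mildly noisy ~1 SUV soft-tissue background through a
smoothed support (an edge reminiscent of partial-volume blur), and the VOI is
a 2-voxel dilation of the support.

Defaults are chosen to resemble a locally advanced NSCLC population on a
4 mm isotropic reconstruction: lesion volume 62 cc (population median
metabolic volume; per-patient values log-normal with log-SD 0.65, floored at
the 10 cc study-exclusion limit), base uptake SUV 9 with log-SD 0.3 (SUVmax
then lands near the 11–15 range typical of such cohorts), texture correlation
length 8 mm and amplitude 15% of base uptake, background SUV 1.

**Repeat pairs.** Two scans of the same phantom differ by (i) independent
additive Gaussian voxel noise (default SD 0.4 SUV) and (ii) a sub-voxel rigid
shift of the second scan (default (1.0, −0.8, 0.6) mm), resampled trilinearly
— emulating the noise and residual-motion differences between even- and
odd-phase mid-position reconstructions. No deformable motion is simulated.
The magnitudes are free parameters of the generator, not estimates of any
particular scanner; they were fixed once at values that leave most features
repeatable while making noise-sensitive ones (e.g. NGTDM Busyness) fail, which
is the regime the selection stage is designed for.

**Cohorts.** Each patient draws lesion size/uptake and clinical covariates:
age ~ Normal(65, 8) truncated to [36, 87]; gender Bernoulli(0.6 male);
histology over {adeno, squamous, large-cell, NOS/other} at (35, 36, 5, 24)%;
T stage 1–4, N stage 0–3 and overall stage IIB–IIIC with marginals loosely
matching stage-III-dominated CCRT cohorts. GTV is set to the VOI volume.
Binary endpoints (2-year OS, 2-/1-year PFS, 1-year LRS, 1-year DMS) are drawn
from a logistic model: standardized planted predictors times planted
coefficients plus a per-endpoint intercept chosen so prevalences sit near
(40, 29, 50, 58, 54)%. The default planted truth puts coefficients
(−0.9, 1.1, −1.0, 0.8) on Age, Sphericity(MTV2.5), GLCM ClusterTendency and
GLCM JointEntropy (both MTV2.5/bin-count), a scale that yields an oracle AUC
(true linear predictor vs realized labels) of ≈ 0.85 at n = 252 — a planted
signal strong enough to be recoverable yet realistically imperfect. The true
linear predictor is returned for oracle comparisons. Seeding: patient *i*
uses `SeedSequence(master, spawn_key=(i,))`, so enlarging a cohort never
reshuffles existing patients.

**What the generator does not emulate:** scanner physics (PSF, reconstruction
iterations, count statistics), deformable respiratory motion, multi-centre
protocol differences, and any real biological coupling between image texture
and outcome. Passing tests therefore demonstrate that the *pipeline* is
correct and well-calibrated, not that any particular feature is prognostic in
real patients.

## Segmentation and discretization

* Absolute rule: SUV strictly **>** 2.5 ("above"); an all-threshold VOI is an
  error. Relative rule: SUV **≥** 0.40 × SUVmax ("at least"), so the maximum
  voxel is always included. Both are pure thresholds within the VOI — no
  largest-connected-component filtering.
* Volumes: MTV as voxel count × voxel volume (cc); the mesh volume appears
  only as the shape feature MetabolicTumourVolume.
* Fixed bin width (0.25 SUV): raw bin of value s is ⌊s/0.25⌋+1, anchored at
  SUV 0 for cross-patient comparability; occupied raw bins are compacted to
  consecutive levels 1..Ng for matrix construction with the raw-bin map
  retained. Ng grows with the SUV range; the scheme is deliberately not
  scale-invariant.
* Fixed bin count (64): equal-width bins over the in-mask [min, max]; values
  on an internal edge go up; the maximum is clamped into bin 64. A constant
  ROI degenerates to Ng = 1 with a warning.

## Feature definitions

All 105 features per configuration follow the standardized (IBSI-style)
definitions; entropies are log₂ (bits).

* First-order (18): computed on raw SUVs except Entropy and Uniformity, which
  use the discretized levels. Population moments; Kurtosis is non-excess.
  Degenerate constant ROIs take Skewness = Kurtosis = 0. TotalEnergy uses the
  voxel volume in mm³.
* Shape (13): iso-surface mesh of the binary mask via marching cubes at level
  0.5 after Gaussian pre-smoothing of 0.8 voxels — the smoothing suppresses
  the staircase artefact that otherwise inflates the surface of a digital
  sphere by ~8% while moving the 0.5-level-set volume by only ~2% (a mask too
  small/thin to survive smoothing is meshed unsmoothed). Sphericity =
  (36πV²)^⅓/A. Axis lengths are 4√λ from PCA of physical voxel centres;
  Elongation = √(λ₂/λ₁), Flatness = √(λ₃/λ₁) (single-voxel masks take the
  limit 1). 2D diameters are maximal point-pair distances among surface-voxel
  centres within planes perpendicular to each axis.
* Texture (74): all five matrices are merged over the 13 unique direction
  vectors at Chebyshev distance 1. GLCM counts are pooled over all 13 offsets
  and symmetrized (each ordered pair counted once per direction sense).
  GLRLM runs are counted per direction and the matrices summed;
  RunPercentage's denominator is 13 × voxel count accordingly. GLSZM zones
  are 26-connected; GLDM uses the 26-neighbourhood at zero gray-level
  tolerance with the centre voxel counted in the dependence size; NGTDM uses
  the mean over available in-mask neighbours (isolated voxels count in nᵢ
  but contribute 0 to sᵢ). Degenerate single-level ROIs take documented
  limiting values: GLCM Correlation, Imc2-complement and MCC → 1,
  NGTDM Contrast/Busyness/Complexity/Strength → 0, Coarseness capped at 10⁶.

**Registry expansion.** 74 texture × 4 configurations + Entropy/Uniformity
× 4 + 16 remaining first-order × 2 masks + 13 shape × 2 masks = 362; the
canonical registry emits first-order Maximum (= SUVmax, identical across
masks by construction) and Minimum (pinned to the segmentation rule itself:
≈ 2.5 under the absolute rule, ≈ 0.4·SUVmax under the relative rule) once
each, giving exactly 360 entries including SUVmax, MTV2.5 and MTV40 as
distinct features.

## Repeatability and independence

* CR = 1.96 × SD(paired differences) with sample (n−1) SD; the equivalent
  2.77 × within-subject-SD formulation is a config switch. %CR divides by the
  absolute grand mean of the two arms' per-patient averages — symmetric in
  the scans and defined for sign-flipping features; |mean| < 10⁻⁸ is flagged
  not-assessable and fails. Cut-off 30% (15% alternative).
* Independence is evaluated on arm A of the repeat pair. Each feature is
  tested against SUVmax and against the MTV of its own mask configuration,
  with average-rank tie handling; |ρ| ≥ 0.5 discards (0.7 alternative).
  SUVmax, MTV2.5 and MTV40 themselves are exempt — they are the established
  baseline the filter protects, remain available to the models, and would
  otherwise discard themselves trivially. Constant features fail by
  convention.
* Elbow diagnostic: average-linkage clustering on 1 − |ρ|; the tree is cut at
  k = 1..n, total within-cluster dissimilarity W(k) tracked, and the elbow
  placed one past the last cut whose reduction reaches 10% of the largest
  reduction. Fewer than 3 features return k = n. This is a diagnostic, not a
  hard filter.
* Selection is the per-configuration intersection of the two pass sets, with
  a full audit trail; an empty selection is legal (models then fall back to
  clinical variables).

## Prognostic models

* Elastic-net logistic regression with mixing parameter α = 0.5 (the value is
  configurable; the penalty is α‖β‖₁ + (1−α)/2·‖β‖₂², glmnet convention).
  The penalty strength is chosen on a log-spaced path (50 values by default)
  by minimal 20-fold cross-validated deviance on the training part only.
* Each repetition draws a stratified 80/20 split (stratification avoids
  single-class validation folds at ~20–30% prevalences), re-fits
  standardization statistics on the training part only (no leakage), fits,
  and scores the validation AUC (rank-based, ties ½). Degenerate splits are
  retried with fresh sub-seeds (≤10 attempts). 100 repetitions by default.
* Families: `rad` (selected radiomics), `clin` (age, GTV, gender binary,
  T/N ordinal, histology and stage dummy-coded against the most frequent
  category), `all` (union). Missing values are an error — no imputation.
* Families are compared by two-sided Mann–Whitney U on the AUC samples
  (all-tied samples return p = 1), significance at p < 0.05. Predictors are
  ranked by nonzero-coefficient frequency, ties broken lexicographically.
* External validation applies the best-performing repetition's model (highest
  internal validation AUC; the median-AUC model is a config alternative) with
  development-data standardization to a held-out cohort.

## Problem sizes

Defaults mirror the study design (repeat cohort 70, development cohort 252,
external 40, 100 repetitions, 20 folds). The test suite and the acceptance
script run scaled-down versions of the stochastic stages — e.g. 20–40
patient repeat cohorts on 32³ grids, 10–30 model repetitions with 5–10 CV
folds and 8–10 penalty values — sizes at which every calibration property
checked (null AUC ≈ 0.5, CR ratio ≈ 1, planted-signal recovery) is already
stable. The oracle-equivalence suite uses ≥100 random ROIs of ≤6³ voxels at
Ng ≤ 6, where brute-force enumeration is exact and fast.

## Known limitations

* The mesh-smoothing sigma trades surface fidelity against volume fidelity;
  very small (≲ 2 voxel) or single-voxel-thin masks fall back to unsmoothed
  meshing and carry the staircase bias.
* GLRLM/GLSZM matrices are stored dense; pathological ROIs with very long
  runs/zones (≫10⁴ voxels at Ng = 1) are memory-heavy.
* The saga solver's CV path is refitted per penalty value; at the default
  100 repetitions × 20 folds the full pipeline is minutes-scale, not
  seconds-scale.
* Synthetic endpoints are generated from linear logistic truth on
  standardized features; non-linear or interaction-driven prognostic signal
  is out of scope for the generator (and for the elastic net itself).
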
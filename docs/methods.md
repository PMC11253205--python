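# Methods

This note documents the models, parameters and numerical choices behind
`svrlsm`, and what the synthetic-data experiments do and do not show.

## The mapping model

SVR-LSM treats lesion-symptom mapping as one multivariate regression
instead of a mass of univariate voxel tests. All retained voxels enter a
single ε-support-vector regression of the (volume-corrected) one-vs-rest
subtype outcome on the (volume-corrected) binary lesion matrix X
(subjects × voxels). The fitted model lives in kernel space; its weight
vector is backprojected onto voxel axes as

    β_j = Σ_i α_i X′_ij,

summing signed dual coefficients over support subjects. For a linear
kernel this is exactly the primal weight vector (strong duality; the
test suite checks the identity against an independent primal QP solve at
1e-6). For the RBF kernel it is the standard sensitivity-map projection
of this method family. The map is descriptive, not causal: a voxel's β
measures how much its lesion status moves the fitted prediction,
jointly with all other voxels.

Signs: the target subtype is coded +1, so positive β means lesion
presence pushes the prediction toward the subtype. Displayed z maps are
negated (`BetaMap.display_z`) to follow the field's convention that
*lower* z marks *higher* subtype occurrence.

### Lesion-volume correction

Large tumors cover more voxels and, unchecked, any subtype with slightly
larger tumors would "map" everywhere. Both X (columnwise) and y are
replaced by OLS residuals on [1, v], v = whole-tumor volume in cm³. The
residual operator is a projection: idempotent, exactly decorrelating
(sample covariance with v is 0 to machine precision), and invariant to
rescaling v. A constant-volume cohort degenerates to mean-centering
(with a warning).

### Hyperparameters

C and γ are chosen by Bayesian optimization of the 5-fold
cross-validated mean squared prediction error over a log10 box (default
[1e-3, 1e3]²): a Matern-5/2 Gaussian process is fit to observed
(log10 C, log10 γ) → loss points and each iteration evaluates the
expected-improvement maximizer over a seeded candidate cloud (200
iterations by default at full scale). Folds are fixed across
evaluations so losses are comparable; the whole procedure is
deterministic given the seed.

One property of this objective deserves honesty: on binary lesion data
the CV-error optimum sits at small γ (a nearly linear, heavily smoothed
kernel), which predicts best but yields low-contrast beta maps — while
the conventional fixed settings of this method family (C = 30, γ = 5 on
raw binary lesion vectors, an almost-diagonal kernel) yield sharper maps
with far better voxelwise detection of planted effects. Prediction
accuracy and map power are different objectives. The package exposes
both: `SvrLsmConfig()` defaults to `C="optimize", gamma="optimize"`;
`toy_config()` (used by the desk-scale simulations) fixes C = 30, γ = 5.
Permutation calibration is valid for any *fixed* hyperparameter choice,
because observed and permuted data are processed identically.

### Cross-validated averaging

Subjects are split into 5 seeded folds, stratified by outcome group so
unbalanced contrasts cannot produce single-class training folds (if a
group is smaller than the fold count, stratification falls back to plain
folds; a single-class training fold triggers one reshuffle, then an
error). Each fold's β map is backprojected from its training fit only;
the 5 maps are averaged arithmetically and standardized (sample SD)
into z.

## Permutation inference

The residualized outcome is permuted B times (B = 10 000 at full scale),
the full fold-averaged map is recomputed with hyperparameters fixed at
the observed-data values, and each voxel gets the add-one estimator
p = (1 + #{extremity ≥ observed}) / (B + 1), two-sided on |β| by
default (one-sided tails are available). Add-one keeps p ≥ 1/(B+1) and
the test level-valid. When the number of distinct label arrangements is
below B (tiny cohorts), all arrangements are enumerated instead and the
classical exact p = count/N is returned, with the observed map taken
from the identity arrangement of the same pipeline.

Two implementation details matter for exactness:

* **Independent streams.** The permutation stream is seeded as
  `default_rng([tag, seed])` with a component-specific tag. Seeding the
  cohort generator and the permutation engine with the same bare integer
  makes "random" permutations correlated with the data and visibly
  miscalibrates the test — a failure mode we measured and designed out.
* **Thresholds at small B.** p < .005 requires B ≥ 200 to be reachable
  at all; at B = 300 only count-0 voxels pass. Small-B runs are
  intentionally strict, not broken.

Significant voxels (p < .005) are labeled into connected components
(6/18/26-connectivity; 26 by default) and components below the minimum
extent (100 voxels at full scale, 30 on the toy grid) are discarded;
survivors are labeled in decreasing size order, peaks at maximum |z|
(ties to the lowest linear voxel index).

## Cluster reporting

Each cluster is expressed as atlas-region percentages
100·|cluster ∩ region|/|cluster| at one decimal, sorted descending.
Atlas-background voxels inside a cluster are reported as "unlabeled"
rather than renormalized away, keeping the ~100% row-sum honest. The
atlas is user-supplied NIfTI + CSV (widely used atlases have license
constraints); the repo generates only toy parcellations.

## The synthetic cohort generator

The generator emulates the structure of a molecular-subtype glioma
cohort; it is the test bed for every downstream stage.

* **Subtype mix**: proportions 40.7 / 33.8 / 18 / 7.6% (RTK II / MES /
  RTK I / other), allocated by largest-remainder rounding so a
  423-subject cohort reproduces the reference counts 172/143/76/32
  exactly (multinomial allocation is available). Proportions are
  accepted within 5e-3 of summing to 1 because published percentages are
  rounded, and are renormalized before allocation.
* **Volumes**: per-subtype lognormals parameterized as (median cm³,
  geometric SD), derived from published mean ± SD whole-tumor volumes
  (87±60, 89±61, 82±59 cm³; "other" uses the pooled scale 86±60 as it is
  not reported separately). The toy grid uses median 4 cm³, GSD 1.5 —
  the same ~15% of brain support that a ~85 cm³ tumor occupies at full
  scale.
* **Lesion shape**: stochastic region growing from a seed voxel —
  uniformly annexing 6-neighbor frontier voxels inside an ellipsoidal
  support — which produces connected, blob-like, volume-exact masks.
  This matches the gross topology of tumor masks, nothing more: no
  white-matter tracts, no mass effect, no intensity model, no spatial
  covariance between compartments.
* **Planted effects**: with relative odds `strength`, a subtype's lesion
  seeds in a target region with probability strength/(1+strength),
  otherwise uniformly across regions (the target included, so the exact
  seeded fraction is p + (1−p)/R). `strength = 0` is an exact null:
  location independent of subtype.
* The toy atlas is a seeded Voronoi parcellation of the ellipsoid;
  cells are convex-set intersections, hence connected.

**What passing tests show**: the pipeline's arithmetic, contracts and
frequentist calibration are correct, and a strong planted predilection
(odds 6, n = 80) is recovered as a cluster with Dice ≥ 0.3 in ≥ 8/10
replicates. **What they do not show**: performance on real lesion
geometry, registration error, segmentation noise, or subtler effect
sizes — the generator's uniform background and convex regions are far
cleaner than brains.

## Problem sizes and Monte-Carlo error

Desk-scale experiments run on a 20×24×20 grid at 2 mm (≈3.6k-voxel
support), n = 80, 300–500 permutations, minimum overlap 5, minimum
extent 30 — sizes chosen so the full suite runs in minutes while keeping
every pipeline stage nontrivial. Because retained voxels are strongly
correlated (lesions are extended blobs), the realized false-positive
fraction of a *single* null cohort scatters widely around its
expectation; calibration is therefore assessed as the mean over 10
independent null cohorts, which the acceptance suite requires to lie in
[0.002, 0.009] around the nominal 0.004 at p < .005 with B = 500.

## Known limitations

* Full-scale runs (139k voxels, 423 subjects, 200 hyperopt iterations,
  10 000 permutations) are supported by the same code paths but take
  hours on one CPU; the Gram-matrix cache makes permutations cheap, but
  the kernel distance matrix itself is O(n²·V).
* The hyperopt objective is prediction error, not map reproducibility;
  see the honesty note above.
* Covariates beyond lesion volume (age, sex) are out of scope, as are
  classification-SVM variants, TFCE/cluster-mass inference, and
  anatomically realistic tumor growth.
* Hemisphere assignment of clusters is not a separate rule; it is
  readable off the atlas-region names.
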
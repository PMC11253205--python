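# svrlsm — multivariate lesion-symptom mapping for tumor cohorts

`svrlsm` maps where in the brain a categorical per-patient label (for
example a DNA-methylation subclass of glioblastoma: MES, RTK I, RTK II)
preferentially occurs, from nothing but co-registered binary lesion masks
and the labels. It implements support-vector-regression-based
lesion-symptom mapping (SVR-LSM) with permutation inference, plus a
synthetic lesion-cohort generator so the whole pipeline can be exercised
and validated without access to patient imaging.

It is intended for neuroimaging researchers who have per-subject tumor
(or stroke) segmentations in a common standard space — e.g. MNI152 at
2 mm — and want voxelwise association maps that are multivariate (all
voxels enter one model), corrected for lesion volume, and thresholded
nonparametrically.

## The method

For one subtype analyzed against the rest of the cohort (one-vs-rest,
outcome y_i = 1 for the target subtype, else 0):

1. **Design matrix.** Binary masks are stacked into X (subjects ×
   voxels), keeping only voxels lesioned in at least *n* subjects
   (default n = 10) so isolated voxels cannot drive the map.
2. **Lesion-volume correction.** Each column of X and the outcome y are
   replaced by residuals from OLS on [1, v], v the whole-tumor volume,
   so tumor size cannot masquerade as location signal.
3. **ε-SVR with RBF kernel** k(a,b) = exp(−γ‖a−b‖²) is fit in the dual;
   the kernel-space weight vector is backprojected onto voxel axes:

       β_j = Σ_i α_i X′_ij   (over support rows)

   For a linear kernel this equals the primal weight vector exactly —
   the identity the test suite verifies against an independent QP solve.
4. **Hyperparameters** (C, γ) are chosen by Bayesian optimization
   (Gaussian process + expected improvement) of the 5-fold
   cross-validated squared error over a log-scaled box, or fixed by the
   user.
5. **Cross-validated map.** The SVR is refit on each of 5 stratified
   training folds; the 5 beta maps are averaged and standardized into a
   z map (for display, lower z = stronger subtype association).
6. **Permutation inference.** The outcome is permuted (hyperparameters
   fixed), the fold-averaged map recomputed each time, and each voxel
   gets an add-one p-value p_j = (1 + #{|β_perm| ≥ |β_obs|}) / (B + 1).
   Voxels with p < .005 are kept, then cleaned by a cluster-extent
   criterion (≥ 100 contiguous voxels at full scale).
7. **Anatomical reporting.** Each surviving cluster is expressed as
   percentages of a labeled atlas's regions ("insula 37.4%, ...").

## Worked example (synthetic cohort)

```python
import svrlsm

atlas = svrlsm.generate_toy_atlas((20, 24, 20), 8, seed=1)
spec = svrlsm.toy_spec(
    n_subjects=80, seed=0,
    planted_effects=[svrlsm.PlantedEffect("MES", 3, 6.0)],
)
cohort = svrlsm.generate_cohort(spec, atlas)
cfg = svrlsm.toy_config(n_permutations=300, seed=0)
res = svrlsm.run_subtype_analysis(cohort, "MES", atlas, cfg)
print(res.composition.to_string(index=False))
```

This plants a spatial predilection of the MES subtype for atlas region 3
(relative odds 6, i.e. ~86% of MES lesions seed there) in an otherwise
uniform 80-subject cohort, and prints:

```
 cluster_id  cluster_voxels    region  n_voxels  pct
          1             212 region_03       185 87.3
          1             212 region_02        21  9.9
          1             212 region_06         6  2.8
```

One significant 212-voxel cluster survives thresholding; 87.3% of it
lies in the planted region (Dice vs. the region: 0.47), with small
spill-over into two neighboring regions — exactly the kind of table a
real run produces for each subtype, with real atlas region names.
`res.retention` reports the overlap filter (here 3362 of 3639 lesioned
voxels retained, 92%), and `res.accounting` the subtype counts and
percentages (here 33/27/14/6 → 41.2/33.8/17.5/7.5%).

The same pipeline is scriptable from the shell:

```sh
svrlsm simulate --spec spec.yaml --out cohort/
svrlsm run --subjects cohort/subjects.csv --subtype MES \
           --atlas cohort/atlas.nii.gz --labels cohort/atlas_labels.csv \
           --config config.yaml --out result/
svrlsm report --result result/
```

For real data, point `--subjects` at a CSV of per-subject NIfTI masks
(already registered to a common space) and `--atlas` at any labeled
atlas volume with a label→name CSV.

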
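"""Atlas composition of significant clusters and the per-subtype pipeline.

The final deliverable of a lesion-symptom mapping run is, per subtype
contrast, a set of significant clusters described by their anatomical
composition: for each cluster, the percentage of its voxels falling in
each atlas region (e.g. "insula 37.4%, posterior temporal lobe 32.2%,
...").  ``run_subtype_analysis`` orchestrates the full chain from a
lesion cohort to that table.
"""

from __future__ import annotations

import json
import os
import platform
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    BetaMap,
    KernelCache,
    SvrLsmConfig,
    crossval_beta,
    make_contrast,
    optimize_hyperparameters,
    residualize_volume,
    resolve_gamma,
)
from .inference import ClusterMap, PermutationResult, permutation_test, threshold_and_cluster
from .lesion_matrix import (
    AccountingReport,
    RetentionReport,
    cohort_accounting,
    overlap_filter,
    stack_cohort,
)
from .synthetic_cohort import AtlasVolume, LesionCohort

__all__ = [
    "cluster_composition",
    "run_subtype_analysis",
    "SubtypeAnalysisResult",
    "StageError",
    "dice",
]

UNLABELED = "unlabeled"


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def _resample_labels_nn(labels: np.ndarray, factor: np.ndarray, new_shape) -> np.ndarray:
    from scipy.ndimage import map_coordinates

    tgt = np.indices(new_shape, dtype=float)
    coords = [tgt[a] * factor[a] for a in range(3)]
    return map_coordinates(labels, coords, order=0, mode="constant", cval=0)


def cluster_composition(
    clusters: ClusterMap, atlas: AtlasVolume, voxel_size_mm: float | None = None
) -> pd.DataFrame:
    """Per-cluster atlas-region percentages (1-decimal, descending).

    Returns a tidy frame with columns (cluster_id, cluster_voxels, region,
    n_voxels, pct).  Atlas-background voxels inside a cluster are reported
    as "unlabeled" rather than renormalized away, so each cluster's
    percentages sum to 100 within rounding.  Regions with zero voxels are
    omitted.  If grids differ, the atlas is nearest-neighbor resampled
    onto the cluster grid using the voxel-size ratio.
    """
    labels = atlas.labels
    if labels.shape != clusters.labels.shape:
        if voxel_size_mm is None:
            raise ValueError(
                "atlas and cluster grids differ; voxel_size_mm of the cluster "
                "grid is required for resampling"
            )
        factor = np.full(3, voxel_size_mm / atlas.voxel_size_mm)
        labels = _resample_labels_nn(labels, factor, clusters.labels.shape)
        if labels.shape != clusters.labels.shape:
            raise ValueError("atlas could not be resampled onto the cluster grid")
    rows = []
    for cid in range(1, clusters.n_clusters + 1):
        comp = clusters.labels == cid
        total = int(comp.sum())
        region_labels, counts = np.unique(labels[comp], return_counts=True)
        entries = []
        for lab, cnt in zip(region_labels, counts):
            name = UNLABELED if lab == 0 else atlas.names[int(lab)]
            entries.append((name, int(cnt), round(100.0 * cnt / total, 1)))
        entries.sort(key=lambda e: (-e[2], e[0]))
        for name, cnt, pct in entries:
            rows.append(
                {
                    "cluster_id": cid,
                    "cluster_voxels": total,
                    "region": name,
                    "n_voxels": cnt,
                    "pct": pct,
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster_id", "cluster_voxels", "region", "n_voxels", "pct"]
    )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {err}")


@dataclass
class SubtypeAnalysisResult:
    """Everything one subtype contrast produces."""

    subtype: str
    beta: BetaMap
    permutation: PermutationResult
    clusters: ClusterMap
    composition: pd.DataFrame
    retention: RetentionReport
    accounting: AccountingReport
    C: float
    gamma: float | None
    manifest: dict


def run_subtype_analysis(
    cohort: LesionCohort,
    subtype_name: str,
    atlas: AtlasVolume,
    config: SvrLsmConfig,
) -> SubtypeAnalysisResult:
    """One-vs-rest analysis of one subtype against the rest of the cohort.

    All other subtypes (including rare ones) stay in the comparison group;
    the row count of the design is constant across contrasts.  Stages:
    stack -> overlap filter -> volume residualization -> hyperparameter
    optimization (unless fixed) -> fold-averaged beta/z map -> permutation
    p-values -> cluster-extent thresholding -> atlas composition.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:  # noqa: BLE001 - re-raise with stage context
            raise StageError(name, err) from err

    matrix = stage("stack_cohort", stack_cohort, cohort)
    matrix, retention = stage("overlap_filter", overlap_filter, matrix,
                              config.min_overlap)
    contrast = stage("make_contrast", make_contrast, cohort.subtype, subtype_name)
    volumes = cohort.whole_volumes_cm3()
    Xr, yr = stage("residualize_volume", residualize_volume,
                   matrix.dense(), contrast.y, volumes)
    strata = contrast.y.astype(int)
    cache = KernelCache(Xr)

    if config.C == "optimize" or config.gamma == "optimize":
        C, gamma = stage(
            "optimize_hyperparameters",
            optimize_hyperparameters,
            Xr, yr,
            iterations=config.hyperopt_iterations,
            bounds=config.hyperopt_bounds,
            seed=config.seed,
            cv_folds=config.cv_folds,
            epsilon=config.epsilon,
            strata=strata,
            kernel=config.kernel,
            cache=cache,
        )
        if config.C != "optimize":
            C = float(config.C)
        if config.gamma != "optimize":
            gamma = resolve_gamma(config.gamma, Xr)
    else:
        C = float(config.C)
        gamma = resolve_gamma(config.gamma, Xr) if config.kernel == "rbf" else None

    betamap = stage(
        "crossval_beta", crossval_beta,
        Xr, yr, config, C=C, gamma=gamma, strata=strata, cache=cache,
        voxel_index=matrix.voxel_index, grid_shape=matrix.grid_shape,
        keep_folds=True,
    )
    perm = stage(
        "permutation_test", permutation_test,
        Xr, yr, config, C=C, gamma=gamma, strata=strata, cache=cache,
        observed=betamap,
    )
    clusters = stage("threshold_and_cluster", threshold_and_cluster,
                     betamap, perm, config)
    composition = stage("cluster_composition", cluster_composition,
                        clusters, atlas, cohort.voxel_size_mm)

    counts = {s: int((cohort.subtype == s).sum())
              for s in pd.unique(cohort.subtype)}
    accounting = cohort_accounting(
        n_screened=cohort.n_subjects, exclusions={}, subtype_counts=counts,
        retention=retention,
    )
    manifest = {
        "subtype": subtype_name,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "C": C,
        "gamma": gamma,
        "seed": config.seed,
        "n_subjects": cohort.n_subjects,
        "n_retained_voxels": retention.n_retained_voxels,
        "versions": {
            "svrlsm": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    return SubtypeAnalysisResult(
        subtype=subtype_name,
        beta=betamap,
        permutation=perm,
        clusters=clusters,
        composition=composition,
        retention=retention,
        accounting=accounting,
        C=C,
        gamma=gamma,
        manifest=manifest,
    )


def save_result(result: SubtypeAnalysisResult, out_dir, voxel_size_mm: float) -> None:
    """Write maps as NIfTI (NaN outside retained voxels) plus CSV/JSON tables."""
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    vi = result.beta.voxel_index
    shape = result.beta.grid_shape

    def to_grid(values):
        out = np.full(shape, np.nan)
        out[tuple(vi.T)] = values
        return out

    for name, values in (
        ("beta", result.beta.beta),
        ("z", result.beta.display_z()),
        ("p", result.permutation.p),
    ):
        nib.save(
            nib.Nifti1Image(to_grid(values).astype(np.float32), affine),
            os.path.join(out_dir, f"{result.subtype}_{name}.nii.gz"),
        )
    nib.save(
        nib.Nifti1Image(result.clusters.labels.astype(np.int32), affine),
        os.path.join(out_dir, f"{result.subtype}_clusters.nii.gz"),
    )
    result.clusters.summary(voxel_size_mm).to_csv(
        os.path.join(out_dir, f"{result.subtype}_clusters.csv"), index=False
    )
    result.composition.to_csv(
        os.path.join(out_dir, f"{result.subtype}_composition.csv"), index=False
    )
    with open(os.path.join(out_dir, f"{result.subtype}_manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    result.accounting.to_json(
        os.path.join(out_dir, f"{result.subtype}_accounting.json")
    )
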
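"""Permutation-based voxelwise inference and cluster-extent thresholding.

Significance of the beta map is assessed nonparametrically: the
(volume-residualized) outcome is randomly permuted across subjects, the
full fold-averaged beta map is recomputed with hyperparameters fixed at
the observed-data optimum, and each voxel's p-value is the add-one
fraction of permuted maps at least as extreme as the observed one,

    p_j = (1 + #{b : ext(beta_b_j) >= ext(beta_obs_j)}) / (B + 1),

with ext = |.| for two-sided tests.  For tiny cohorts where the number of
distinct label arrangements falls below the requested count, all distinct
permutations are enumerated exactly instead (classical exact test, the
identity arrangement counted in the numerator).

Significant voxels (p below the voxelwise threshold, .005 by convention)
are then cleaned by a cluster-extent criterion: connected components
(6/18/26-connectivity) smaller than a minimum size (100 voxels at full
scale) are discarded.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BetaMap, KernelCache, SvrLsmConfig, crossval_beta

__all__ = [
    "PermutationResult",
    "ClusterMap",
    "permutation_test",
    "pvalues_from_null",
    "threshold_and_cluster",
    "connectivity_structure",
]


@dataclass
class PermutationResult:
    """Per-voxel permutation p-values and a summary of the null."""

    p: np.ndarray
    n_permutations: int
    null_mean: np.ndarray
    null_sd: np.ndarray
    seed: int
    exact: bool = False
    tail: str = "two_sided"


def _extremity(beta: np.ndarray, tail: str) -> np.ndarray:
    if tail == "two_sided":
        return np.abs(beta)
    if tail == "one_sided_positive":
        return beta
    if tail == "one_sided_negative":
        return -beta
    raise ValueError(f"unknown tail {tail!r}")


def pvalues_from_null(
    beta_obs: np.ndarray,
    null_betas: np.ndarray,
    tail: str = "two_sided",
    exact: bool = False,
) -> np.ndarray:
    """p-values from an observed map and a (B x V) null ensemble.

    Sampled mode uses the add-one estimator (p >= 1/(B+1), never zero).
    Exact mode assumes ``null_betas`` enumerates every distinct
    arrangement including the identity, so p = count / B.
    """
    obs = _extremity(np.asarray(beta_obs, dtype=float), tail)
    null = _extremity(np.asarray(null_betas, dtype=float), tail)
    count = (null >= obs[None, :]).sum(axis=0)
    B = null.shape[0]
    if exact:
        return count / B
    return (1.0 + count) / (B + 1.0)


def _n_distinct_arrangements(y: np.ndarray) -> int:
    _, counts = np.unique(y, return_counts=True)
    n = math.factorial(len(y))
    for c in counts:
        n //= math.factorial(int(c))
    return n


def _distinct_permutations(y: np.ndarray):
    """All distinct arrangements of y (identity included), as index-free values."""
    seen = set()
    for perm in itertools.permutations(range(len(y))):
        arr = tuple(y[list(perm)])
        if arr not in seen:
            seen.add(arr)
            yield np.asarray(arr, dtype=float)


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    config: SvrLsmConfig,
    C: float,
    gamma: float | None,
    strata: np.ndarray | None = None,
    cache: KernelCache | None = None,
    observed: BetaMap | None = None,
) -> PermutationResult:
    """Voxelwise permutation p-values for the fold-averaged beta map.

    The residualized outcome (and the stratification labels with it) is
    permuted; lesions stay fixed, hyperparameters stay at (C, gamma).
    Deterministic given ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if cache is None:
        cache = KernelCache(X)
    if observed is None:
        observed = crossval_beta(X, y, config, C=C, gamma=gamma, strata=strata,
                                 cache=cache)
    beta_obs = observed.beta

    n_req = config.n_permutations
    n_distinct = _n_distinct_arrangements(y)
    exact = n_distinct <= n_req
    # component-tagged stream: never aliases the cohort generator's stream
    # even when the user passes one seed everywhere
    rng = np.random.default_rng([0x7065726D, config.seed])

    if exact:
        warnings.warn(
            f"only {n_distinct} distinct label arrangements (< {n_req} "
            "requested): enumerating all permutations exactly"
        )
        null = np.empty((n_distinct, X.shape[1]))
        # identity-arrangement beta is recomputed through the same pipeline
        for b, y_b in enumerate(_distinct_permutations(y)):
            bm = crossval_beta(X, y_b, config, C=C, gamma=gamma, strata=None,
                               cache=cache, fold_seed=config.seed)
            null[b] = bm.beta
        n_used = n_distinct
        # the identity arrangement is enumerated first; use it as the
        # observed map so observed and null share one pipeline exactly
        beta_obs = null[0]
    else:
        null = np.empty((n_req, X.shape[1]))
        for b in range(n_req):
            perm = rng.permutation(n)
            strata_b = None if strata is None else np.asarray(strata)[perm]
            bm = crossval_beta(
                X, y[perm], config, C=C, gamma=gamma, strata=strata_b,
                cache=cache, fold_seed=config.seed,
            )
            null[b] = bm.beta
        n_used = n_req

    p = pvalues_from_null(beta_obs, null, tail=config.tail, exact=exact)
    return PermutationResult(
        p=p,
        n_permutations=n_used,
        null_mean=null.mean(axis=0),
        null_sd=null.std(axis=0),
        seed=config.seed,
        exact=exact,
        tail=config.tail,
    )


# ---------------------------------------------------------------------------
# Cluster-extent thresholding


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D neighborhood structure for 6-, 18- or 26-connectivity."""
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class ClusterMap:
    """Significant clusters surviving the extent criterion.

    ``labels`` assigns 1..k in decreasing size order (0 = nonsignificant).
    Peak coordinates maximize |z| within each cluster (ties broken by
    lowest linear voxel index).
    """

    labels: np.ndarray
    sizes: list[int]
    peaks: list[tuple[int, int, int]]
    peak_z: list[float]
    connectivity: int
    min_cluster_voxels: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def summary(self, voxel_size_mm: float | None = None) -> pd.DataFrame:
        rows = []
        for cid, (size, peak, pz) in enumerate(
            zip(self.sizes, self.peaks, self.peak_z), start=1
        ):
            row = {
                "cluster_id": cid,
                "n_voxels": size,
                "peak_i": peak[0],
                "peak_j": peak[1],
                "peak_k": peak[2],
                "peak_abs_z": pz,
            }
            if voxel_size_mm is not None:
                row["volume_cm3"] = size * voxel_size_mm**3 / 1000.0
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id", "n_voxels", "peak_i", "peak_j", "peak_k",
                "peak_abs_z",
            ] + (["volume_cm3"] if voxel_size_mm is not None else []),
        )


def threshold_and_cluster(
    betamap: BetaMap,
    perm: PermutationResult,
    config: SvrLsmConfig,
) -> ClusterMap:
    """Threshold p < p_threshold, keep components >= min_cluster_voxels.

    Surviving components are labeled 1..k in decreasing size order.  An
    empty map is a valid outcome.
    """
    if betamap.voxel_index is None or betamap.grid_shape is None:
        raise ValueError("beta map lacks grid projection metadata")
    if len(perm.p) != len(betamap.beta):
        raise ValueError("p map and beta map must share the voxel index")
    grid_shape = betamap.grid_shape
    sig = np.zeros(grid_shape, dtype=bool)
    sig[tuple(betamap.voxel_index.T)] = perm.p < config.p_threshold
    z_grid = np.zeros(grid_shape)
    z_grid[tuple(betamap.voxel_index.T)] = betamap.z

    structure = connectivity_structure(config.connectivity)
    labeled, n_comp = ndimage.label(sig, structure=structure)
    if n_comp == 0:
        return ClusterMap(
            labels=np.zeros(grid_shape, dtype=np.int32), sizes=[], peaks=[],
            peak_z=[], connectivity=config.connectivity,
            min_cluster_voxels=config.min_cluster_voxels,
        )
    sizes = ndimage.sum_labels(sig, labeled, index=np.arange(1, n_comp + 1))
    keep = np.flatnonzero(sizes >= config.min_cluster_voxels) + 1
    # decreasing size; ties keep the original (scan-order) labeling
    order = keep[np.argsort(-sizes[keep - 1], kind="stable")]
    out = np.zeros(grid_shape, dtype=np.int32)
    out_sizes, peaks, peak_z = [], [], []
    for new_id, old_id in enumerate(order, start=1):
        comp = labeled == old_id
        out[comp] = new_id
        out_sizes.append(int(sizes[old_id - 1]))
        flat = np.flatnonzero(comp.ravel())
        absz = np.abs(z_grid.ravel()[flat])
        peak_flat = flat[int(np.argmax(absz))]  # argmax -> lowest linear index tie
        peaks.append(tuple(int(c) for c in np.unravel_index(peak_flat, grid_shape)))
        peak_z.append(float(absz.max()))
    return ClusterMap(
        labels=out,
        sizes=out_sizes,
        peaks=peaks,
        peak_z=peak_z,
        connectivity=config.connectivity,
        min_cluster_voxels=config.min_cluster_voxels,
    )
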
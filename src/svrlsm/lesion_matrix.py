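"""Subject-by-voxel design matrix, minimum-overlap filter, and cohort accounting.

The multivariate analysis operates on a binary matrix X (subjects x
lesioned voxels).  Only voxels lesioned in at least ``min_n`` subjects are
retained (n = 10 at full scale), so single-outlier voxels cannot drive the
map.  This module also carries the exact integer bookkeeping used in
cohort reporting: inclusion percentages, subtype percentages, voxel
retention, and the segmentation-correction rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .synthetic_cohort import LesionCohort

__all__ = [
    "LesionMatrix",
    "RetentionReport",
    "AccountingReport",
    "EmptyMatrixError",
    "stack_cohort",
    "overlap_filter",
    "cohort_accounting",
    "qc_correction_rate",
]

logger = logging.getLogger(__name__)


@dataclass
class LesionMatrix:
    """Binary subjects x retained-voxels matrix with a map back to the grid.

    Columns exist only for voxels lesioned in at least one subject
    (column-sparse by contract).  ``voxel_index`` holds the (i, j, k) grid
    coordinate of each column.
    """

    X: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.uint8)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D (subjects x voxels)")
        if self.voxel_index.shape != (self.X.shape[1], 3):
            raise ValueError("voxel_index must be (n_voxels, 3)")
        flat = np.ravel_multi_index(tuple(self.voxel_index.T), self.grid_shape)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("voxel_index entries must be unique")
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("one subject id per row required")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def overlap_count(self) -> np.ndarray:
        return self.X.sum(axis=0).astype(np.int64)

    def to_grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-column vector back onto the 3D grid."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise ValueError("one value per retained voxel required")
        out = np.full(self.grid_shape, fill, dtype=float)
        out[tuple(self.voxel_index.T)] = values
        return out

    def dense(self) -> np.ndarray:
        return self.X.astype(np.float64)


@dataclass
class RetentionReport:
    """Voxel counts before/after the minimum-overlap filter."""

    n_lesioned_voxels: int
    n_retained_voxels: int
    min_n: int

    @property
    def pct_retained(self) -> int:
        # integer rounding, matching how retention is reported
        return int(round(100.0 * self.n_retained_voxels / self.n_lesioned_voxels))


class EmptyMatrixError(ValueError):
    """No voxel survived the minimum-overlap filter."""

    def __init__(self, report: RetentionReport):
        self.report = report
        super().__init__(
            f"no voxel lesioned in >= {report.min_n} subjects "
            f"(of {report.n_lesioned_voxels} lesioned voxels)"
        )


def stack_cohort(cohort: LesionCohort) -> LesionMatrix:
    """Assemble the unfiltered design matrix from a cohort.

    One column per voxel lesioned in at least one subject; row order is
    subject order.
    """
    n = cohort.n_subjects
    flat = cohort.masks.reshape(n, -1)
    any_mask = flat.any(axis=0)
    cols = np.flatnonzero(any_mask)
    X = flat[:, cols].astype(np.uint8)
    voxel_index = np.stack(np.unravel_index(cols, cohort.grid_shape), axis=1)
    return LesionMatrix(
        X=X,
        voxel_index=voxel_index,
        grid_shape=tuple(cohort.grid_shape),
        voxel_size_mm=cohort.voxel_size_mm,
        subject_ids=list(cohort.subject_ids),
    )


def overlap_filter(
    matrix: LesionMatrix, min_n: int
) -> tuple[LesionMatrix, RetentionReport]:
    """Retain voxels lesioned in at least ``min_n`` subjects."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    keep = matrix.overlap_count >= min_n
    report = RetentionReport(
        n_lesioned_voxels=matrix.n_voxels,
        n_retained_voxels=int(keep.sum()),
        min_n=min_n,
    )
    logger.info(
        "overlap filter (min %d): retained %d of %d lesioned voxels (%d%%)",
        min_n, report.n_retained_voxels, report.n_lesioned_voxels,
        report.pct_retained,
    )
    if report.n_retained_voxels == 0:
        raise EmptyMatrixError(report)
    filtered = LesionMatrix(
        X=matrix.X[:, keep],
        voxel_index=matrix.voxel_index[keep],
        grid_shape=matrix.grid_shape,
        voxel_size_mm=matrix.voxel_size_mm,
        subject_ids=list(matrix.subject_ids),
    )
    return filtered, report


@dataclass
class AccountingReport:
    """Exact integer cohort bookkeeping with printed-precision percentages."""

    n_screened: int
    n_excluded_by_reason: dict[str, int]
    n_included: int
    pct_included: float
    subtype_counts: dict[str, int] = field(default_factory=dict)
    subtype_pct: dict[str, float] = field(default_factory=dict)
    n_lesioned_voxels: int | None = None
    n_retained_voxels: int | None = None
    pct_retained: int | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def cohort_accounting(
    n_screened: int,
    exclusions: dict[str, int] | None = None,
    subtype_counts: dict[str, int] | None = None,
    retention: RetentionReport | None = None,
) -> AccountingReport:
    """Inclusion/exclusion bookkeeping with 1-decimal percentages.

    Subtype percentages are computed over the included count.
    """
    exclusions = dict(exclusions or {})
    subtype_counts = dict(subtype_counts or {})
    if n_screened < 0 or any(v < 0 for v in exclusions.values()):
        raise ValueError("counts must be nonnegative")
    if any(v < 0 for v in subtype_counts.values()):
        raise ValueError("subtype counts must be nonnegative")
    n_excluded = sum(exclusions.values())
    if n_excluded > n_screened:
        raise ValueError("exclusions exceed screened count")
    n_included = n_screened - n_excluded
    pct_included = round(100.0 * n_included / n_screened, 1) if n_screened else 0.0
    subtype_pct = {
        k: round(100.0 * v / n_included, 1) for k, v in subtype_counts.items()
    } if n_included else {}
    report = AccountingReport(
        n_screened=n_screened,
        n_excluded_by_reason=exclusions,
        n_included=n_included,
        pct_included=pct_included,
        subtype_counts=subtype_counts,
        subtype_pct=subtype_pct,
    )
    if retention is not None:
        report.n_lesioned_voxels = retention.n_lesioned_voxels
        report.n_retained_voxels = retention.n_retained_voxels
        report.pct_retained = retention.pct_retained
    return report


def qc_correction_rate(n_corrected: int, n_total: int) -> float:
    """Manual segmentation-correction rate as a percentage (2 decimals)."""
    if n_total == 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_corrected <= n_total:
        raise ValueError("need 0 <= n_corrected <= n_total")
    return round(100.0 * n_corrected / n_total, 2)
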
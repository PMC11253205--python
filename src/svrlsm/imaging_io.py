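"""NIfTI mask I/O, compartment merging, resampling and volumetry.

The analysis consumes binary tumor masks that were segmented and
registered to a common standard space upstream; this module handles the
remaining image plumbing: reading/writing masks, merging the
contrast-enhancing / T2-FLAIR-hyperintense / necrosis compartments into
one unified mask, nearest-neighbor resampling to the analysis resolution
(2 mm by convention), and compartment volumetry in cm^3.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .synthetic_cohort import AtlasVolume, LesionCohort, SyntheticCohortSpec

__all__ = [
    "MaskImage",
    "read_mask",
    "write_mask",
    "merge_compartments",
    "resample_mask",
    "compute_volumes",
    "write_atlas",
    "read_atlas",
    "write_cohort",
    "read_cohort",
]


@dataclass
class MaskImage:
    """A binary 3D mask with its grid-to-world affine.

    ``data`` is boolean; voxel sizes are derived from the affine column
    norms.  ``space_tag`` is a free-form space identifier (e.g. "MNI152").
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask data must be binary (0/1)")
            self.data = self.data.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def volume_cm3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_mm3 / 1000.0


def read_mask(path, space_tag: str = "") -> MaskImage:
    """Load a 3D NIfTI volume and binarize it at 0.5.

    Registration interpolation can leave fractional values; anything above
    0.5 is foreground.  4D inputs and non-finite values are rejected.
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    data = np.asarray(data, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: mask contains non-finite values")
    return MaskImage(data=data > 0.5, affine=img.affine, space_tag=space_tag)


def write_mask(mask: MaskImage, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, os.fspath(path))


def _check_same_grid(masks: list[MaskImage]) -> None:
    ref = masks[0]
    for m in masks[1:]:
        if m.shape != ref.shape:
            raise ValueError(f"grid shape mismatch: {m.shape} vs {ref.shape}")
        if not np.allclose(m.affine, ref.affine, atol=1e-6):
            raise ValueError("affine mismatch between compartment masks")


def merge_compartments(*masks: MaskImage) -> MaskImage:
    """Voxelwise OR of compartment masks into one unified tumor mask."""
    if not masks:
        raise ValueError("at least one compartment mask required")
    _check_same_grid(list(masks))
    union = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        union |= m.data
    return MaskImage(data=union, affine=masks[0].affine, space_tag=masks[0].space_tag)


def resample_mask(mask: MaskImage, target_voxel_mm: float) -> MaskImage:
    """Nearest-neighbor resampling onto an isotropic target grid.

    The output affine is the source affine with its direction columns
    rescaled, so the world position of each voxel center is preserved.
    Resampling at the source resolution is the identity.
    """
    if target_voxel_mm <= 0:
        raise ValueError("target voxel size must be positive")
    src = mask.voxel_size_mm
    factor = target_voxel_mm / src  # per-axis index scale
    if np.allclose(factor, 1.0):
        return MaskImage(data=mask.data.copy(), affine=mask.affine.copy(),
                         space_tag=mask.space_tag)
    new_shape = tuple(
        max(1, int(np.ceil(s / f))) for s, f in zip(mask.shape, factor)
    )
    tgt_idx = np.indices(new_shape, dtype=float)
    coords = [tgt_idx[a] * factor[a] for a in range(3)]
    data = map_coordinates(
        mask.data.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).astype(bool)
    affine = mask.affine.copy()
    affine[:3, :3] = mask.affine[:3, :3] * factor[None, :]
    return MaskImage(data=data, affine=affine, space_tag=mask.space_tag)


def compute_volumes(
    compartments: dict[str, MaskImage | np.ndarray],
    voxel_size_mm: float | None = None,
) -> dict[str, float]:
    """Compartment volumes in cm^3; ``whole`` is the union volume.

    Accepts MaskImage values (voxel volume from the affine) or raw boolean
    arrays plus an explicit isotropic ``voxel_size_mm``.
    """
    if not compartments:
        raise ValueError("no compartments given")
    vols: dict[str, float] = {}
    union = None
    voxvol = None
    for name, m in compartments.items():
        if isinstance(m, MaskImage):
            data, vv = m.data, m.voxel_volume_mm3
        else:
            if voxel_size_mm is None:
                raise ValueError("voxel_size_mm required for raw arrays")
            data, vv = np.asarray(m, dtype=bool), float(voxel_size_mm) ** 3
        if voxvol is None:
            voxvol = vv
        vols[name] = float(data.sum()) * vv / 1000.0
        union = data.copy() if union is None else (union | data)
    if "whole" not in vols:
        vols["whole"] = float(union.sum()) * voxvol / 1000.0
    return vols


# ---------------------------------------------------------------------------
# Atlas and cohort serialization


def write_atlas(atlas: AtlasVolume, nifti_path, labels_csv_path) -> None:
    affine = np.diag([atlas.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), affine),
             os.fspath(nifti_path))
    pd.DataFrame(
        {"label": list(atlas.names), "name": list(atlas.names.values())}
    ).to_csv(labels_csv_path, index=False)


def read_atlas(nifti_path, labels_csv_path) -> AtlasVolume:
    img = nib.load(os.fspath(nifti_path))
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    if labels.ndim != 3:
        raise ValueError("atlas must be a 3D labeled volume")
    voxel = float(np.linalg.norm(img.affine[:3, :3], axis=0)[0])
    table = pd.read_csv(labels_csv_path)
    names = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    return AtlasVolume(labels=labels, names=names, voxel_size_mm=voxel)


def write_cohort(cohort: LesionCohort, out_dir) -> None:
    """One NIfTI mask per subject plus a subjects CSV (and spec YAML)."""
    os.makedirs(out_dir, exist_ok=True)
    affine = np.diag([cohort.voxel_size_mm] * 3 + [1.0])
    rows = []
    for i, sid in enumerate(cohort.subject_ids):
        path = os.path.join(out_dir, f"{sid}_mask.nii.gz")
        nib.save(nib.Nifti1Image(cohort.masks[i].astype(np.uint8), affine), path)
        row = {"subject_id": sid, "subtype": cohort.subtype[i],
               "mask_path": f"{sid}_mask.nii.gz"}
        if cohort.compartment_volumes_cm3 is not None:
            for col in cohort.compartment_volumes_cm3.columns:
                row[f"volume_{col}_cm3"] = cohort.compartment_volumes_cm3.iloc[i][col]
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "subjects.csv"), index=False)
    if cohort.ground_truth is not None:
        cohort.ground_truth.to_yaml(os.path.join(out_dir, "cohort_spec.yaml"))


def read_cohort(subjects_csv) -> LesionCohort:
    """Assemble a cohort from a subjects table referencing per-subject masks.

    All masks must share one grid; a shape or affine mismatch anywhere in
    the cohort is an error.
    """
    table = pd.read_csv(subjects_csv)
    base = os.path.dirname(os.path.abspath(os.fspath(subjects_csv)))
    masks = []
    ref: MaskImage | None = None
    for _, row in table.iterrows():
        p = row["mask_path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        m = read_mask(p)
        if ref is None:
            ref = m
        else:
            _check_same_grid([ref, m])
        masks.append(m.data)
    voxel = float(ref.voxel_size_mm[0])
    vol_cols = [c for c in table.columns if c.startswith("volume_")]
    vols = None
    if vol_cols:
        vols = table[vol_cols].copy()
        vols.columns = [c.removeprefix("volume_").removesuffix("_cm3")
                        for c in vol_cols]
        vols.index = list(table["subject_id"].astype(str))
    return LesionCohort(
        subject_ids=list(table["subject_id"].astype(str)),
        masks=np.stack(masks),
        voxel_size_mm=voxel,
        subtype=table["subtype"].to_numpy(dtype=object),
        compartment_volumes_cm3=vols,
    )
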
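"""Synthetic lesion cohorts with known ground truth.

Real multivariate lesion-symptom mapping studies rest on patient imaging
that usually cannot be redistributed.  This module generates cohorts of
binary lesion masks on a configurable grid so every downstream stage —
design-matrix assembly, SVR fitting, permutation inference, atlas
reporting — can be exercised and validated against planted effects.

The generator emulates the structure of a molecular-subtype glioma cohort:

* subtype labels allocated to match configured proportions exactly
  (largest-remainder rounding), e.g. MES / RTK I / RTK II / other;
* per-subject whole-tumor volumes drawn from subtype-specific lognormals
  parameterized as (median cm^3, geometric SD), optionally derived from a
  published mean +/- SD;
* lesions grown as connected blobs by stochastic region growing from a
  seed voxel, so masks have the gross topology of tumor segmentations;
* optional subtype-specific spatial predilection: with relative odds
  ``effect_strength`` the seed voxel is placed in a target atlas region,
  otherwise uniformly across regions.  ``effect_strength = 0`` makes
  lesion location independent of subtype (a true null).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "VolumeDistribution",
    "PlantedEffect",
    "SyntheticCohortSpec",
    "AtlasVolume",
    "LesionCohort",
    "generate_toy_atlas",
    "sample_lesion",
    "generate_cohort",
    "allocate_subtypes",
    "allocate_seed_regions",
    "cohort_summary",
    "toy_spec",
    "fullscale_spec",
]

# Reference cohort composition: subtype proportions as printed for a
# 423-patient IDH-wild-type glioblastoma series (RTK II most common).
REFERENCE_PROPORTIONS = {
    "RTK II": 0.407,
    "MES": 0.338,
    "RTK I": 0.18,
    "other": 0.076,
}

# Whole-tumor volume (mean +/- SD, cm^3) per subtype at full scale.
REFERENCE_VOLUMES_CM3 = {
    "MES": (87.0, 60.0),
    "RTK I": (89.0, 61.0),
    "RTK II": (82.0, 59.0),
    "other": (86.0, 60.0),  # pooled scale; not reported separately
}


@dataclass(frozen=True)
class VolumeDistribution:
    """Lognormal lesion-volume model: median (cm^3) and geometric SD (> 1)."""

    median_cm3: float
    gsd: float

    def __post_init__(self) -> None:
        if self.median_cm3 <= 0:
            raise ValueError("median_cm3 must be positive")
        if self.gsd < 1:
            raise ValueError("geometric SD must be >= 1")

    @classmethod
    def from_mean_sd(cls, mean: float, sd: float) -> "VolumeDistribution":
        """Match a lognormal to an arithmetic mean and SD."""
        if mean <= 0 or sd < 0:
            raise ValueError("mean must be positive and sd nonnegative")
        sigma2 = math.log1p((sd / mean) ** 2)
        median = mean * math.exp(-sigma2 / 2.0)
        return cls(median_cm3=median, gsd=math.exp(math.sqrt(sigma2)))

    @property
    def mean_cm3(self) -> float:
        sigma = math.log(self.gsd)
        return self.median_cm3 * math.exp(sigma**2 / 2.0)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.lognormal(
            mean=math.log(self.median_cm3), sigma=math.log(self.gsd), size=size
        )


@dataclass(frozen=True)
class PlantedEffect:
    """Spatial predilection of one subtype for one atlas region.

    ``strength`` is the relative odds that a lesion of this subtype is
    seeded in the target region rather than drawn from the uniform
    region mixture: with probability ``strength / (1 + strength)`` the
    seed region is the target, otherwise it is uniform over all regions
    (including the target).  ``strength = 0`` is a true null.
    """

    subtype: str
    region_label: int
    strength: float

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("effect strength must be >= 0")

    @property
    def p_target(self) -> float:
        return self.strength / (1.0 + self.strength)

    def seeded_fraction(self, n_regions: int) -> float:
        """Exact expected fraction of lesions seeded in the target region."""
        p = self.p_target
        return p + (1.0 - p) / n_regions


_PROPORTION_TOL = 5e-3  # printed percentages may sum to e.g. 100.1


@dataclass
class SyntheticCohortSpec:
    """Distributional recipe a simulator run realizes.

    Proportions must sum to 1 within ``5e-3`` (published, rounded
    percentages are accepted); they are renormalized before allocation.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    n_subjects: int
    subtype_proportions: dict[str, float]
    volume_distributions: dict[str, VolumeDistribution]
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > _PROPORTION_TOL:
            raise ValueError(
                f"subtype proportions sum to {total:.4f}, expected 1 within "
                f"{_PROPORTION_TOL}"
            )
        if any(p < 0 or p > 1 for p in self.subtype_proportions.values()):
            raise ValueError("proportions must lie in [0, 1]")
        missing = set(self.subtype_proportions) - set(self.volume_distributions)
        if missing:
            raise ValueError(f"no volume distribution for subtypes {sorted(missing)}")
        for eff in self.planted_effects:
            if eff.subtype not in self.subtype_proportions:
                raise ValueError(f"planted effect on unknown subtype {eff.subtype!r}")

    def effect_for(self, subtype: str) -> PlantedEffect | None:
        for eff in self.planted_effects:
            if eff.subtype == subtype:
                return eff
        return None

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "n_subjects": self.n_subjects,
            "subtype_proportions": dict(self.subtype_proportions),
            "volume_distributions": {
                k: asdict(v) for k, v in self.volume_distributions.items()
            },
            "planted_effects": [asdict(e) for e in self.planted_effects],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortSpec":
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            voxel_size_mm=float(d["voxel_size_mm"]),
            n_subjects=int(d["n_subjects"]),
            subtype_proportions=dict(d["subtype_proportions"]),
            volume_distributions={
                k: VolumeDistribution(**v) for k, v in d["volume_distributions"].items()
            },
            planted_effects=[PlantedEffect(**e) for e in d.get("planted_effects", [])],
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AtlasVolume:
    """Integer-labeled parcellation (0 = background) with region names."""

    labels: np.ndarray
    names: dict[int, str]
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise ValueError(f"atlas labels without names: {sorted(unnamed)}")

    @property
    def region_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs != 0]

    @property
    def support(self) -> np.ndarray:
        """Boolean brain mask (union of all regions)."""
        return self.labels > 0

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class LesionCohort:
    """Per-subject binary lesion masks on a shared grid, with subtype labels.

    ``masks`` is an ``(n_subjects, *grid_shape)`` boolean array.
    ``compartment_volumes_cm3`` holds one row per subject; columns among
    {whole, nonenhancing, enhancing, necrosis} are optional except that a
    ``whole`` column, when present alongside masks, must equal voxel count
    times voxel volume.  ``seed_regions`` records the generator's seeding
    region per subject (provenance; absent for real data).
    """

    subject_ids: list[str]
    masks: np.ndarray
    voxel_size_mm: float
    subtype: np.ndarray
    compartment_volumes_cm3: pd.DataFrame | None = None
    ground_truth: SyntheticCohortSpec | None = None
    seed_regions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.subtype = np.asarray(self.subtype, dtype=object)
        n = len(self.subject_ids)
        if self.masks.ndim != 4 or self.masks.shape[0] != n:
            raise ValueError("masks must be (n_subjects, nx, ny, nz)")
        if len(self.subtype) != n:
            raise ValueError("one subtype label per subject required")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.compartment_volumes_cm3 is not None:
            vols = self.compartment_volumes_cm3
            if len(vols) != n:
                raise ValueError("one volume row per subject required")
            if "whole" in vols.columns:
                voxvol = self.voxel_size_mm**3 / 1000.0
                counted = self.masks.reshape(n, -1).sum(axis=1) * voxvol
                if not np.allclose(vols["whole"].to_numpy(), counted, atol=1e-6):
                    raise ValueError(
                        "whole-tumor volumes inconsistent with mask voxel counts"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.masks.shape[1:]

    def whole_volumes_cm3(self) -> np.ndarray:
        voxvol = self.voxel_size_mm**3 / 1000.0
        return self.masks.reshape(self.n_subjects, -1).sum(axis=1) * voxvol


# ---------------------------------------------------------------------------
# Atlas generation


def _ellipsoid_support(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal 'brain' support inscribed in the grid (90% semi-axes)."""
    center = (np.asarray(grid_shape) - 1) / 2.0
    semi = np.maximum(np.asarray(grid_shape) * 0.45, 0.5)
    ii, jj, kk = np.indices(grid_shape)
    r2 = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    return r2 <= 1.0


def generate_toy_atlas(
    grid_shape: tuple[int, int, int],
    n_regions: int,
    seed: int,
    voxel_size_mm: float = 2.0,
) -> AtlasVolume:
    """Seeded Voronoi parcellation of an ellipsoidal support.

    ``n_regions`` seed voxels are drawn uniformly from the support and every
    support voxel is assigned to its nearest seed (ties to the lowest seed
    index).  Voronoi cells are convex, and so is the ellipsoid, so each
    region is a single connected component.  Background is label 0.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2 (degenerate parcellation rejected)")
    support = _ellipsoid_support(grid_shape)
    coords = np.argwhere(support)
    if len(coords) < n_regions:
        raise ValueError(
            f"grid {grid_shape} has only {len(coords)} support voxels; "
            f"cannot host {n_regions} regions"
        )
    rng = np.random.default_rng(seed)
    seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)  # ties -> lowest seed index
    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[tuple(coords.T)] = assign + 1
    names = {i + 1: f"region_{i + 1:02d}" for i in range(n_regions)}
    return AtlasVolume(labels=labels, names=names, voxel_size_mm=voxel_size_mm)


# ---------------------------------------------------------------------------
# Lesion growth

_NEIGHBORS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_lesion(
    support: np.ndarray, start: tuple[int, int, int], n_voxels: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic region growing: one connected blob of n_voxels voxels.

    Repeatedly annexes a uniformly chosen frontier voxel (6-neighbors of the
    blob inside the support).  The support is connected, so growth reaches
    the exact target unless the target exceeds the support size.
    """
    shape = support.shape
    mask = np.zeros(shape, dtype=bool)
    in_frontier = np.zeros(shape, dtype=bool)
    mask[start] = True
    frontier: list[tuple[int, int, int]] = []

    def push_neighbors(v):
        for d in _NEIGHBORS6:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and support[w]
                and not mask[w]
                and not in_frontier[w]
            ):
                in_frontier[w] = True
                frontier.append(w)

    push_neighbors(start)
    grown = 1
    while grown < n_voxels and frontier:
        i = int(rng.integers(len(frontier)))
        v = frontier[i]
        frontier[i] = frontier[-1]
        frontier.pop()
        in_frontier[v] = False
        mask[v] = True
        grown += 1
        push_neighbors(v)
    return mask


def sample_lesion(
    atlas: AtlasVolume,
    center_region: int | None,
    target_volume_cm3: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Grow one connected lesion mask of approximately the target volume.

    The seed voxel is uniform within ``center_region`` if given, otherwise
    uniform within the whole support.  Voxel count equals
    ``round(target_volume / voxel_volume)`` (at least 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    voxvol = atlas.voxel_size_mm**3 / 1000.0
    n_voxels = max(1, int(round(target_volume_cm3 / voxvol)))
    support = atlas.support
    n_support = int(support.sum())
    if n_voxels > n_support:
        raise ValueError(
            f"target volume {target_volume_cm3:.3f} cm^3 ({n_voxels} voxels) "
            f"exceeds brain support ({n_support} voxels)"
        )
    if center_region is not None:
        region = atlas.labels == center_region
        if not region.any():
            raise ValueError(f"center_region {center_region} not present in atlas")
        coords = np.argwhere(region)
    else:
        coords = np.argwhere(support)
    start = tuple(coords[int(rng.integers(len(coords)))])
    return _grow_lesion(support, start, n_voxels, rng)


# ---------------------------------------------------------------------------
# Cohort generation


def allocate_subtypes(
    proportions: dict[str, float], n: int, method: str = "largest_remainder",
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Integer subtype counts from proportions.

    ``largest_remainder`` (default) reproduces printed cohort counts exactly
    and deterministically; ``multinomial`` draws stochastic counts.
    """
    names = list(proportions)
    p = np.array([proportions[k] for k in names], dtype=float)
    p = p / p.sum()
    if method == "multinomial":
        if rng is None:
            raise ValueError("multinomial allocation needs an rng")
        counts = rng.multinomial(n, p)
        return dict(zip(names, (int(c) for c in counts)))
    if method != "largest_remainder":
        raise ValueError(f"unknown allocation method {method!r}")
    quotas = p * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return dict(zip(names, (int(c) for c in counts)))


def allocate_seed_regions(
    spec: SyntheticCohortSpec,
    atlas: AtlasVolume,
    rng: np.random.Generator,
    subtypes: np.ndarray,
) -> np.ndarray:
    """Draw the seeding region for each subject from the effect mixture."""
    regions = atlas.region_labels
    out = np.empty(len(subtypes), dtype=np.int64)
    for i, st in enumerate(subtypes):
        eff = spec.effect_for(st)
        if eff is not None and rng.random() < eff.p_target:
            out[i] = eff.region_label
        else:
            out[i] = regions[int(rng.integers(len(regions)))]
    return out


def generate_cohort(
    spec: SyntheticCohortSpec,
    atlas: AtlasVolume,
    allocation: str = "largest_remainder",
) -> LesionCohort:
    """Realize a cohort from a spec on the given atlas.

    Subtype counts are allocated deterministically (largest remainder) so a
    423-subject cohort with the reference proportions reproduces the printed
    counts (172, 143, 76, 32); volumes come from subtype lognormals; the
    seeding region comes from the planted-effect mixture.
    """
    if tuple(atlas.labels.shape) != spec.grid_shape:
        raise ValueError("atlas grid does not match spec.grid_shape")
    for eff in spec.planted_effects:
        if eff.region_label not in atlas.names:
            raise ValueError(f"planted-effect region {eff.region_label} not in atlas")
    rng = np.random.default_rng(spec.seed)
    counts = allocate_subtypes(
        spec.subtype_proportions, spec.n_subjects, method=allocation, rng=rng
    )
    subtypes = np.concatenate(
        [np.full(c, name, dtype=object) for name, c in counts.items()]
    )
    seed_regions = allocate_seed_regions(spec, atlas, rng, subtypes)
    voxvol = spec.voxel_size_mm**3 / 1000.0
    n_support = int(atlas.support.sum())
    masks = np.zeros((spec.n_subjects, *spec.grid_shape), dtype=bool)
    volumes = np.empty(spec.n_subjects)
    for i in range(spec.n_subjects):
        dist = spec.volume_distributions[subtypes[i]]
        target = float(dist.sample(rng))
        # clip at the support: a lesion cannot exceed the brain
        target = min(target, n_support * voxvol)
        masks[i] = sample_lesion(atlas, int(seed_regions[i]), target, rng)
        volumes[i] = masks[i].sum() * voxvol
    subject_ids = [f"sub-{i + 1:04d}" for i in range(spec.n_subjects)]
    vols = pd.DataFrame({"whole": volumes}, index=subject_ids)
    return LesionCohort(
        subject_ids=subject_ids,
        masks=masks,
        voxel_size_mm=spec.voxel_size_mm,
        subtype=subtypes,
        compartment_volumes_cm3=vols,
        ground_truth=spec,
        seed_regions=seed_regions,
    )


# ---------------------------------------------------------------------------
# Cohort summary statistics


def wilcoxon_mann_whitney(a, b) -> float:
    """Exact two-sided Wilcoxon–Mann–Whitney p-value (asymptotic for large n)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    method = "exact" if (len(a) <= 25 and len(b) <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def cohort_summary(
    cohort: LesionCohort,
    categorical: dict[str, np.ndarray] | None = None,
    pairwise: bool = False,
) -> pd.DataFrame:
    """Per-subtype descriptive table with across-group p-values.

    Rows are subtypes (n, percentage at 1 decimal, mean +/- SD of each
    compartment volume).  Continuous variables are compared with the exact
    Wilcoxon–Mann–Whitney test for 2 groups and the Kruskal–Wallis omnibus
    for more (pairwise Wilcoxon additionally in ``.attrs`` when
    ``pairwise=True``); categorical variables with the chi-squared test.
    P-values are attached in ``.attrs['pvalues']``.
    """
    levels = [s for s in pd.unique(cohort.subtype)]
    groups = {s: np.flatnonzero(cohort.subtype == s) for s in levels}
    empty = [s for s, idx in groups.items() if len(idx) == 0]
    for s in empty:
        warnings.warn(f"subtype {s!r} has n = 0 and is omitted from the summary")
        del groups[s]
    if len(groups) < 2:
        raise ValueError("cohort summary needs >= 2 nonempty subtype groups")

    n_total = cohort.n_subjects
    rows = {}
    for s, idx in groups.items():
        rows[s] = {"n": len(idx), "pct": round(100.0 * len(idx) / n_total, 1)}
    vols = cohort.compartment_volumes_cm3
    pvalues: dict[str, float] = {}
    pairwise_p: dict[str, dict[tuple[str, str], float]] = {}
    if vols is not None:
        for col in vols.columns:
            x = vols[col].to_numpy(dtype=float)
            samples = [x[idx] for idx in groups.values()]
            for s, idx in groups.items():
                rows[s][f"{col}_mean"] = float(np.mean(x[idx]))
                rows[s][f"{col}_sd"] = float(np.std(x[idx], ddof=1)) if len(idx) > 1 else 0.0
            if len(samples) == 2:
                pvalues[col] = wilcoxon_mann_whitney(*samples)
            else:
                pvalues[col] = float(stats.kruskal(*samples).pvalue)
                if pairwise:
                    names = list(groups)
                    pairwise_p[col] = {
                        (names[i], names[j]): wilcoxon_mann_whitney(
                            samples[i], samples[j]
                        )
                        for i in range(len(names))
                        for j in range(i + 1, len(names))
                    }
    if categorical:
        for name, values in categorical.items():
            values = np.asarray(values, dtype=object)
            table = pd.crosstab(cohort.subtype, values)
            table = table.loc[[s for s in groups if s in table.index]]
            pvalues[name] = float(stats.chi2_contingency(table.to_numpy()).pvalue)

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subtype"
    out.attrs["pvalues"] = pvalues
    if pairwise:
        out.attrs["pairwise_pvalues"] = pairwise_p
    return out


# ---------------------------------------------------------------------------
# Ready-made specs


def _reference_volume_distributions() -> dict[str, VolumeDistribution]:
    return {
        k: VolumeDistribution.from_mean_sd(*v) for k, v in REFERENCE_VOLUMES_CM3.items()
    }


def fullscale_spec(
    n_subjects: int = 423, seed: int = 0, planted_effects=()
) -> SyntheticCohortSpec:
    """Full-scale recipe: MNI-like 2 mm grid (91 x 109 x 91), reference
    subtype proportions and Table-scale volume distributions."""
    return SyntheticCohortSpec(
        grid_shape=(91, 109, 91),
        voxel_size_mm=2.0,
        n_subjects=n_subjects,
        subtype_proportions=dict(REFERENCE_PROPORTIONS),
        volume_distributions=_reference_volume_distributions(),
        planted_effects=list(planted_effects),
        seed=seed,
    )


def toy_spec(
    n_subjects: int = 80,
    seed: int = 0,
    planted_effects=(),
    grid_shape: tuple[int, int, int] = (20, 24, 20),
    median_cm3: float = 4.0,
    gsd: float = 1.5,
) -> SyntheticCohortSpec:
    """Desk-scale recipe: 20 x 24 x 20 grid at 2 mm, same subtype mix,
    volumes scaled to the toy support (median 4 cm^3, GSD 1.5)."""
    dist = VolumeDistribution(median_cm3=median_cm3, gsd=gsd)
    return SyntheticCohortSpec(
        grid_shape=grid_shape,
        voxel_size_mm=2.0,
        n_subjects=n_subjects,
        subtype_proportions=dict(REFERENCE_PROPORTIONS),
        volume_distributions={k: dist for k in REFERENCE_PROPORTIONS},
        planted_effects=list(planted_effects),
        seed=seed,
    )
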
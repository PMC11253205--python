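"""Synthetic cohort generator: atlas, lesion growth, allocation, summaries."""

import numpy as np
import pytest
from scipy import stats

import svrlsm
from svrlsm.synthetic_cohort import (
    VolumeDistribution,
    allocate_seed_regions,
    allocate_subtypes,
    wilcoxon_mann_whitney,
)

from _oracles import exact_mannwhitney_p, n_components


class TestToyAtlas:
    def test_regions_are_connected_components(self, toy_atlas):
        labels = toy_atlas.labels
        assert sorted(np.unique(labels)) == list(range(9))
        for lab in range(1, 9):
            assert n_components(labels == lab, 26) == 1

    def test_seeded_determinism(self):
        a = svrlsm.generate_toy_atlas((20, 24, 20), 8, seed=1)
        b = svrlsm.generate_toy_atlas((20, 24, 20), 8, seed=1)
        assert np.array_equal(a.labels, b.labels)
        c = svrlsm.generate_toy_atlas((20, 24, 20), 8, seed=2)
        assert not np.array_equal(a.labels, c.labels)

    def test_degenerate_parcellations_rejected(self):
        with pytest.raises(ValueError):
            svrlsm.generate_toy_atlas((20, 24, 20), 1, seed=0)
        with pytest.raises(ValueError):
            svrlsm.generate_toy_atlas((4, 4, 4), 1000, seed=0)

    def test_every_label_named(self, toy_atlas):
        present = set(np.unique(toy_atlas.labels)) - {0}
        assert present <= set(toy_atlas.names)


class TestSampleLesion:
    def test_minimal_lesion_inside_requested_region(self, toy_atlas):
        voxvol = toy_atlas.voxel_size_mm**3 / 1000.0
        mask = svrlsm.sample_lesion(toy_atlas, 5, voxvol, seed=0)
        assert mask.sum() == 1
        assert toy_atlas.labels[mask][0] == 5

    @pytest.mark.parametrize("target_vox", [10, 100, 400])
    def test_exact_volume_and_connectivity(self, toy_atlas, target_vox):
        voxvol = toy_atlas.voxel_size_mm**3 / 1000.0
        mask = svrlsm.sample_lesion(toy_atlas, None, target_vox * voxvol, seed=7)
        assert mask.sum() == target_vox
        assert n_components(mask, 6) == 1
        assert not mask[~toy_atlas.support].any()

    def test_seeded_determinism(self, toy_atlas):
        a = svrlsm.sample_lesion(toy_atlas, 2, 1.0, seed=9)
        b = svrlsm.sample_lesion(toy_atlas, 2, 1.0, seed=9)
        assert np.array_equal(a, b)

    def test_target_beyond_support_rejected(self, toy_atlas):
        voxvol = toy_atlas.voxel_size_mm**3 / 1000.0
        too_big = (toy_atlas.support.sum() + 1) * voxvol
        with pytest.raises(ValueError, match="support"):
            svrlsm.sample_lesion(toy_atlas, None, too_big, seed=0)


class TestAllocation:
    def test_reference_cohort_counts_reproduced(self):
        counts = allocate_subtypes(
            {"RTK II": 0.407, "MES": 0.338, "RTK I": 0.18, "other": 0.076}, 423
        )
        assert counts == {"RTK II": 172, "MES": 143, "RTK I": 76, "other": 32}

    @pytest.mark.parametrize("n", [1, 7, 80, 423, 1000])
    def test_counts_sum_to_n(self, n):
        counts = allocate_subtypes(
            {"a": 0.407, "b": 0.338, "c": 0.18, "d": 0.076}, n
        )
        assert sum(counts.values()) == n

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            svrlsm.SyntheticCohortSpec(
                grid_shape=(10, 10, 10),
                voxel_size_mm=2.0,
                n_subjects=10,
                subtype_proportions={"a": 0.6, "b": 0.2},
                volume_distributions={
                    "a": VolumeDistribution(1.0, 1.5),
                    "b": VolumeDistribution(1.0, 1.5),
                },
            )


class TestPlantedEffects:
    def test_seeded_fraction_matches_mixture_formula(self, toy_atlas):
        # odds 4 -> p_target 0.8; uniform fallback adds (1-p)/R mass
        spec = svrlsm.toy_spec(
            n_subjects=400,
            seed=42,
            planted_effects=[svrlsm.PlantedEffect("MES", 3, 4.0)],
        )
        rng = np.random.default_rng(999)
        subtypes = np.array(["MES"] * 400, dtype=object)
        regions = allocate_seed_regions(spec, toy_atlas, rng, subtypes)
        frac = (regions == 3).mean()
        expected = spec.planted_effects[0].seeded_fraction(8)
        se = np.sqrt(expected * (1 - expected) / 400)
        assert abs(frac - expected) < 3 * se

    def test_null_effect_gives_independent_locations(self, toy_atlas):
        """With zero effect strength, subtype x seed-region independence
        holds: the chi-squared test rejects in about 5% of replicates."""
        spec = svrlsm.toy_spec(n_subjects=200, seed=0)
        counts = svrlsm.synthetic_cohort.allocate_subtypes(
            spec.subtype_proportions, 200
        )
        subtypes = np.concatenate(
            [np.full(c, k, dtype=object) for k, c in counts.items()]
        )
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            regions = allocate_seed_regions(spec, toy_atlas, rng, subtypes)
            table = np.zeros((len(counts), 8), dtype=int)
            for i, st in enumerate(counts):
                sel = subtypes == st
                for r in range(8):
                    table[i, r] = (regions[sel] == r + 1).sum()
            p = stats.chi2_contingency(table).pvalue
            rejections += p < 0.05
        # binomial(200, .05): 3 sigma band around 10
        assert 1 <= rejections <= 20


class TestVolumeDistribution:
    def test_from_mean_sd_round_trip(self):
        d = VolumeDistribution.from_mean_sd(87.0, 60.0)
        assert d.mean_cm3 == pytest.approx(87.0, rel=1e-12)

    def test_sample_mean_converges(self):
        d = VolumeDistribution.from_mean_sd(87.0, 60.0)
        rng = np.random.default_rng(5)
        x = d.sample(rng, size=1000)
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - 87.0) < 2 * se


class TestGenerateCohort:
    def test_determinism_and_ground_truth(self, toy_atlas):
        spec = svrlsm.toy_spec(n_subjects=12, seed=8)
        a = svrlsm.generate_cohort(spec, toy_atlas)
        b = svrlsm.generate_cohort(spec, toy_atlas)
        assert np.array_equal(a.masks, b.masks)
        assert list(a.subtype) == list(b.subtype)
        assert a.ground_truth is spec

    def test_whole_volume_matches_mask_counts(self, small_cohort):
        voxvol = small_cohort.voxel_size_mm**3 / 1000.0
        counted = small_cohort.masks.reshape(40, -1).sum(axis=1) * voxvol
        np.testing.assert_allclose(
            small_cohort.compartment_volumes_cm3["whole"].to_numpy(),
            counted, atol=1e-6,
        )

    def test_masks_are_connected_blobs(self, small_cohort):
        for i in range(0, 40, 10):
            assert n_components(small_cohort.masks[i], 6) == 1

    def test_planted_region_must_exist(self, toy_atlas):
        spec = svrlsm.toy_spec(
            n_subjects=5, planted_effects=[svrlsm.PlantedEffect("MES", 99, 2.0)]
        )
        with pytest.raises(ValueError, match="region"):
            svrlsm.generate_cohort(spec, toy_atlas)


class TestCohortSummary:
    def test_identical_groups_give_p_one(self):
        assert wilcoxon_mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_exact_p_matches_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert wilcoxon_mann_whitney(a, b) == pytest.approx(0.1, abs=1e-12)
        assert exact_mannwhitney_p(np.array(a), np.array(b)) == pytest.approx(0.1)
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(loc=0.5, size=5)
            assert wilcoxon_mann_whitney(x, y) == pytest.approx(
                exact_mannwhitney_p(x, y), abs=1e-12
            )

    def test_reference_percentages_at_423(self):
        counts = {"RTK II": 172, "MES": 143, "RTK I": 76, "other": 32}
        subtypes = np.concatenate(
            [np.full(c, k, dtype=object) for k, c in counts.items()]
        )
        masks = np.zeros((423, 4, 4, 4), dtype=bool)
        masks[:, 0, 0, 0] = True  # minimal valid masks
        cohort = svrlsm.LesionCohort(
            subject_ids=[f"s{i}" for i in range(423)],
            masks=masks, voxel_size_mm=2.0, subtype=subtypes,
        )
        table = svrlsm.cohort_summary(cohort)
        assert dict(table["pct"]) == {
            "RTK II": 40.7, "MES": 33.8, "RTK I": 18.0, "other": 7.6,
        }

    def test_volume_pvalues_present(self, small_cohort):
        table = svrlsm.cohort_summary(small_cohort)
        assert "whole" in table.attrs["pvalues"]
        assert 0 < table.attrs["pvalues"]["whole"] <= 1
        assert {"whole_mean", "whole_sd"} <= set(table.columns)


class TestSpecSerialization:
    def test_yaml_round_trip(self, tmp_path):
        spec = svrlsm.toy_spec(
            n_subjects=17, seed=4,
            planted_effects=[svrlsm.PlantedEffect("RTK I", 2, 3.0)],
        )
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = svrlsm.SyntheticCohortSpec.from_yaml(path)
        assert back == spec
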
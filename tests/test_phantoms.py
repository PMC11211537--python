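"""Phantom generator: geometry, growth, staging rule, cohort statistics."""

import numpy as np
import pytest
from scipy import ndimage, stats as sps

from npcstage.phantoms import (
    AtlasSizingError,
    InvalidCaseError,
    PhantomConfig,
    TumorGrowthError,
    build_atlas,
    generate_cohort,
    grow_tumor,
    read_manifest,
    stage_from_overlap,
    synthesize_image,
    write_cohort,
)


class TestAtlas:
    def test_all_bands_present_and_partition(self, atlas):
        labels = np.unique(atlas.regions)
        assert set(labels.tolist()) == {0, 1, 2, 3, 4}
        # nested: band b+1 voxels are farther from the centre than band b median
        assert (atlas.regions == 1).sum() > 0

    def test_deterministic_per_seed(self, phantom_config):
        a = build_atlas(phantom_config.shape, phantom_config.spacing, seed=7)
        b = build_atlas(phantom_config.shape, phantom_config.spacing, seed=7)
        np.testing.assert_array_equal(a.regions, b.regions)
        c = build_atlas(phantom_config.shape, phantom_config.spacing, seed=8)
        assert not np.array_equal(a.regions, c.regions)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(AtlasSizingError):
            build_atlas((4, 64, 64), (6.0, 0.5, 0.5), seed=0)


class TestGrowth:
    def test_single_voxel_inside_core(self, atlas):
        mask = grow_tumor(atlas, 1, seed=5)
        assert mask.sum() == 1
        assert atlas.regions[tuple(np.argwhere(mask)[0])] == 1

    def test_exact_volume_and_connectivity(self, atlas):
        mask = grow_tumor(atlas, 500, seed=5)
        assert int(mask.sum()) == 500
        _, n_components = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
        assert n_components == 1

    def test_deterministic_per_seed(self, atlas):
        np.testing.assert_array_equal(grow_tumor(atlas, 200, seed=3),
                                      grow_tumor(atlas, 200, seed=3))

    def test_unreachable_volume_raises(self, atlas):
        reachable = int((atlas.regions > 0).sum())
        with pytest.raises(TumorGrowthError):
            grow_tumor(atlas, reachable + 1, seed=0)
        with pytest.raises(TumorGrowthError):
            grow_tumor(atlas, 0, seed=0)


class TestStagingRule:
    def test_core_confined_tumor_is_stage_1(self, atlas):
        mask = np.zeros(atlas.shape, dtype=np.uint8)
        core = np.argwhere(atlas.regions == 1)
        mask[tuple(core[:5].T)] = 1
        assert stage_from_overlap(mask, atlas) == 1

    def test_band4_dominant_tumor_is_stage_4(self, atlas):
        mask = (atlas.regions == 4).astype(np.uint8)
        assert stage_from_overlap(mask, atlas) == 4

    def test_matches_bruteforce_fraction_rule(self, atlas, rng):
        thresholds = (0.05, 0.05, 0.05)
        inside = np.argwhere(atlas.regions > 0)
        for _ in range(25):
            pick = inside[rng.choice(len(inside), size=rng.integers(5, 400), replace=False)]
            mask = np.zeros(atlas.shape, dtype=np.uint8)
            mask[tuple(pick.T)] = 1
            # oracle: exhaustive per-band overlap fractions
            total = mask.sum()
            expected = 1
            for band, thr in zip((2, 3, 4), thresholds):
                if mask[atlas.regions == band].sum() / total >= thr:
                    expected = band
            assert stage_from_overlap(mask, atlas, thresholds) == expected

    def test_adding_deep_voxels_never_lowers_stage(self, atlas, rng):
        mask = grow_tumor(atlas, 300, seed=9)
        base = stage_from_overlap(mask, atlas)
        band4 = np.argwhere((atlas.regions == 4) & (mask == 0))
        grown = mask.copy()
        grown[tuple(band4[rng.choice(len(band4), 200, replace=False)].T)] = 1
        assert stage_from_overlap(grown, atlas) >= base

    def test_empty_mask_rejected(self, atlas):
        with pytest.raises(InvalidCaseError):
            stage_from_overlap(np.zeros(atlas.shape, dtype=np.uint8), atlas)


class TestCohort:
    def test_stage_labels_replay_from_masks(self, small_cohort, phantom_config):
        # the cohort's atlas is derived from the cohort seed
        cohort_atlas = build_atlas(phantom_config.shape, phantom_config.spacing, seed=11)
        for case in small_cohort:
            assert case.stage == stage_from_overlap(case.mask, cohort_atlas,
                                                    phantom_config.invasion_thresholds)

    def test_counts_within_multinomial_interval(self):
        cfg = PhantomConfig(stage_mixture=(0.25, 0.25, 0.25, 0.25))
        cases = generate_cohort(cfg, 100, seed=1)
        counts = np.bincount([c.stage for c in cases], minlength=5)[1:]
        lo, hi = sps.binom.ppf([0.005, 0.995], 100, 0.25)
        assert all(lo <= c <= hi for c in counts), counts

    def test_same_seed_gives_byte_identical_manifest(self, tmp_path, phantom_config):
        for sub in ("a", "b"):
            write_cohort(generate_cohort(phantom_config, 6, seed=2), tmp_path / sub)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
            (tmp_path / "b" / "manifest.csv").read_bytes()

    def test_manifest_roundtrip(self, tmp_path, small_cohort):
        manifest = write_cohort(small_cohort[:5], tmp_path)
        rows = read_manifest(manifest)
        assert [r["case_id"] for r in rows] == [c.case_id for c in small_cohort[:5]]
        assert all(r["volume_voxels"] == int(c.mask.sum())
                   for r, c in zip(rows, small_cohort[:5]))

    def test_mean_volume_strictly_increasing_in_stage(self, small_cohort):
        cases = generate_cohort(PhantomConfig(), 60, seed=21)
        vols = {s: [] for s in (1, 2, 3, 4)}
        for c in cases + list(small_cohort):
            vols[c.stage].append(c.mask.sum())
        means = [np.mean(vols[s]) for s in (1, 2, 3, 4) if vols[s]]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_volume_threshold_separates_stage4(self, small_cohort):
        cases = generate_cohort(PhantomConfig(), 80, seed=13)
        vols = np.array([c.mask.sum() for c in cases])
        is4 = np.array([c.stage == 4 for c in cases])
        if is4.sum() >= 3:
            from sklearn.metrics import roc_auc_score
            assert roc_auc_score(is4, vols) > 0.8

    def test_snr_matches_configured_contrast(self, atlas):
        cfg = PhantomConfig(texture_amplitude=0.0, bias_amplitude=0.0, noise_sd=0.15)
        rng = np.random.default_rng(4)
        mask = grow_tumor(atlas, 800, seed=4)
        img = synthesize_image(atlas, mask, cfg, rng)
        inside = (atlas.regions > 0) & (mask == 0)
        # shells carry a small deterministic intensity gradient; compare the
        # tumor against its own shell-mix baseline via the no-tumor image
        img0 = synthesize_image(atlas, np.zeros_like(mask), cfg, np.random.default_rng(5))
        delta = (img - img0)[mask == 1]
        n = mask.sum()
        assert abs(delta.mean() - cfg.tumor_contrast) < 3 * np.sqrt(2) * cfg.noise_sd / np.sqrt(n)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(stage_mixture=(0.5, 0.5, 0.25, -0.25))
        with pytest.raises(ValueError):
            PhantomConfig(stage_mixture=(0.3, 0.3, 0.3, 0.3))

    def test_tiny_cohort_rejected(self, phantom_config):
        with pytest.raises(ValueError):
            generate_cohort(phantom_config, 3, seed=0)
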
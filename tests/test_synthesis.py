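import numpy as np
import pytest
from scipy import stats

from longlesion.augment import AugmentationConfig
from longlesion.io_volumes import LesionMask
from longlesion.phantom import LesionAtlas, TissueMap
from longlesion.synthesis import (
    FATES,
    SynthesisConfig,
    assign_fates,
    classical_inpainter,
    corrupt_for_inpainting,
    inpaint_components,
    prepare_generator_sample,
    reconstruct_new_mask,
    sample_generation_sites,
    split_lesions,
    synthesize_pair,
)

from test_evaluate import flood_fill_components


class TestSplitLesions:
    def test_empty_mask(self):
        assert split_lesions(LesionMask(np.zeros((8, 8, 8), np.uint8))) == []

    def test_two_disjoint_cubes(self):
        m = np.zeros((12, 12, 12), np.uint8)
        m[1:4, 1:4, 1:4] = 1
        m[7:10, 7:10, 7:10] = 1
        comps = split_lesions(LesionMask(m))
        assert len(comps) == 2
        assert all(len(c.voxels) == 27 for c in comps)
        assert all(c.volume_mm3 == pytest.approx(27.0) for c in comps)

    def test_diagonal_touch_is_one_component(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[2, 2, 2] = 1
        m[3, 3, 3] = 1  # touches only diagonally
        comps = split_lesions(LesionMask(m))
        assert len(comps) == 1
        assert len(flood_fill_components(m)) == 1

    def test_labels_ordered_by_first_voxel(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[8, 8, 8] = 1
        m[1, 1, 1] = 1
        comps = split_lesions(LesionMask(m))
        assert tuple(comps[0].voxels[0]) == (1, 1, 1)
        assert comps[0].label == 1


class TestAssignFates:
    def test_degenerate_distribution(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[1:3, 1:3, 1:3] = 1
        comps = split_lesions(LesionMask(m))
        cfg = SynthesisConfig(fate_probabilities=(1.0, 0.0, 0.0, 0.0))
        fates = assign_fates(comps * 5, cfg, np.random.default_rng(0))
        assert all(f.fate == "keep_both" for f in fates)

    def test_multinomial_counts_within_3_sigma(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[1, 1, 1] = 1
        comp = split_lesions(LesionMask(m))[0]
        cfg = SynthesisConfig(fate_probabilities=(0.25, 0.25, 0.25, 0.25))
        fates = assign_fates([comp] * 10000, cfg, np.random.default_rng(3))
        counts = {f: 0 for f in FATES}
        for f in fates:
            counts[f.fate] += 1
        sigma = np.sqrt(10000 * 0.25 * 0.75)
        for f in FATES:
            assert abs(counts[f] - 2500) <= 3 * sigma

    def test_seeded_reproducibility(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[1, 1, 1] = 1
        comp = split_lesions(LesionMask(m))[0]
        cfg = SynthesisConfig()
        a = assign_fates([comp] * 50, cfg, np.random.default_rng(9))
        b = assign_fates([comp] * 50, cfg, np.random.default_rng(9))
        assert [f.fate for f in a] == [f.fate for f in b]


class TestInpainting:
    def test_empty_component_list_is_identity(self, small_phantom):
        out = inpaint_components(small_phantom["vol"], [])
        assert np.array_equal(out.data, small_phantom["vol"].data)

    def test_inpainted_region_matches_surrounding_wm(self, small_phantom):
        vol, mask, tissue = (small_phantom["vol"], small_phantom["mask"],
                             small_phantom["tissue"])
        cfg = small_phantom["cfg"]
        comps = split_lesions(mask)
        out = inpaint_components(vol, comps, classical_inpainter,
                                 np.random.default_rng(1))
        for comp in comps:
            region = comp.mask(vol.shape)
            shell = tissue.wm & ~region
            assert abs(out.data[region].mean() - vol.data[shell].mean()) \
                < 2 * cfg.noise_sd + 0.05

    def test_locality_voxels_far_from_components_untouched(self, small_phantom):
        from scipy import ndimage

        vol, mask = small_phantom["vol"], small_phantom["mask"]
        comps = split_lesions(mask)
        out = inpaint_components(vol, comps, classical_inpainter,
                                 np.random.default_rng(1))
        far = ~ndimage.binary_dilation(mask.data > 0, np.ones((3, 3, 3)),
                                       iterations=3)
        assert np.array_equal(out.data[far], vol.data[far])

    def test_out_of_grid_component_rejected(self, small_phantom):
        from longlesion.synthesis import LesionComponent

        bad = LesionComponent(1, np.array([[100, 0, 0]]), 1.0)
        with pytest.raises(ValueError, match="outside"):
            inpaint_components(small_phantom["vol"], [bad])


class TestCorruptForInpainting:
    def test_zero_regions_identity(self, small_phantom, rng):
        vol = small_phantom["vol"]
        clean = LesionMask(np.zeros(vol.shape, np.uint8))
        corrupted, target, region = corrupt_for_inpainting(
            vol, clean, rng, n_regions_range=(0, 0))
        assert np.array_equal(corrupted.data, target.data)
        assert region.n_voxels == 0

    def test_filled_region_has_global_statistics(self, small_phantom):
        vol = small_phantom["vol"]
        clean = LesionMask(np.zeros(vol.shape, np.uint8))
        corrupted, target, region = corrupt_for_inpainting(
            vol, clean, np.random.default_rng(4), n_regions_range=(3, 3))
        r = region.data > 0
        n = int(r.sum())
        assert n > 0
        sd = float(vol.data.std())
        assert abs(corrupted.data[r].mean() - vol.data.mean()) < 3 * sd / np.sqrt(n)

    def test_regions_are_connected_blobs(self, small_phantom):
        vol = small_phantom["vol"]
        clean = LesionMask(np.zeros(vol.shape, np.uint8))
        _, _, region = corrupt_for_inpainting(
            vol, clean, np.random.default_rng(8), n_regions_range=(2, 2),
            radius_range_mm=(2.0, 3.0))
        comps = flood_fill_components(region.data)
        assert 1 <= len(comps) <= 2
        for comp in comps:
            arr = np.array(comp)
            extent = arr.max(axis=0) - arr.min(axis=0)
            assert (extent <= 2 * np.ceil(3.0 * 1.3) + 1).all()


class TestGeneratorSample:
    def test_channels_and_locality(self, small_phantom):
        vol, mask = small_phantom["vol"], small_phantom["mask"]
        channels, target = prepare_generator_sample(vol, mask,
                                                    np.random.default_rng(2))
        assert channels.shape == (2,) + vol.shape
        assert np.array_equal(channels[1], mask.data.astype(np.float64))
        outside = mask.data == 0
        assert np.array_equal(channels[0][outside],
                              vol.data.astype(np.float64)[outside])
        assert np.array_equal(target, vol.data.astype(np.float64))

    def test_masked_region_decorrelated_from_target(self, small_phantom):
        vol, mask = small_phantom["vol"], small_phantom["mask"]
        channels, target = prepare_generator_sample(vol, mask,
                                                    np.random.default_rng(2))
        inside = mask.data > 0
        r = np.corrcoef(channels[0][inside], target[inside])[0, 1]
        assert abs(r) < 0.3

    def test_empty_mask_rejected(self, small_phantom):
        empty = LesionMask(np.zeros(small_phantom["vol"].shape, np.uint8))
        with pytest.raises(ValueError):
            prepare_generator_sample(small_phantom["vol"], empty,
                                     np.random.default_rng(0))


class TestGenerationSites:
    def _uniform_setup(self):
        labels = np.zeros((20, 20, 20), np.uint8)
        labels[4:16, 4:16, 4:16] = 3  # WM cube
        tissue = TissueMap(labels)
        atlas_data = np.zeros(labels.shape)
        atlas_data[labels == 3] = 1.0
        atlas = LesionAtlas(atlas_data / atlas_data.sum())
        return tissue, atlas

    def test_empirical_distribution_uniform_over_wm(self):
        tissue, atlas = self._uniform_setup()
        rng = np.random.default_rng(0)
        sites = sample_generation_sites(tissue, atlas, 10000, rng,
                                        min_separation=0)
        # chi-square against uniformity over the 12^3 WM cube, coarse 3x3x3 bins
        counts = np.zeros((3, 3, 3))
        for s in sites:
            counts[tuple((np.array(s) - 4) // 4)] += 1
        _, p = stats.chisquare(counts.ravel())
        assert p > 0.01

    def test_point_atlas_pins_all_sites(self):
        labels = np.zeros((10, 10, 10), np.uint8)
        labels[2:8, 2:8, 2:8] = 3
        tissue = TissueMap(labels)
        atlas_data = np.zeros(labels.shape)
        atlas_data[5, 5, 5] = 1.0
        atlas = LesionAtlas(atlas_data)
        sites = sample_generation_sites(tissue, atlas, 3,
                                        np.random.default_rng(0),
                                        min_separation=0)
        assert sites == [(5, 5, 5)] * 3

    def test_zero_sites(self):
        tissue, atlas = self._uniform_setup()
        assert sample_generation_sites(tissue, atlas, 0,
                                       np.random.default_rng(0)) == []

    def test_pairwise_separation(self):
        tissue, atlas = self._uniform_setup()
        sites = sample_generation_sites(tissue, atlas, 5,
                                        np.random.default_rng(1),
                                        min_separation=3)
        for i, a in enumerate(sites):
            for b in sites[i + 1:]:
                assert max(abs(x - y) for x, y in zip(a, b)) >= 3


class TestSynthesizePair:
    def test_keep_all_no_generation(self, small_phantom):
        cfg = SynthesisConfig(fate_probabilities=(1, 0, 0, 0),
                              n_generated_range=(0, 0), seed=3)
        s = synthesize_pair(small_phantom["vol"], small_phantom["mask"],
                            small_phantom["tissue"], small_phantom["atlas"], cfg)
        assert s.new_mask.n_voxels == 0
        # without quality augmentation the two copies are identical
        assert np.array_equal(s.tp1.data, s.tp2.data)

    def test_all_components_removed_from_tp1(self, small_phantom):
        cfg = SynthesisConfig(fate_probabilities=(0, 1, 0, 0),
                              n_generated_range=(0, 0), seed=4)
        s = synthesize_pair(small_phantom["vol"], small_phantom["mask"],
                            small_phantom["tissue"], small_phantom["atlas"], cfg)
        # new mask equals the (geometrically transformed) original support
        union = np.zeros(s.new_mask.shape, bool)
        for f in s.fates:
            union |= f.component.mask(s.new_mask.shape)
        assert np.array_equal(s.new_mask.data > 0, union)
        assert s.new_mask.n_voxels == small_phantom["mask"].n_voxels
        # tp1 is lesion-free there: intensities near WM level
        cfgp = small_phantom["cfg"]
        assert s.tp1.data[union].mean() < cfgp.wm_intensity + cfgp.lesion_contrast / 4

    def test_determinism(self, small_phantom):
        cfg = SynthesisConfig(seed=12)
        aug = AugmentationConfig()
        a = synthesize_pair(small_phantom["vol"], small_phantom["mask"],
                            small_phantom["tissue"], small_phantom["atlas"],
                            cfg, aug)
        b = synthesize_pair(small_phantom["vol"], small_phantom["mask"],
                            small_phantom["tissue"], small_phantom["atlas"],
                            cfg, aug)
        assert np.array_equal(a.tp1.data, b.tp1.data)
        assert np.array_equal(a.tp2.data, b.tp2.data)
        assert np.array_equal(a.new_mask.data, b.new_mask.data)
        assert [f.fate for f in a.fates] == [f.fate for f in b.fates]

    def test_bookkeeping_and_disjointness_sweep(self, small_phantom):
        for seed in range(30):
            cfg = SynthesisConfig(seed=seed)
            s = synthesize_pair(small_phantom["vol"], small_phantom["mask"],
                                small_phantom["tissue"], small_phantom["atlas"],
                                cfg)
            rec = reconstruct_new_mask(s, s.new_mask.shape)
            assert np.array_equal(rec, s.new_mask.data > 0)
            tp1_support = np.zeros(s.new_mask.shape, bool)
            for f in s.fates:
                if f.fate in ("keep_both", "remove_tp2"):
                    tp1_support |= f.component.mask(s.new_mask.shape)
            for site in s.generated_sites:
                if site.placement in ("tp1_only", "both"):
                    tp1_support |= site.mask
            assert not (tp1_support & (s.new_mask.data > 0)).any()

    def test_generated_both_identical_realization(self, small_phantom):
        cfg = SynthesisConfig(fate_probabilities=(1, 0, 0, 0),
                              n_generated_range=(3, 3),
                              generated_placement_probabilities={
                                  "both": 1.0, "tp2_only": 0.0, "tp1_only": 0.0},
                              seed=6)
        s = synthesize_pair(small_phantom["vol"], small_phantom["mask"],
                            small_phantom["tissue"], small_phantom["atlas"], cfg)
        assert s.new_mask.n_voxels == 0
        assert np.array_equal(s.tp1.data, s.tp2.data)
        assert all(site.placement == "both" for site in s.generated_sites)


class TestConfigValidation:
    def test_fate_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SynthesisConfig(fate_probabilities=(0.5, 0.2, 0.2, 0.2))

    def test_placement_keys_checked(self):
        with pytest.raises(ValueError):
            SynthesisConfig(generated_placement_probabilities={"tp2_only": 1.0})
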
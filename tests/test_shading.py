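"""Shading-map construction and intensity normalization."""

import numpy as np
import pytest
from scipy import ndimage

from mr2ct.evaluate import tissue_stats
from mr2ct.shading import (BulkIntensities, build_three_intensity_mask,
                           compute_ratio_image, correct_intensity,
                           normalize_mri, smooth_ratio)
from mr2ct.simulate import (BiasSpec, PhantomConfig, make_bias_field,
                            make_torso_phantom)
from mr2ct.volume import TissueLabelMap, Volume


def bulk_of(levels):
    return BulkIntensities({k: float(v) for k, v in levels.items()})


class TestThreeIntensityMask:
    def test_table_lookup(self):
        labels = TissueLabelMap(np.array([[[0, 1], [2, 2]]]))
        mask = build_three_intensity_mask(labels,
                                          BulkIntensities({0: 14, 1: 64, 2: 149}))
        np.testing.assert_array_equal(mask.data[0], [[14, 64], [149, 149]])

    def test_uniform_label_gives_constant(self):
        labels = TissueLabelMap(np.ones((2, 5, 5), dtype=int))
        mask = build_three_intensity_mask(labels, BulkIntensities({0: 1, 1: 64, 2: 149}))
        assert np.all(mask.data == 64)
        assert len(np.unique(mask.data)) == 1

    def test_phantom_truth_reconstructs_clean_mri(self, clean_chest_phantom):
        ph = clean_chest_phantom
        mask = build_three_intensity_mask(ph.labels,
                                          bulk_of(ph.config.tissue_mri_levels))
        np.testing.assert_array_equal(mask.data, ph.clean_mri.data)

    def test_bulk_table_validation(self):
        with pytest.raises(ValueError):
            BulkIntensities({0: 10, 1: 20})
        with pytest.raises(ValueError):
            BulkIntensities({0: 10, 1: -5, 2: 20})


class TestRatioImage:
    def test_identity_and_scaling(self, rng):
        mask = Volume(rng.uniform(10, 100, (2, 8, 8)))
        assert np.all(compute_ratio_image(mask, mask).data == 1.0)
        doubled = mask.copy_with(2 * mask.data)
        assert np.allclose(compute_ratio_image(doubled, mask).data, 2.0)

    def test_recovers_known_bias_field(self, clean_chest_phantom):
        ph = clean_chest_phantom
        bias = make_bias_field(ph.mri.shape, BiasSpec(amplitude=0.2), seed=3)
        biased = ph.clean_mri.copy_with(ph.clean_mri.data * bias.data)
        ratio = compute_ratio_image(biased, ph.clean_mri)
        np.testing.assert_allclose(ratio.data, bias.data, rtol=1e-10)

    def test_nonpositive_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_ratio_image(Volume(np.ones((1, 4, 4))),
                                Volume(np.zeros((1, 4, 4))))


class TestSmoothRatio:
    def test_constant_preserved(self):
        sm = smooth_ratio(Volume(np.full((2, 30, 30), 3.7)), width=10)
        np.testing.assert_allclose(sm.map.data, 3.7, rtol=1e-12)

    def test_single_pixel_box_response(self):
        """A +h spike spreads as exactly h/100 over the even-offset 10x10 window."""
        img = np.ones((1, 40, 40))
        img[0, 20, 20] += 100.0
        sm = smooth_ratio(Volume(img), width=10)
        delta = sm.map.data[0] - 1.0
        expected = np.zeros((40, 40))
        expected[16:26, 16:26] = 1.0        # window [i-5, i+4] around 20
        np.testing.assert_allclose(delta, expected, atol=1e-12)

    def test_width_one_is_identity(self, rng):
        vol = Volume(rng.uniform(0.5, 2.0, (2, 12, 12)))
        sm = smooth_ratio(vol, width=1)
        np.testing.assert_allclose(sm.map.data, vol.data)

    def test_width_larger_than_slice_rejected(self):
        with pytest.raises(ValueError):
            smooth_ratio(Volume(np.ones((1, 8, 8))), width=10)

    def test_output_strictly_positive_even_for_zero_ratio(self):
        sm = smooth_ratio(Volume(np.zeros((1, 20, 20)) + 1e-30), width=5)
        assert np.all(sm.map.data > 0)


class TestCorrectIntensity:
    def test_identity_and_homogeneity(self, rng):
        mri = Volume(rng.uniform(10, 300, (2, 20, 20)))
        ones = smooth_ratio(Volume(np.ones(mri.shape)), width=1)
        np.testing.assert_allclose(correct_intensity(mri, ones).data, mri.data)
        double = smooth_ratio(Volume(np.full(mri.shape, 2.0)), width=1)
        np.testing.assert_allclose(correct_intensity(mri, double).data,
                                   mri.data / 2)

    def test_width_one_pipeline_reproduces_mask_exactly(self, clean_chest_phantom):
        """With width-1 smoothing the corrected volume equals the mask."""
        ph = clean_chest_phantom
        bulk = bulk_of(ph.config.tissue_mri_levels)
        corrected, _, _ = normalize_mri(ph.mri, bulk=bulk, width=1,
                                        labels=ph.labels)
        np.testing.assert_allclose(corrected.data, ph.clean_mri.data, rtol=1e-9)


def interior_mask(labels: np.ndarray, margin: int = 10) -> np.ndarray:
    """Voxels at least `margin` px from any class boundary, per slice."""
    out = np.zeros(labels.shape, bool)
    for s in range(labels.shape[0]):
        edges = (ndimage.maximum_filter(labels[s], 3)
                 != ndimage.minimum_filter(labels[s], 3))
        out[s] = ~ndimage.binary_dilation(edges, iterations=margin)
    return out


class TestNormalizeMri:
    @pytest.fixture(scope="class")
    def recovery(self):
        """Phantom with smooth bias and noise, bulk = true class levels."""
        ph = make_torso_phantom(PhantomConfig(
            shape=(6, 160, 160), bias=BiasSpec(amplitude=0.3, length_scale=40),
            noise_sd=5.0, seed=21))
        corrected, shading, labels = normalize_mri(
            ph.mri, bulk=bulk_of(ph.config.tissue_mri_levels))
        return ph, corrected, shading, labels

    def test_fat_and_soft_cv_decrease(self, recovery):
        ph, corrected, _, _ = recovery
        before = tissue_stats(ph.mri, ph.labels)
        after = tissue_stats(corrected, ph.labels)
        for tissue in (1, 2):
            assert (after.for_tissue(tissue).cv_percent
                    < before.for_tissue(tissue).cv_percent)

    def test_shading_map_recovers_bias_interior(self, recovery):
        ph, _, shading, _ = recovery
        inside = interior_mask(ph.labels.labels) & (ph.labels.labels > 0)
        rel = (shading.map.data[inside] - ph.bias_field.data[inside]) \
            / ph.bias_field.data[inside]
        assert np.sqrt(np.mean(rel**2)) < 0.02

    def test_corrected_means_land_at_bulk_levels(self, recovery):
        ph, corrected, _, labels = recovery
        stats = tissue_stats(corrected, labels)
        for tissue, level in ph.config.tissue_mri_levels.items():
            mean = stats.for_tissue(tissue)["mean"]
            assert abs(mean - level) / level < 0.05

    def test_edge_contrast_preserved(self, recovery):
        """Fat/soft step contrast across the boundary survives correction
        within 10 percent (the shading map is smooth, edges are not)."""
        ph, corrected, _, _ = recovery
        lab = ph.labels.labels
        # 2-px bands on either side of the fat/soft interface, per slice
        fat_band = np.zeros(lab.shape, bool)
        soft_band = np.zeros(lab.shape, bool)
        for s in range(lab.shape[0]):
            soft = lab[s] == 1
            fat = lab[s] == 2
            near_soft = ndimage.binary_dilation(soft, iterations=2)
            near_fat = ndimage.binary_dilation(fat, iterations=2)
            fat_band[s] = fat & near_soft
            soft_band[s] = soft & near_fat
        step = lambda vol: (vol.data[fat_band].mean()
                            - vol.data[soft_band].mean())
        ratio = step(corrected) / step(ph.clean_mri)
        assert 0.9 < ratio < 1.1

    def test_inter_scanner_harmonization(self):
        """One bulk table maps x1 and x(533/297) level tables to equal means."""
        from mr2ct.simulate import CHEST_MRI_LEVELS
        scale = 533.0 / 297.0
        means = {}
        for name, factor, seed in [("chest", 1.0, 1), ("scaled", scale, 2)]:
            levels = {k: v * factor for k, v in CHEST_MRI_LEVELS.items()}
            ph = make_torso_phantom(PhantomConfig(
                shape=(6, 160, 160), tissue_mri_levels=levels, seed=seed))
            corrected, _, labels = normalize_mri(ph.mri)
            means[name] = tissue_stats(corrected, labels).for_tissue(2)["mean"]
        assert abs(means["chest"] - means["scaled"]) / means["chest"] < 0.05
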
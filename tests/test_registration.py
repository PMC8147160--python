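"""Mattes mutual information metric and rigid registration."""

import numpy as np
import pytest

from mr2ct.registration import (MattesConfig, OptimizerSettings, RigidTransform,
                                _mi_from_samples, apply_deformation, mattes_mi,
                                resample, rigid_register, volume_center_mm)
from mr2ct.volume import Volume


@pytest.fixture(scope="module")
def textured(small_chest_phantom):
    return small_chest_phantom.mri


class TestMattesMI:
    def test_self_information_dominates_permutation(self, textured, rng):
        perm = Volume(rng.permutation(textured.data.ravel()).reshape(textured.shape))
        cfg = MattesConfig(samples=5000)
        assert mattes_mi(textured, textured, cfg=cfg) \
            > mattes_mi(textured, perm, cfg=cfg) + 0.5

    def test_independent_noise_mi_consistent_with_zero(self, rng):
        """Independence: observed MI is within the small-sample bias null
        spread (estimated by repetition) and decays with sample size."""
        x = rng.uniform(size=60000)
        y = rng.uniform(size=60000)
        obs = _mi_from_samples(x[:5000], y[:5000], 50)
        null = [_mi_from_samples(x[:5000],
                                 np.random.default_rng(i).permutation(y[:5000]),
                                 50) for i in range(8)]
        lo, hi = min(null), max(null)
        spread = hi - lo
        assert lo - 3 * spread < obs < hi + 3 * spread
        # bias shrinks roughly like 1/n
        big = _mi_from_samples(x, y, 50)
        assert big < obs / 4

    def test_gaussian_pair_matches_closed_form(self, rng):
        """Jointly Gaussian, rho = 0.9: MI within 25% of -0.5*ln(1-rho^2)."""
        rho = 0.9
        n = 40000
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        mi = _mi_from_samples(x, y, 50)
        truth = -0.5 * np.log(1 - rho**2)
        assert abs(mi - truth) / truth < 0.25

    def test_invariance_to_monotone_affine_rescaling(self, textured):
        cfg = MattesConfig(samples=4000)
        base = mattes_mi(textured, textured, cfg=cfg)
        rescaled = textured.copy_with(3.0 * textured.data + 50.0)
        assert abs(mattes_mi(textured, rescaled, cfg=cfg) - base) < 0.05 * base

    def test_landscape_peaks_at_true_alignment(self, textured):
        cfg = MattesConfig(samples=4000)
        center = volume_center_mm(textured)
        at_zero = mattes_mi(textured, textured,
                            RigidTransform(center_mm=center), cfg)
        for axis in (1, 2):
            for sign in (-1, 1):
                t = [0.0, 0.0, 0.0]
                t[axis] = sign * 2 * textured.spacing[axis]
                off = mattes_mi(textured, textured,
                                RigidTransform(translation_mm=tuple(t),
                                               center_mm=center), cfg)
                assert at_zero > off

    def test_errors(self, textured):
        const = Volume(np.full(textured.shape, 5.0))
        with pytest.raises(ValueError, match="constant"):
            mattes_mi(textured, const)
        far = RigidTransform(translation_mm=(0.0, 1e5, 0.0),
                             center_mm=volume_center_mm(textured))
        with pytest.raises(ValueError, match="overlap"):
            mattes_mi(textured, textured, far)

    def test_cross_check_against_simpleitk(self, textured):
        """Independent oracle: SimpleITK's Mattes metric ranks the same
        alignments in the same order as this implementation."""
        sitk = pytest.importorskip("SimpleITK")
        img = sitk.GetImageFromArray(textured.data.astype(np.float32))
        img.SetSpacing(tuple(reversed(textured.spacing)))

        def sitk_mi(shift_px):
            reg = sitk.ImageRegistrationMethod()
            reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
            reg.SetMetricSamplingStrategy(reg.NONE)
            tr = sitk.TranslationTransform(3)
            tr.SetOffset((shift_px * textured.spacing[2], 0.0, 0.0))
            reg.SetInitialTransform(tr)
            return -reg.MetricEvaluate(img, img)

        def ours(shift_px):
            t = RigidTransform(translation_mm=(0, 0, shift_px * textured.spacing[2]),
                               center_mm=volume_center_mm(textured))
            return mattes_mi(textured, textured, t, MattesConfig(samples=8000))

        shifts = [0.0, 2.0, 5.0]
        ours_vals = [ours(s) for s in shifts]
        sitk_vals = [sitk_mi(s) for s in shifts]
        assert np.argsort(ours_vals).tolist() == np.argsort(sitk_vals).tolist()


class TestRigidRegister:
    def test_identity_recovered_for_same_volume(self, textured):
        res = rigid_register(textured, textured,
                             opt=OptimizerSettings(max_sweeps=6))
        assert np.all(np.abs(res.transform.rotation_deg) < 0.1)
        px = np.array(res.transform.translation_mm) / np.array(textured.spacing)
        assert np.all(np.abs(px) < 0.1)

    def test_known_translation_recovered_within_half_pixel(self, textured):
        """Moving = fixed shifted by (3, -2, 0) px; the registration finds
        the pull-back transform, i.e. the inverse (negated) translation."""
        t_true = RigidTransform(
            translation_mm=(0.0, 3.0 * textured.spacing[1],
                            -2.0 * textured.spacing[2]),
            center_mm=volume_center_mm(textured))
        moved = resample(textured, t_true, textured, fill=0.0)
        res = rigid_register(textured, moved)
        rec_px = np.array(res.transform.translation_mm) / np.array(textured.spacing)
        np.testing.assert_allclose(rec_px, [0.0, -3.0, 2.0], atol=0.5)

    def test_known_inplane_rotation_recovered_within_one_degree(self, textured):
        t_true = RigidTransform(rotation_deg=(5.0, 0.0, 0.0),
                                center_mm=volume_center_mm(textured))
        moved = resample(textured, t_true, textured, fill=0.0)
        res = rigid_register(textured, moved)
        assert abs(abs(res.transform.rotation_deg[0]) - 5.0) < 1.0


class TestResample:
    def test_identity_same_grid(self, textured):
        out = resample(textured, RigidTransform(), textured, fill=0.0)
        np.testing.assert_allclose(out.data, textured.data, atol=1e-9)

    def test_integer_translation_is_index_shift(self, rng):
        vol = Volume(rng.uniform(0, 100, (3, 10, 10)))
        t = RigidTransform(translation_mm=(0.0, 2.0, 0.0))
        out = resample(vol, t, vol, fill=-1.0)
        np.testing.assert_allclose(out.data[:, :8, :], vol.data[:, 2:, :])
        assert np.all(out.data[:, 8:, :] == -1.0)

    def test_half_voxel_shift_of_linear_ramp(self):
        ramp = Volume(np.tile(np.arange(10.0), (1, 10, 1)))
        t = RigidTransform(translation_mm=(0.0, 0.0, 0.5))
        out = resample(ramp, t, ramp, fill=0.0)
        np.testing.assert_allclose(out.data[0, :, :9],
                                   ramp.data[0, :, :9] + 0.5, atol=1e-9)

    def test_constants_preserved(self):
        const = Volume(np.full((3, 8, 8), 42.0))
        t = RigidTransform(rotation_deg=(3.0, 0, 0),
                           center_mm=volume_center_mm(const))
        out = resample(const, t, const, fill=42.0)
        np.testing.assert_allclose(out.data, 42.0)


class TestApplyDeformation:
    def test_zero_field_is_identity(self, textured):
        field = np.zeros(textured.shape + (3,))
        out = apply_deformation(textured, field, textured)
        np.testing.assert_allclose(out.data, textured.data, atol=1e-9)

    def test_constant_field_matches_translation(self, rng):
        vol = Volume(rng.uniform(0, 100, (3, 12, 12)))
        field = np.zeros(vol.shape + (3,))
        field[..., 1] = 1.0        # one voxel along rows
        warped = apply_deformation(vol, field, vol, fill=0.0)
        shifted = resample(vol, RigidTransform(translation_mm=(0.0, 1.0, 0.0)),
                           vol, fill=0.0)
        np.testing.assert_allclose(warped.data, shifted.data, atol=1e-9)

    def test_sinusoidal_field_roundtrip_residual_small(self):
        """Warping by a smooth field then by its negation nearly cancels."""
        base = np.tile(np.linspace(0, 100, 40), (1, 40, 1)) \
            + np.tile(np.linspace(0, 50, 40)[:, None], (1, 1, 40))
        vol = Volume(base)
        rr, cc = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        disp = 0.8 * np.sin(2 * np.pi * rr / 40) * np.cos(2 * np.pi * cc / 40)
        field = np.zeros(vol.shape + (3,))
        field[0, ..., 2] = disp
        warped = apply_deformation(vol, field, vol, fill=0.0)
        back = apply_deformation(warped, -field, vol, fill=0.0)
        inner = (slice(0, 1), slice(5, 35), slice(5, 35))
        resid = np.abs(back.data[inner] - vol.data[inner])
        # 0.2 voxel of the local gradient (~2.5 a.u. per voxel in-plane)
        assert np.median(resid) < 0.2 * 2.6

    def test_shape_mismatch_rejected(self, textured):
        with pytest.raises(ValueError):
            apply_deformation(textured, np.zeros((2, 2, 2, 3)), textured)
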
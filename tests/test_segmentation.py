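import numpy as np
import pytest

import robustpet as rp
from robustpet.errors import EmptyMaskError, SegmentationError
from robustpet.segmentation import (
    COAParams,
    SeedROI,
    SegMask,
    calibrate_coa,
    estimate_background,
    recovery_coefficient,
    segment_coa,
    segment_region_growing,
    segment_threshold40,
)


def _pet(values, spacing=1.0):
    return rp.VolumeGrid(np.asarray(values, dtype=float), spacing)


def _two_level_lesion(inner=6.0, outer=1.0, bg=0.1):
    """Unblurred two-layer cube lesion: hot 4^3 core inside a 8^3 shell."""
    v = np.full((16, 16, 16), bg)
    v[4:12, 4:12, 4:12] = outer
    v[6:10, 6:10, 6:10] = inner
    truth = np.zeros(v.shape, dtype=bool)
    truth[4:12, 4:12, 4:12] = True
    return _pet(v), truth


class TestRegionGrowing:
    def test_clean_lesion_recovered_exactly(self):
        scene = rp.lesion_bed_scene(rp.homogeneous_sphere(8.0, 5.0), "s")
        _, truth, ct = rp.build_scene(scene, 1.0)
        seed = tuple(np.array(np.nonzero(truth.masks["s"]))[:, 0])
        m = segment_region_growing(ct, seed, smooth_radius_vox=0.0)
        assert np.array_equal(m.mask, truth.masks["s"])

    def test_smoothed_edge_within_one_voxel_layer(self):
        scene = rp.lesion_bed_scene(rp.homogeneous_sphere(8.0, 5.0), "s")
        _, truth, ct = rp.build_scene(scene, 1.0)
        seed = tuple(int(round(c)) for c in
                     np.array(np.nonzero(truth.masks["s"])).mean(axis=1))
        m = segment_region_growing(ct, seed, smooth_radius_vox=2.0)
        from scipy.ndimage import binary_dilation, binary_erosion

        sym_diff = m.mask ^ truth.masks["s"]
        # every disagreeing voxel lies in the +-1 voxel boundary band
        band = binary_dilation(truth.masks["s"]) & ~binary_erosion(
            truth.masks["s"]
        )
        assert np.all(sym_diff <= band)

    def test_connectivity_excludes_second_lesion(self):
        ct = _pet(np.zeros((20, 20, 20)))
        ct.values[2:6, 2:6, 2:6] = 100.0
        ct.values[12:16, 12:16, 12:16] = 100.0
        m = segment_region_growing(ct, (3, 3, 3), smooth_radius_vox=0.0)
        assert m.mask[3, 3, 3] and not m.mask[13, 13, 13]

    def test_seed_outside_window_raises(self):
        ct = _pet(np.zeros((10, 10, 10)))
        with pytest.raises(SegmentationError):
            segment_region_growing(ct, (5, 5, 5))


class TestThreshold40:
    def test_clean_sphere_exact(self):
        v = np.ones((12, 12, 12))
        v[4:8, 4:8, 4:8] = 10.0
        pet = _pet(v)
        roi = SeedROI((2, 2, 2), (10, 10, 10))
        m = segment_threshold40(pet, roi)
        expect = np.zeros_like(v, dtype=bool)
        expect[4:8, 4:8, 4:8] = True
        assert np.array_equal(m.mask, expect)

    def test_inward_hot_lesion_rejects_cold_periphery(self):
        pet, truth = _two_level_lesion(inner=6.0, outer=1.0)
        roi = SeedROI.from_mask(truth, margin_vox=1)
        m = segment_threshold40(pet, roi)  # T = 2.4 > outer layer
        assert m.mask.sum() == 4**3
        assert m.volume_ml < truth.sum() / 1000.0

    def test_scale_invariance(self):
        pet, truth = _two_level_lesion()
        roi = SeedROI.from_mask(truth, margin_vox=1)
        a = segment_threshold40(pet, roi)
        b = segment_threshold40(_pet(pet.values * 7.3), roi)
        assert np.array_equal(a.mask, b.mask)

    def test_constant_roi_returns_roi_with_warning(self):
        pet = _pet(np.ones((10, 10, 10)))
        roi = SeedROI((2, 2, 2), (8, 8, 8))
        with pytest.warns(UserWarning):
            m = segment_threshold40(pet, roi)
        assert m.n_voxels == 6**3


class TestEstimateBackground:
    def test_uniform_image(self):
        assert estimate_background(_pet(np.full((10, 10, 10), 2.5))) == \
            pytest.approx(2.5, rel=0.01)

    def test_noisy_background_with_hot_lesions_excluded(self):
        rng = np.random.default_rng(0)
        v = rng.normal(1.0, 0.05, size=(24, 24, 24))
        v[2:8, 2:8, 2:8] = 10.0
        excl = np.zeros(v.shape, dtype=bool)
        excl[0:10, 0:10, 0:10] = True
        bg = estimate_background(_pet(np.clip(v, 0, None)), excl)
        assert 0.97 <= bg <= 1.03

    def test_normalized_phantom_background_near_one(self, blurred_sphere_pet):
        pet, truth, _ = blurred_sphere_pet
        bgm = truth.background_mask(margin_mm=10.0)
        bgm2 = rp.block_downsample_mask(bgm, 2, threshold=0.999)
        normed = rp.normalize_background(pet, bgm2)
        excl = rp.block_downsample_mask(~truth.background_mask(5.0), 2, 0.01)
        assert estimate_background(normed, excl) == pytest.approx(1.0, abs=0.05)


class TestCOA:
    def test_homogeneous_lesion_hand_computation(self):
        v = np.ones((12, 12, 12))
        v[4:8, 4:8, 4:8] = 10.0
        pet = _pet(v)
        roi = SeedROI((2, 2, 2), (10, 10, 10))
        m = segment_coa(pet, roi, COAParams(0.5, 0.5), bg=1.0)
        # I70 = 10, T = 5.5 -> lesion exactly
        assert m.n_voxels == 4**3

    def test_zero_background_reduces_to_relative_threshold(self):
        v = np.zeros((12, 12, 12))
        v[4:8, 4:8, 4:8] = 10.0
        v[0, 0, 0] = 1e-9
        pet = _pet(v)
        roi = SeedROI((2, 2, 2), (10, 10, 10))
        m40 = segment_threshold40(pet, roi)
        mcoa = segment_coa(pet, roi, COAParams(a=0.4, b=0.0), bg=0.0)
        assert np.array_equal(m40.mask, mcoa.mask)

    def test_joint_scale_invariance(self):
        pet, truth = _two_level_lesion()
        roi = SeedROI.from_mask(truth, margin_vox=1)
        a = segment_coa(pet, roi, bg=0.1)
        b = segment_coa(_pet(pet.values * 3), roi, bg=0.3)
        assert np.array_equal(a.mask, b.mask)

    def test_threshold_above_max_raises_empty_mask(self):
        pet = _pet(np.ones((10, 10, 10)) + 0.001 *
                   np.random.default_rng(0).random((10, 10, 10)))
        roi = SeedROI((2, 2, 2), (8, 8, 8))
        with pytest.raises(EmptyMaskError):
            segment_coa(pet, roi, COAParams(a=1.0, b=5.0), bg=1.0)


class TestRecoveryCoefficient:
    def test_identity_and_ratio(self):
        m = SegMask(np.ones((2, 2, 2), dtype=bool), 1.0, "gt")
        assert recovery_coefficient(m, m) == 1.0
        m8 = SegMask(np.arange(10) < 8, 1.0, "th40")
        m10 = SegMask(np.ones(10, dtype=bool), 1.0, "gt")
        assert recovery_coefficient(m8, m10) == pytest.approx(0.8)

    def test_zero_reference_raises(self):
        empty = SegMask(np.zeros((2, 2, 2), dtype=bool), 1.0, "gt")
        full = SegMask(np.ones((2, 2, 2), dtype=bool), 1.0, "gt")
        with pytest.raises(SegmentationError):
            recovery_coefficient(full, empty)


class TestSegmentationBehaviour:
    """PVE-scale behaviour on blurred phantom lesions."""

    def test_both_pet_methods_within_15pct_on_large_sphere(
        self, blurred_sphere_pet
    ):
        pet, truth, mask2 = blurred_sphere_pet
        true_ml = truth.true_volumes_ml["sph"]
        roi = SeedROI.from_mask(mask2, margin_vox=2)
        v40 = segment_threshold40(pet, roi).volume_ml
        vcoa = segment_coa(pet, roi, COAParams(0.5, 0.5), bg=1.0).volume_ml
        assert abs(v40 - true_ml) / true_ml < 0.15
        assert abs(vcoa - true_ml) / true_ml < 0.15

    def test_calibrated_coa_improves_volume_error_on_spheres(self):
        cases = []
        for radius in (10.0, 13.0, 16.0):
            scene = rp.lesion_bed_scene(
                rp.homogeneous_sphere(radius, 10.0), "s", margin_mm=15.0)
            act, truth, _ = rp.build_scene(scene, 1.0)
            pet = rp.apply_system(act, rp.SystemModel(4.8, 2.0, 0.0, 0))
            m2 = rp.block_downsample_mask(truth.masks["s"], 2)
            roi = SeedROI.from_mask(m2, margin_vox=2)
            cases.append((pet, roi, truth.true_volumes_ml["s"]))
        params = calibrate_coa(cases, bg=1.0)
        assert params.a >= 0 and params.b >= 0

        def mean_err(p):
            return np.mean([
                abs(segment_coa(pet, roi, p, bg=1.0).volume_ml - v) / v
                for pet, roi, v in cases
            ])

        assert mean_err(params) <= mean_err(COAParams(0.5, 0.5)) + 1e-9
        assert mean_err(params) < 0.1

    def test_inward_hot_multilayer_undersegmented(self, inward_hot_lesion_pet):
        pet, truth, mask2 = inward_hot_lesion_pet
        true_ml = truth.true_volumes_ml["l4"]
        roi = SeedROI.from_mask(mask2, margin_vox=2)
        v40 = segment_threshold40(pet, roi).volume_ml
        vcoa = segment_coa(pet, roi, COAParams(0.5, 0.5), bg=1.0).volume_ml
        assert v40 < true_ml
        assert vcoa < true_ml
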
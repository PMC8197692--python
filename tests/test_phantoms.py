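import numpy as np
import pytest

import robustpet as rp
from robustpet.errors import ConfigurationError
from robustpet.phantoms import (
    V_SERIES_VOLUMES_ML,
    ArtifactSpec,
    Sphere,
    build_scene,
    cheese_scene,
    heterogeneous_lesion_set,
    inject_streaks,
    lesion_bed_scene,
    nema_scene,
)


class TestBuildScene:
    def test_v_series_true_volumes_span_1_to_15_6_ml(self):
        lesions = dict(heterogeneous_lesion_set())
        for i, v in enumerate(V_SERIES_VOLUMES_ML, start=1):
            les = lesions[f"V{i}"]
            assert les.envelope_volume_ml == pytest.approx(v, rel=1e-6)
        scene = rp.lesion_bed_scene(lesions["V1"], "V1")
        _, truth, _ = build_scene(scene, 1.0)
        assert truth.true_volumes_ml["V1"] == pytest.approx(1.0, rel=1e-6)
        # voxelized volume matches the analytic one within voxelization error
        vox_ml = truth.masks["V1"].sum() / 1000.0
        assert vox_ml == pytest.approx(1.0, rel=0.1)

    def test_sphere_r10_volume_on_1mm_grid(self):
        scene = lesion_bed_scene(rp.homogeneous_sphere(10.0, 5.0), "s")
        _, truth, _ = build_scene(scene, 1.0)
        assert truth.masks["s"].sum() / 1000.0 == pytest.approx(4.19, abs=0.1)

    def test_multilayer_has_three_values_with_declared_ratios(self):
        les = rp.multilayer_lesion("L4", (8.0, 4.0), c_low=10.0)
        scene = lesion_bed_scene(les, "l")
        activity, truth, _ = build_scene(scene, 1.0)
        vals = np.unique(activity.values[truth.masks["l"]])
        assert len(vals) == 3
        assert vals / vals.min() == pytest.approx([1.0, 4.0, 8.0])

    @pytest.mark.parametrize("pattern", ["L1", "L2", "L3", "L5", "L6"])
    def test_all_patterns_have_three_layers(self, pattern):
        les = rp.multilayer_lesion(pattern, (10.0, 5.0), c_low=10.0)
        scene = lesion_bed_scene(les, "l")
        activity, truth, _ = build_scene(scene, 2.0)
        assert len(np.unique(activity.values[truth.masks["l"]])) == 3

    def test_voxelized_volume_converges_with_spacing(self):
        les = rp.homogeneous_sphere(12.0, 5.0)
        true_ml = les.envelope_volume_ml
        errs = []
        for spacing in (2.0, 1.0, 0.5):
            scene = lesion_bed_scene(les, "s", margin_mm=8.0)
            _, truth, _ = build_scene(scene, spacing)
            vox = truth.masks["s"].sum() * spacing**3 / 1000.0
            errs.append(abs(vox - true_ml) / true_ml)
        assert errs[2] < errs[0]
        assert errs[2] < 0.01

    def test_pseudo_ct_values(self):
        scene = lesion_bed_scene(rp.homogeneous_sphere(10.0, 5.0), "s")
        _, truth, ct = build_scene(scene, 1.0)
        assert set(np.unique(ct.values)) == {0.0, 100.0}
        assert 50 <= ct.values[truth.masks["s"]].min() <= 150

    def test_overlapping_lesions_rejected(self):
        scene = rp.PhantomScene(
            "lesion_bed", 1.0, (60.0, 60.0, 60.0),
            [
                ("a", rp.homogeneous_sphere(10.0, 5.0, (30, 30, 30))),
                ("b", rp.homogeneous_sphere(10.0, 5.0, (35, 30, 30))),
            ],
        )
        with pytest.raises(ConfigurationError):
            build_scene(scene, 1.0)

    def test_sub_voxel_lesion_rejected(self):
        scene = rp.PhantomScene(
            "lesion_bed", 1.0, (40.0, 40.0, 40.0),
            [("tiny", rp.homogeneous_sphere(0.4, 5.0, (20, 20, 20)))],
        )
        with pytest.raises(ConfigurationError):
            build_scene(scene, 2.0)

    def test_nema_scene_has_6_hot_and_10_background_spheres(self):
        scene = nema_scene()
        _, truth, _ = build_scene(scene, 2.0)
        ids = truth.lesion_ids()
        assert sum(i.startswith("S") for i in ids) == 6
        assert sum(i.startswith("B") for i in ids) == 10
        vols = [truth.true_volumes_ml[f"S{i}"] for i in range(1, 7)]
        assert 0.4 < min(vols) < 0.6 and 25 < max(vols) < 28


class TestApplySystem:
    def test_zero_noise_is_blur_plus_box_average(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(1)
        act = rp.VolumeGrid(rng.random((16, 16, 16)) + 1, 1.0)
        pet = rp.apply_system(act, rp.SystemModel(3.0, 2.0, 0.0, 0))
        sigma = 3.0 / (2 * np.sqrt(2 * np.log(2)))
        ref = rp.block_downsample(
            act.copy(values=gaussian_filter(act.values, sigma, mode="reflect")),
            2,
        )
        np.testing.assert_allclose(pet.values, ref.values, rtol=1e-12)

    def test_undersampling_warns(self):
        act = rp.VolumeGrid(np.ones((16, 16, 16)), 1.0)
        with pytest.warns(UserWarning, match="undersampled"):
            rp.apply_system(act, rp.SystemModel(2.0, 4.0, 0.0, 0))

    def test_blur_conserves_homogeneous_mean(self):
        act = rp.VolumeGrid(np.full((24, 24, 24), 3.0), 1.0)
        pet = rp.apply_system(act, rp.SystemModel(4.8, 2.0, 0.0, 0))
        np.testing.assert_allclose(pet.values, 3.0, rtol=1e-9)

    def test_total_activity_conserved_for_interior_lesion(self):
        scene = lesion_bed_scene(rp.homogeneous_sphere(10.0, 8.0), "s")
        act, _, _ = build_scene(scene, 1.0)
        pet = rp.apply_system(act, rp.SystemModel(4.8, 2.0, 0.0, 0))
        total_in = act.values.sum() * act.voxel_volume_ml
        total_out = pet.values.sum() * pet.voxel_volume_ml
        assert total_out == pytest.approx(total_in, rel=0.005)

    def test_seeded_noise_is_bit_reproducible(self):
        act = rp.VolumeGrid(np.full((16, 16, 16), 2.0), 1.0)
        sys = rp.SystemModel(4.8, 2.0, 0.05, 42)
        a = rp.apply_system(act, sys)
        b = rp.apply_system(act, sys)
        assert np.array_equal(a.values, b.values)
        c = rp.apply_system(act, rp.SystemModel(4.8, 2.0, 0.05, 43))
        assert not np.array_equal(a.values, c.values)

    def test_pve_small_sphere_recovers_less(self):
        rcs = {}
        for name, radius in (("small", 6.2), ("large", 15.5)):
            scene = lesion_bed_scene(
                rp.homogeneous_sphere(radius, 10.0), "s")
            act, truth, _ = build_scene(scene, 1.0)
            pet = rp.apply_system(act, rp.SystemModel(4.8, 2.0, 0.0, 0))
            m = rp.block_downsample_mask(truth.masks["s"], 2)
            rcs[name] = pet.values[m].max() / 10.0
        assert rcs["small"] < rcs["large"]

    def test_spacing_coarser_than_target_rejected(self):
        act = rp.VolumeGrid(np.ones((16, 16, 16)), 2.0)
        with pytest.raises(ConfigurationError):
            rp.apply_system(act, rp.SystemModel(4.8, 1.0, 0.0, 0))


class TestNormalizeBackground:
    def test_mean_is_exactly_one_and_idempotent(self):
        rng = np.random.default_rng(2)
        g = rp.VolumeGrid(rng.random((10, 10, 10)) + 0.5, 1.0)
        mask = np.ones(g.shape, dtype=bool)
        n1 = rp.normalize_background(g, mask)
        assert n1.values[mask].mean() == pytest.approx(1.0, abs=1e-15)
        n2 = rp.normalize_background(n1, mask)
        np.testing.assert_allclose(n1.values, n2.values, rtol=1e-14)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.random((10, 10, 10)) + 0.5
        mask = np.ones(vals.shape, dtype=bool)
        a = rp.normalize_background(rp.VolumeGrid(vals, 1.0), mask)
        b = rp.normalize_background(rp.VolumeGrid(vals * 5, 1.0), mask)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-14)

    def test_lesion_contrast_preserved_without_blur(self):
        scene = lesion_bed_scene(rp.homogeneous_sphere(10.0, 10.0), "s",
                                 c_bg=1.0)
        act, truth, _ = build_scene(scene, 1.0)
        bg = truth.background_mask(margin_mm=3.0)
        normed = rp.normalize_background(act, bg)
        assert normed.values[truth.masks["s"]].min() == pytest.approx(10.0)

    def test_empty_mask_raises(self):
        g = rp.VolumeGrid(np.ones((8, 8, 8)), 1.0)
        with pytest.raises(rp.errors.NormalizationError):
            rp.normalize_background(g, np.zeros(g.shape, dtype=bool))


class TestInjectStreaks:
    def _cheese(self):
        scene = cheese_scene("pc", metal="steel")
        act, truth, ct = build_scene(scene, 2.0)
        pet = rp.apply_system(act, rp.SystemModel(4.8, 2.0, 0.0, 0))
        return scene, ct, pet

    def test_zero_amplitude_is_bit_exact_noop(self):
        scene, ct, pet = self._cheese()
        spec = ArtifactSpec(scene.artifact.metal_centers_mm, amplitude=0.0)
        ct2, pet2 = inject_streaks(ct, pet, spec)
        assert np.array_equal(pet2.values, pet.values)
        assert np.array_equal(ct2.values, ct.values)

    def test_bias_decays_with_distance_from_metal(self):
        scene, ct, pet = self._cheese()
        _, pet2 = inject_streaks(ct, pet, scene.artifact)
        center = np.array(scene.artifact.metal_centers_mm[0])
        xs, ys, zs = pet.voxel_centers()
        r = np.sqrt((xs - center[0]) ** 2 + (ys - center[1]) ** 2
                    + 0 * zs)
        ok = pet.values > 0.1
        rel = np.abs(pet2.values - pet.values) / np.where(ok, pet.values, 1)
        near = rel[ok & (r < 30)].mean()
        far = rel[ok & (r > 60)].mean()
        assert near > far

    def test_steel_bias_larger_than_aluminum(self):
        scene, ct, pet = self._cheese()
        deltas = {}
        for metal in ("aluminum", "steel"):
            spec = ArtifactSpec(
                scene.artifact.metal_centers_mm, material=metal, amplitude=0.15
            )
            _, pet2 = inject_streaks(ct, pet, spec)
            deltas[metal] = np.abs(pet2.values - pet.values).mean()
        assert deltas["steel"] > deltas["aluminum"]

    def test_ct_streaks_alternate_in_sign(self):
        scene, ct, pet = self._cheese()
        ct2, _ = inject_streaks(ct, pet, scene.artifact)
        delta = ct2.values - ct.values
        assert delta.max() > 0 and delta.min() < 0
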
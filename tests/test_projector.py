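import numpy as np
import pytest

import limbtrack as lt
from limbtrack.projector import (add_poisson_noise, build_manifest,
                                 generate_dataset, project_mask,
                                 project_volume, study_plan, training_plan)
from limbtrack.volume_ops import Volume
from limbtrack.geometry import project_point


GEOM = lt.ConeBeamGeometry(sod=200.0, sdd=300.0, det_rows=96, det_cols=96,
                           det_pitch=1.0, binning=1)


class TestProjectVolume:
    def test_empty_volume_gives_zero_image(self):
        rad = project_volume(Volume(np.zeros((16, 16, 16))), GEOM)
        assert np.all(rad.image == 0.0)

    def test_bright_voxel_projects_where_the_point_does(self):
        data = np.zeros((32, 32, 32))
        data[20, 10, 16] = 1.0
        rad = project_volume(Volume(data), GEOM)
        world = np.array([20.0, 10.0, 16.0]) - 15.5
        uv = project_point(GEOM, world)
        r, c = np.unravel_index(np.argmax(rad.image), rad.image.shape)
        # image row ~ v, column ~ u, origin at image center
        expect_c = uv[0] + (rad.image.shape[1] - 1) / 2
        expect_r = uv[1] + (rad.image.shape[0] - 1) / 2
        assert abs(r - expect_r) <= 1.0 and abs(c - expect_c) <= 1.0

    def test_central_chord_through_unit_cube(self):
        n = 21
        vol = Volume(np.ones((n, n, n)))
        rad = project_volume(vol, GEOM)
        center = rad.image[rad.image.shape[0] // 2, rad.image.shape[1] // 2]
        # the trilinearly sampled cube spans n-1 units between the first
        # and last voxel centers: the analytic central chord is n-1
        assert center == pytest.approx(n - 1, rel=0.02)

    def test_linearity_and_monotonicity(self):
        rng = np.random.default_rng(0)
        a = rng.random((16, 16, 16))
        b = rng.random((16, 16, 16))
        ia = project_volume(Volume(a), GEOM).image
        ib = project_volume(Volume(b), GEOM).image
        iab = project_volume(Volume(a + b), GEOM).image
        assert np.abs(iab - (ia + ib)).max() < 1e-8
        assert np.all(iab >= ia - 1e-12)


class TestProjectMask:
    def test_bone_outside_field_of_view(self):
        labels = np.zeros((16, 16, 16), np.int32)
        labels[2:5, 2:5, 2:5] = 1
        pose = lt.PoseParameters(x_o=5000.0)   # far outside the cone
        mask = project_mask(labels, 1, GEOM, pose)
        assert not mask.any()

    def test_union_of_bones_is_union_of_masks(self, phantom_bundle):
        _, labels, _ = phantom_bundle
        geom = lt.ConeBeamGeometry(sod=655.0, sdd=1000.0, det_rows=160,
                                   det_cols=160, det_pitch=1.0, binning=1)
        m1 = project_mask(labels, 1, geom)
        m2 = project_mask(labels, 2, geom)
        both = project_mask((labels > 0).astype(np.int32), 1, geom)
        assert np.array_equal(both, m1 | m2)

    def test_landmarks_project_onto_their_bone_mask(self, phantom_bundle,
                                                    landmark_sets):
        _, labels, _ = phantom_bundle
        geom = lt.ConeBeamGeometry(sod=655.0, sdd=1000.0, det_rows=160,
                                   det_cols=160, det_pitch=1.0, binning=1)
        for ls in landmark_sets:
            mask = project_mask(labels, ls.bone, geom)
            uv = project_point(geom, ls.coordinates)
            rc = np.stack([uv[:, 1] + (mask.shape[0] - 1) / 2,
                           uv[:, 0] + (mask.shape[1] - 1) / 2], axis=1)
            rci = np.rint(rc).astype(int)
            from scipy import ndimage
            grown = ndimage.binary_dilation(mask)  # 1-pixel tolerance
            assert grown[rci[:, 0], rci[:, 1]].all()


class TestPoissonNoise:
    def test_scaling_contract_max_is_I0(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32)) * 7.3
        scaled = np.clip(img * (2000.0 / img.max()), 0, None)
        assert scaled.max() == pytest.approx(2000.0)

    def test_same_seed_identical(self):
        img = np.random.default_rng(2).random((16, 16)) + 0.1
        a = add_poisson_noise(img, 500.0, seed=42)
        b = add_poisson_noise(img, 500.0, seed=42)
        assert np.array_equal(a, b)

    def test_mean_matches_scaled_intensity(self):
        img = np.full((1, 1), 1.0)
        draws = [add_poisson_noise(img * 100, 100.0, seed=s)[0, 0]
                 for s in range(10_000)]
        assert 99.0 <= np.mean(draws) <= 101.0

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            add_poisson_noise(np.zeros((4, 4)), 100.0)

    def test_nonpositive_I0_rejected(self):
        with pytest.raises(ValueError):
            add_poisson_noise(np.ones((4, 4)), 0.0)


class TestAcquisitionPlans:
    def test_training_plan_enumeration(self):
        plan = training_plan()
        assert plan.n_volumes == 30
        manifest = build_manifest(plan)
        assert len(manifest) == 15_600

    def test_study_plan_articulated_volumes(self):
        assert study_plan().n_volumes == 9

    def test_minimal_plan_single_entry(self):
        plan = lt.AcquisitionPlan(articulation_grids=[[0.0]], angle_centers=[0.0],
                                  angle_half_width=1.0, projections_per_interval=1)
        assert len(build_manifest(plan)) == 1

    def test_split_fractions_respected(self):
        plan = training_plan()
        manifest = build_manifest(plan)
        counts = {s: 0 for s in ("train", "val", "test")}
        for e in manifest:
            counts[e["split"]] += 1
        n = len(manifest)
        assert counts["train"] == pytest.approx(0.75 * n, abs=1)
        assert counts["val"] == pytest.approx(0.20 * n, abs=1)
        assert counts["test"] == pytest.approx(0.05 * n, abs=1)

    def test_manifest_deterministic(self):
        a = build_manifest(study_plan(seed=9))
        b = build_manifest(study_plan(seed=9))
        assert a == b

    def test_jitter_within_ranges(self):
        plan = training_plan(seed=1)
        for e in build_manifest(plan)[::999]:
            assert abs(e["x"]) <= 180 and abs(e["y"]) <= 120 and abs(e["z"]) <= 180
            assert abs(e["theta"]) <= 15 and abs(e["eta"]) <= 15
            assert 6550 - 180 <= e["sod"] <= 6550 + 180
            assert 2000 - 350 <= e["I0"] <= 2000 + 350


class TestGenerateDataset:
    @pytest.fixture(scope="class")
    def small_samples(self, phantom_bundle, seg_bundle, fusion_cfg, fusion_maps,
                      landmark_sets):
        vol, _, _ = phantom_bundle
        seg, frames = seg_bundle
        plan = lt.AcquisitionPlan(
            articulation_grids=[[10.0], [-6.0]], angle_centers=[0.0],
            angle_half_width=1.5, projections_per_interval=2,
            sod=(655.0, 10.0), sdd=(1000.0, 20.0),
            xyz_range=(8.0, 6.0, 8.0), tilt_range=5.0, seed=0)
        builder = lambda etas: lt.build_articulation_model(
            seg, frames, list(etas), fusion_cfg, weights=fusion_maps)
        manifest = build_manifest(plan)
        return generate_dataset(manifest, vol, seg, landmark_sets, builder,
                                det_shape=(96, 96))

    def test_ground_truth_landmarks_are_projections(
            self, small_samples, seg_bundle, fusion_cfg, fusion_maps, landmark_sets):
        from limbtrack.geometry import apply_rigid
        from limbtrack.polyaffine import transform_points
        seg, frames = seg_bundle
        s = small_samples[0]
        model = lt.build_articulation_model(
            seg, frames, list(s.pose.eta_joints), fusion_cfg, weights=fusion_maps)
        for ls in landmark_sets:
            moved = transform_points(ls.coordinates, model, freeze_weights=True)
            posed = apply_rigid(s.pose, moved, eta_o=s.eta_o)
            uv = project_point(s.radiograph.geometry, posed)
            assert np.abs(uv - s.landmarks_2d[(ls.bone, ls.kind)]).max() < 1e-6

    def test_landmarks_in_view_flags(self, small_samples):
        s = small_samples[0]
        rows, cols = s.radiograph.geometry.image_shape
        for key, uv in s.landmarks_2d.items():
            inside = (np.abs(uv[:, 0]) <= (cols - 1) / 2) & \
                     (np.abs(uv[:, 1]) <= (rows - 1) / 2)
            assert np.array_equal(inside, s.landmarks_in_view[key])

    def test_radiographs_nonnegative_and_finite(self, small_samples):
        for s in small_samples:
            assert np.all(np.isfinite(s.radiograph.image))
            assert np.all(s.radiograph.image >= 0)


class TestDatasetIO:
    def test_write_dataset_round_trip(self, tmp_path, phantom_bundle, seg_bundle,
                                      fusion_cfg, fusion_maps, landmark_sets):
        import json
        import tifffile
        vol, _, _ = phantom_bundle
        seg, frames = seg_bundle
        plan = lt.AcquisitionPlan(
            articulation_grids=[[8.0], [-4.0]], angle_centers=[0.0],
            angle_half_width=1.0, projections_per_interval=1,
            sod=(655.0, 5.0), sdd=(1000.0, 10.0),
            xyz_range=(5.0, 4.0, 5.0), tilt_range=3.0, seed=1)
        builder = lambda etas: lt.build_articulation_model(
            seg, frames, list(etas), fusion_cfg, weights=fusion_maps)
        samples = generate_dataset(build_manifest(plan), vol, seg,
                                   landmark_sets, builder, det_shape=(96, 96))
        from limbtrack.projector import write_dataset
        manifest = write_dataset(samples, tmp_path)
        lines = manifest.read_text().splitlines()
        assert len(lines) == 1
        rec = json.loads(lines[0])
        img = tifffile.imread(tmp_path / rec["radiograph"]).astype(float)
        back = img / rec["intensity_scale"]
        assert np.abs(back - samples[0].radiograph.image).max() < 1.0
        assert rec["pose"]["eta_joints"] == [8.0, -4.0]
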
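import numpy as np
import pytest
from scipy.linalg import expm

import limbtrack as lt
from limbtrack.polyaffine import (BoneRotation, FusionConfig, PolyaffineModel,
                                  fusion_step, fusion_weights, log_rotation,
                                  rodrigues, rotation_angle, transform_points,
                                  warp_volume)
from limbtrack.volume_ops import Volume, index_to_world


def random_rotation(rng, alpha=None):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    if alpha is None:
        alpha = rng.uniform(0.01, 3.0)
    return rodrigues(axis, alpha), alpha


class TestRotationAngle:
    def test_identity_is_zero(self):
        assert rotation_angle(np.eye(3)) == 0.0

    def test_z_rotation_30_degrees(self):
        R = rodrigues([0, 0, 1], np.deg2rad(30))
        assert np.degrees(rotation_angle(R)) == pytest.approx(30.0, abs=1e-10)

    def test_rodrigues_construction_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            R, _ = random_rotation(rng, alpha=np.deg2rad(77.0))
            assert rotation_angle(R) == pytest.approx(np.deg2rad(77.0), abs=1e-10)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            rotation_angle(np.eye(3) * 1.1)


class TestLogRotation:
    def test_identity_gives_zero_matrix(self):
        assert np.array_equal(log_rotation(np.eye(3)), np.zeros((3, 3)))

    def test_exp_log_round_trip_100_rotations(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(100):
            R, _ = random_rotation(rng)
            worst = max(worst, np.abs(expm(log_rotation(R)) - R).max())
        assert worst <= 1e-10

    def test_antisymmetric_by_construction(self):
        rng = np.random.default_rng(2)
        R, _ = random_rotation(rng)
        L = log_rotation(R)
        assert np.array_equal(L.T, -L)

    def test_angle_near_pi_rejected(self):
        R = rodrigues([1, 0, 0], np.pi - 1e-9)
        with pytest.raises(ValueError):
            log_rotation(R)


class TestFusionWeights:
    def test_single_bone_weight_is_one_on_support(self):
        labels = np.zeros((24, 24, 24), np.int32)
        labels[8:16, 8:16, 8:16] = 1
        w, support = fusion_weights(labels, [1], FusionConfig(S=4, sigma_f=2.0, k_f=7))
        assert np.allclose(w[0][support], 1.0)
        assert np.all(w[0][~support] == 0.0)

    def test_mirror_symmetric_segments_split_evenly(self):
        labels = np.zeros((31, 24, 24), np.int32)
        labels[5:10, 8:16, 8:16] = 1      # mirror image of 21:26 about x=15
        labels[21:26, 8:16, 8:16] = 2
        w, support = fusion_weights(labels, [1, 2],
                                    FusionConfig(S=4, sigma_f=4.0, k_f=17))
        mid = w[:, 15, 8:16, 8:16]        # the mirror plane itself
        assert support[15, 8:16, 8:16].all()
        assert np.abs(mid - 0.5).max() < 1e-6

    def test_normalization_sums_to_one_on_support(self, seg_bundle, fusion_maps):
        w, support = fusion_maps
        total = w.sum(axis=0)
        assert np.abs(total[support] - 1.0).max() < 1e-10
        assert np.all(total[~support] == 0.0)


def single_bone_model(origin, axis, eta_deg, shape=(32, 32, 32), S=18):
    cfg = FusionConfig(S=S, sigma_f=3.0, k_f=9)
    w = np.ones((1,) + shape)
    support = np.ones(shape, bool)
    return PolyaffineModel([BoneRotation(1, eta_deg, np.asarray(origin, float),
                                         np.asarray(axis, float))], w, support, cfg)


class TestFusionStep:
    def test_zero_angles_are_identity(self, zero_model):
        pts = np.array([[1.0, 2.0, 3.0], [-4.0, 0.0, 8.0]])
        assert np.allclose(fusion_step(pts, zero_model), pts)

    def test_single_bone_full_weight_is_substep_exponential(self):
        model = single_bone_model([2.0, -1.0, 0.0], [0, 0, 1], 36.0)
        pts = np.array([[5.0, 5.0, 1.0]])
        out = fusion_step(pts, model)
        R_sub, t_sub = model.rotations[0].substep_affine(model.config.S)
        assert np.abs(out - (pts @ R_sub.T + t_sub)).max() < 1e-12

    def test_two_bone_blend_matches_direct_evaluation(self):
        shape = (24, 24, 24)
        cfg = FusionConfig(S=10, sigma_f=2.0, k_f=7)
        r1 = BoneRotation(1, 20.0, np.zeros(3), np.array([0.0, 0.0, 1.0]))
        r2 = BoneRotation(2, -15.0, np.array([3.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        w_val = 0.37
        w = np.stack([np.full(shape, w_val), np.full(shape, 1.0 - w_val)])
        model = PolyaffineModel([r1, r2], w, np.ones(shape, bool), cfg)
        pts = np.array([[2.0, 3.0, -1.0]])
        out = fusion_step(pts, model)
        E1 = r1.substep_affine(10)
        E2 = r2.substep_affine(10)
        direct = pts + w_val * ((pts @ E1[0].T + E1[1]) - pts) \
            + (1 - w_val) * ((pts @ E2[0].T + E2[1]) - pts)
        assert np.abs(out - direct).max() < 1e-12


class TestTransformPoints:
    def test_full_composition_equals_exact_rigid_rotation(self):
        origin = np.array([1.0, 2.0, -3.0])
        axis = np.array([0.3, 0.9, 0.1]) / np.linalg.norm([0.3, 0.9, 0.1])
        model = single_bone_model(origin, axis, 47.0, S=18)
        rng = np.random.default_rng(3)
        pts = rng.uniform(-10, 10, (20, 3))
        out = transform_points(pts, model, k=18)
        R = rodrigues(axis, np.deg2rad(47.0))
        exact = (pts - origin) @ R.T + origin
        assert np.abs(out - exact).max() <= 1e-9

    def test_zero_angles_identity_any_k(self, zero_model):
        pts = np.array([[3.0, -7.0, 2.0]])
        for k in (1, 5, 18):
            assert np.allclose(transform_points(pts, zero_model, k=k), pts)

    def test_forward_inverse_round_trip_on_bone_points(
            self, seg_bundle, fusion_cfg, fusion_maps):
        seg, frames = seg_bundle
        model = lt.build_articulation_model(seg, frames, [12.0, -8.0],
                                            fusion_cfg, weights=fusion_maps)
        pts = index_to_world(np.argwhere(seg > 0)[::7].astype(float), seg.shape)
        fwd = transform_points(pts, model)
        back = transform_points(fwd, model.inverse())
        assert np.abs(back - pts).max() < 0.1

    def test_step_size_consistency_second_order(
            self, seg_bundle, fusion_cfg, fusion_maps, landmark_sets):
        seg, frames = seg_bundle
        model = lt.build_articulation_model(seg, frames, [15.0, -10.0],
                                            fusion_cfg, weights=fusion_maps)
        cfg2 = FusionConfig(S=2 * fusion_cfg.S, sigma_f=fusion_cfg.sigma_f,
                            k_f=fusion_cfg.k_f)
        model2 = PolyaffineModel(model.rotations, model.weights, model.support, cfg2)
        pts = np.vstack([ls.coordinates for ls in landmark_sets])
        a = transform_points(pts, model)
        b = transform_points(pts, model2)
        assert np.abs(a - b).max() < 0.05

    def test_k_out_of_range_rejected(self, zero_model):
        with pytest.raises(ValueError):
            transform_points(np.zeros((1, 3)), zero_model, k=0)


class TestWarpVolume:
    def test_identity_model_preserves_volume(self):
        rng = np.random.default_rng(4)
        shape = (20, 20, 20)
        labels = np.zeros(shape, np.int32)
        labels[6:14, 6:14, 6:14] = 1
        vol = Volume(rng.random(shape))
        cfg = FusionConfig(S=4, sigma_f=2.0, k_f=7)
        model = lt.build_articulation_model(labels, _frame_at_center(labels), [0.0], cfg)
        out = warp_volume(vol, model)
        assert np.abs(out.data - vol.data).max() < 1e-9

    def test_rotated_ball_matches_analytic_rotation(self):
        shape = (48, 48, 48)
        idx = np.indices(shape).astype(float)
        c = (np.array(shape)[:, None, None, None] - 1) / 2
        x, y, z = idx - c
        center = np.array([6.0, 0.0, 0.0])
        dist = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2
                       + (z - center[2]) ** 2)
        # anti-aliased ball: a one-voxel linear ramp at the surface keeps
        # the 0.5 level set on the true sphere (a hard binary ball would
        # measure voxelization noise, not warp accuracy)
        vol = Volume(np.clip(10.0 + 0.5 - dist, 0.0, 1.0))
        origin = np.zeros(3)
        model = single_bone_model(origin, [0, 0, 1], 20.0, shape=shape, S=18)
        out = warp_volume(vol, model)
        R = rodrigues([0, 0, 1], np.deg2rad(20.0))
        rc = R @ center
        rotated = ((x - rc[0]) ** 2 + (y - rc[1]) ** 2 + (z - rc[2]) ** 2 <= 10.0 ** 2)
        got = out.data > 0.5
        iou = (got & rotated).sum() / (got | rotated).sum()
        assert iou >= 0.99

    def test_two_bone_phantom_warp_is_finite_and_conserves_mass(
            self, phantom_bundle, seg_bundle, fusion_cfg, fusion_maps):
        vol, _, _ = phantom_bundle
        seg, frames = seg_bundle
        model = lt.build_articulation_model(seg, frames, [10.0, -6.0],
                                            fusion_cfg, weights=fusion_maps)
        out = warp_volume(vol, model)
        assert np.all(np.isfinite(out.data))
        assert abs(out.data.sum() - vol.data.sum()) / vol.data.sum() < 0.05

    def test_smooth_joint_transition(self, seg_bundle, fusion_cfg, fusion_maps):
        # displacement jumps between adjacent voxels across the joint
        # region stay below the inter-voxel bound 2 sin(da/2) r_max
        seg, frames = seg_bundle
        eta = 14.0
        model = lt.build_articulation_model(seg, frames, [eta, -eta],
                                            fusion_cfg, weights=fusion_maps)
        ii = np.arange(-14, 15)
        grid = np.stack(np.meshgrid(ii, ii, ii, indexing="ij"), axis=-1).reshape(-1, 3).astype(float)
        disp = (transform_points(grid, model) - grid).reshape(29, 29, 29, 3)
        jumps = []
        for ax in range(3):
            d = np.diff(disp, axis=ax)
            jumps.append(np.linalg.norm(d, axis=-1).max())
        r_max = max(np.linalg.norm(grid - r.origin, axis=1).max()
                    for r in model.rotations)
        # relative articulation between the bones is 2*eta
        bound = 2 * np.sin(np.deg2rad(2 * eta) / 2) * r_max
        assert max(jumps) < bound


def _frame_at_center(labels):
    from limbtrack.volume_ops import BoneFrame
    return [BoneFrame(origin=np.zeros(3), axes=np.eye(3),
                      eigenvalues=np.array([3.0, 2.0, 1.0]),
                      com=np.zeros(3), label=1)]
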
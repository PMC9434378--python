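"""Reproducible phantom studies: the numerical experiments behind the
package's headline checks.

Each study builds its own inputs from the phantom generator, runs the
method, and measures the result; everything is driven by one integer
seed.  They are used by the test suite, the acceptance script and the
examples, so the numbers those surfaces print all come from the same
code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import limbtrack as lt
from .detection import VotingConfig, encode_vector_field, vote_landmark
from .detection.bonenet import BoneNetConfig
from .detection.train import TrainConfig, train_bonenet
from .landmarks3d import select_landmarks, SelectionConfig
from .polyaffine import (BoneRotation, FusionConfig, PolyaffineModel,
                         log_rotation, rodrigues, transform_points)
from .registration import ArticulatedForwardModel, ObservationSet, register
from .volume_ops import BoneFrame

__all__ = [
    "PhantomAssets",
    "build_phantom_assets",
    "plan_counts",
    "projection_offset_example",
    "exact_rotation_limit_study",
    "log_exp_roundtrip_study",
    "selection_oracle_study",
    "voting_study",
    "pose_recovery_study",
    "training_smoke_study",
    "overfit_study",
]


@dataclass
class PhantomAssets:
    volume: "lt.Volume"
    labels: np.ndarray
    frames: list
    landmark_sets: list
    fusion_cfg: FusionConfig
    model: PolyaffineModel


def build_phantom_assets(K: int = 20, lam: float = 1.5,
                         seed: int = 0) -> PhantomAssets:
    """Phantom -> segmentation -> frames -> reference landmarks."""
    vol, _, _ = lt.make_limb_phantom(lt.PhantomConfig(seed=seed))
    seg = lt.segment_bones(vol)
    frames = [lt.bone_frame(seg, b, end_hint=+1) for b in (1, 2)]
    # kernel support sized so the weight field covers the articulation
    # displacements at phantom scale
    fusion_cfg = FusionConfig(S=18, sigma_f=5.0, k_f=29)
    model = lt.build_articulation_model(seg, frames, [0.0, 0.0], fusion_cfg)
    sel = SelectionConfig(K=K, lam=lam)
    sets = [select_landmarks(lt.candidate_bone_voxels(seg, b), f, sel,
                             kind="bounding")
            for b, f in zip((1, 2), frames)]
    return PhantomAssets(vol, seg, frames, sets, fusion_cfg, model)


def plan_counts() -> dict:
    """Enumeration of the two acquisition campaigns."""
    training = lt.training_plan()
    study = lt.study_plan()
    return {
        "training_radiographs": len(lt.build_manifest(training)),
        "training_articulated_volumes": training.n_volumes,
        "study_articulated_volumes": study.n_volumes,
    }


def projection_offset_example() -> dict:
    """In-plane 20-voxel offset at magnification 1.5 and binning 6."""
    geom = lt.ConeBeamGeometry(sod=100.0, sdd=150.0, det_pitch=1.0, binning=6)
    uv0 = lt.project_point(geom, np.zeros(3))
    uv1 = lt.project_point(geom, np.array([20.0, 0.0, 0.0]))
    binned = float(np.linalg.norm(uv1 - uv0))
    return {
        "detector_offset_voxels": binned * geom.det_pitch * geom.binning,
        "binned_pixel_offset": binned,
    }


def exact_rotation_limit_study(seed: int = 0, S: int = 18) -> float:
    """Single bone, uniform weights: S-fold composition vs exact rigid
    rotation; returns the max position error (voxels)."""
    rng = np.random.default_rng(seed)
    # grid large enough that every point's circular orbit stays inside
    # the uniform weight field throughout the composition
    shape = (48, 48, 48)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    origin = rng.uniform(-3, 3, 3)
    eta = rng.uniform(10.0, 60.0)
    model = PolyaffineModel(
        [BoneRotation(1, eta, origin, axis)],
        np.ones((1,) + shape), np.ones(shape, bool),
        FusionConfig(S=S, sigma_f=3.0, k_f=9))
    pts = rng.uniform(-8, 8, (50, 3))
    out = transform_points(pts, model, k=S)
    R = rodrigues(axis, np.deg2rad(eta))
    exact = (pts - origin) @ R.T + origin
    return float(np.abs(out - exact).max())


def log_exp_roundtrip_study(seed: int = 0, n: int = 100) -> float:
    """max ||expm(log R) - R|| over n random rotations."""
    from scipy.linalg import expm
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = rodrigues(axis, rng.uniform(0.01, 3.0))
        worst = max(worst, float(np.abs(expm(log_rotation(R)) - R).max()))
    return worst


def selection_oracle_study(seed: int = 0, n_points: int = 200, K: int = 6,
                           lam: float = 1.0) -> dict:
    """Greedy selection vs a full-rescan brute-force oracle."""
    rng = np.random.default_rng(seed)
    cands = rng.uniform(-25, 25, (n_points, 3))
    sigma_min = 16.0
    frame = BoneFrame(origin=np.zeros(3), axes=np.eye(3),
                      eigenvalues=np.array([100.0, 30.0, sigma_min]),
                      com=rng.uniform(-2, 2, 3), label=1)
    out = select_landmarks(cands, frame, SelectionConfig(K=K, lam=lam))

    floor = lam * np.sqrt(sigma_min)
    selected: list[np.ndarray] = []
    pool = list(map(tuple, cands))
    while len(selected) < K:
        best, best_d = None, -1.0
        for c in pool:
            if any(np.allclose(c, s) for s in selected):
                continue
            if any(np.linalg.norm(np.subtract(c, s)) < floor for s in selected):
                continue
            d = np.linalg.norm(np.subtract(c, frame.com))
            if d > best_d:
                best, best_d = c, d
        if best is None:
            break
        selected.append(np.asarray(best))
    oracle = np.asarray(selected)

    match = (out.coordinates.shape == oracle.shape
             and np.allclose(out.coordinates, oracle))
    d = np.linalg.norm(out.coordinates[:, None] - out.coordinates[None], axis=2)
    np.fill_diagonal(d, np.inf)
    return {
        "oracle_match": float(match),
        "min_pairwise_distance": float(d.min()),
        "distance_floor": float(floor),
    }


def voting_study(seed: int = 0, n_cases: int = 20,
                 corrupt_frac: float = 0.0) -> dict:
    """Encode -> (corrupt) -> vote over random mask/landmark pairs."""
    rng = np.random.default_rng(seed)
    errs = []
    for t in range(n_cases):
        mask = np.zeros((64, 64), bool)
        r0, c0 = rng.integers(12, 52, 2)
        h, w = rng.integers(8, 14, 2)
        mask[r0 - h // 2:r0 + h // 2, c0 - w // 2:c0 + w // 2] = True
        lm = np.array([r0, c0]) + rng.uniform(-3, 3, 2)
        f = encode_vector_field(mask, lm).field
        if corrupt_frac > 0:
            rr, cc = np.nonzero(mask)
            idx = rng.choice(len(rr), int(corrupt_frac * len(rr)), replace=False)
            ang = rng.uniform(0, 2 * np.pi, len(idx))
            f = f.copy()
            f[0, rr[idx], cc[idx]] = np.cos(ang)
            f[1, rr[idx], cc[idx]] = np.sin(ang)
        obs = vote_landmark(f, mask, VotingConfig(seed=int(seed * 1000 + t)))
        errs.append(np.linalg.norm(obs.mu_hat - lm))
    return {"max_error_px": float(np.max(errs)),
            "median_error_px": float(np.median(errs))}


def _study_geometry(rng, sod=(6550.0, 180.0), sdd=(10000.0, 540.0)):
    # unbinned detector: the phantom subtends a pixel extent comparable
    # to the full-scale study images
    return lt.ConeBeamGeometry(
        sod=sod[0] + rng.uniform(-sod[1], sod[1]),
        sdd=sdd[0] + rng.uniform(-sdd[1], sdd[1]),
        det_rows=512, det_cols=512, det_pitch=1.0, binning=1)


def pose_recovery_study(n_trials: int = 50, seed: int = 0,
                        noise_px: float = 0.0,
                        assets: PhantomAssets | None = None) -> dict:
    """Random poses in the simulation ranges, oracle landmark
    observations (optionally noisy), zero-initialized registration.

    Returns success statistics (translations within 1 voxel and
    rotations within 0.1 degrees) and per-parameter error summaries.
    """
    a = assets or build_phantom_assets()
    rng = np.random.default_rng(seed)
    n_lm = sum(len(s.coordinates) for s in a.landmark_sets)
    succ = 0
    terrs, rerrs, jerrs = [], [], []
    for _ in range(n_trials):
        geom = _study_geometry(rng)
        fwd = ArticulatedForwardModel(a.landmark_sets, a.frames, geom, a.model)
        phi = rng.choice([0.0, 180.0]) + rng.uniform(-30, 30)
        truth = lt.PoseParameters(
            rng.uniform(-180, 180), rng.uniform(-120, 120),
            rng.uniform(-180, 180), rng.uniform(-15, 15), phi,
            [rng.uniform(-30, 35), rng.uniform(-20, 35)])
        eta_o = rng.uniform(-15, 15)
        uv = fwd.project(truth, eta_o=eta_o)
        if noise_px > 0:
            uv = uv + rng.normal(0.0, noise_px, uv.shape)
        obs = ObservationSet(uv, np.ones(n_lm), eta_o=eta_o)
        est = register(obs, a.landmark_sets, a.frames, a.model, geom)
        d = np.abs(est.pose.to_vector() - truth.to_vector())
        terrs.append(d[:3].max())
        rerrs.append(d[3:].max())
        jerrs.extend(d[5:])
        succ += (d[:3].max() < 1.0) and (d[3:].max() < 0.1)
    return {
        "n_trials": n_trials,
        "success_rate_pct": 100.0 * succ / n_trials,
        "median_translation_error_voxels": float(np.median(terrs)),
        "median_rotation_error_deg": float(np.median(rerrs)),
        "median_joint_angle_error_deg": float(np.median(jerrs)),
        "q3_joint_angle_error_deg": float(np.percentile(jerrs, 75)),
    }


def _toy_detection_data(n, rng, size=64, K=3):
    xs, fs, ms = [], [], []
    for _ in range(n):
        mask = np.zeros((size, size), bool)
        r0, c0 = rng.integers(14, size - 14, 2)
        mask[r0 - 8:r0 + 8, c0 - 6:c0 + 6] = True
        img = mask.astype(float) * 0.8 + rng.normal(0, 0.05, (size, size))
        lms = np.stack([rng.uniform(r0 - 8, r0 + 8, K),
                        rng.uniform(c0 - 6, c0 + 6, K)], 1)
        fs.append(np.concatenate(
            [encode_vector_field(mask, lm).field for lm in lms], 0))
        xs.append(img[None])
        ms.append(mask.astype(float))
    return np.stack(xs), np.stack(fs), np.stack(ms)


def training_smoke_study(seed: int = 0, n_samples: int = 20,
                         epochs: int = 30) -> dict:
    """Train the network on a toy set with the standard schedule."""
    rng = np.random.default_rng(seed)
    xs, fs, ms = _toy_detection_data(n_samples, rng)
    _, hist = train_bonenet(
        xs, fs, ms,
        net_config=BoneNetConfig(input_size=64, K=fs.shape[1] // 2, seed=seed),
        train_config=TrainConfig(max_epochs=epochs, seed=seed))
    return {
        "initial_train_loss": hist["train"][0],
        "final_train_loss": hist["train"][-1],
        "loss_ratio": hist["train"][-1] / hist["train"][0],
    }


def overfit_study(seed: int = 0, epochs: int = 200) -> dict:
    """Single-sample capacity check: the vector-field loss of a net fit
    to one sample should collapse (here with a task-scale learning
    rate; the production schedule is far gentler)."""
    rng = np.random.default_rng(seed)
    xs, fs, ms = _toy_detection_data(1, rng)
    _, hist = train_bonenet(
        xs, fs, ms,
        net_config=BoneNetConfig(input_size=64, K=fs.shape[1] // 2, seed=seed),
        train_config=TrainConfig(base_lr=3e-3, decay_epochs=0,
                                 max_epochs=epochs, batch_size=1, seed=seed,
                                 val_fraction=0.0))
    return {
        "initial_field_loss": hist["field"][0],
        "final_field_loss": hist["field"][-1],
        "field_loss_ratio": hist["field"][-1] / hist["field"][0],
    }
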
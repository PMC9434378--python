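"""Polyaffine articulated-motion simulation.

Each bone moves rigidly — a pitch rotation about its own transverse axis
through its joint origin — and the per-bone motions are fused into one
smooth global deformation with the log-Euclidean polyaffine scheme: the
matrix logarithm of each rotation is the bone's motion *speed*; spatial
Gaussian weight maps blend the speeds; and the total motion is the
composition of ``S`` small sub-steps, each advancing every point by
1/``S`` of the blended speed.  This produces rigid motion deep inside
each bone and a smooth transition across the joint, which is what makes
the simulated articulations anatomically plausible training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_ops import BoneFrame, Volume, tricubic_interpolate, index_to_world, world_to_index

__all__ = [
    "FusionConfig",
    "BoneRotation",
    "PolyaffineModel",
    "rotation_angle",
    "log_rotation",
    "rodrigues",
    "fusion_weights",
    "fusion_step",
    "transform_points",
    "warp_volume",
    "warp_labels",
    "build_articulation_model",
]

_EPS_SUPPORT = 1e-8


@dataclass
class FusionConfig:
    """Fusion time scale and Gaussian weight-kernel parameters.

    ``S`` sub-steps per unit time; ``sigma_f`` the Gaussian standard
    deviation (voxels) and ``k_f`` the (odd) kernel support width used
    to diffuse each bone's binary segment into its weight map.
    """

    S: int = 18
    sigma_f: float = 13.0
    k_f: int = 23

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")
        if self.k_f < 3 or self.k_f % 2 == 0:
            raise ValueError("k_f must be odd and >= 3")


def rodrigues(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues form)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6:
        raise ValueError("input is not an orthonormal rotation matrix")
    return R


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle ``alpha = arccos((tr R - 1) / 2)`` in [0, pi]."""
    R = _check_rotation(R)
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def log_rotation(R: np.ndarray) -> np.ndarray:
    """Principal matrix log of a rotation: antisymmetric speed matrix.

    ``log(R) = alpha / (2 sin alpha) * (R - R^T)`` for alpha in (0, pi);
    the zero matrix at alpha = 0.  Angles at (or numerically near) pi
    fall outside the principal branch and raise.
    """
    R = _check_rotation(R)
    alpha = rotation_angle(R)
    if alpha < 1e-12:
        return np.zeros((3, 3))
    if alpha > np.pi - 1e-6:
        raise ValueError("rotation angle at pi: matrix log branch undefined")
    return alpha / (2.0 * np.sin(alpha)) * (R - R.T)


@dataclass
class BoneRotation:
    """One bone's rigid rotation: pitch about its transverse axis."""

    bone: int
    eta_deg: float
    origin: np.ndarray          # rotation center (joint origin), world coords
    axis: np.ndarray            # unit rotation axis (bone transverse axis)

    @property
    def matrix(self) -> np.ndarray:
        return rodrigues(self.axis, np.deg2rad(self.eta_deg))

    @property
    def alpha(self) -> float:
        return abs(np.deg2rad(self.eta_deg))

    def substep_affine(self, S: int, sign: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Exact affine exponential ``e^{A/S}`` as (R_sub, t_sub).

        The speed ``A`` is the homogeneous affine log (rotation log plus
        the translation induced by centering at the joint origin), so
        its exponential is exactly the rotation by ``eta/S`` about the
        origin: ``x -> R_sub (x - O) + O``.
        """
        R_sub = rodrigues(self.axis, sign * np.deg2rad(self.eta_deg) / S)
        t_sub = self.origin - R_sub @ self.origin
        return R_sub, t_sub


def fusion_weights(
    labels: np.ndarray,
    bones: list[int],
    config: FusionConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-diffused, voxelwise-normalized per-bone weight maps.

    Each bone's binary segment is convolved with a truncated Gaussian
    kernel (sd ``sigma_f``, support ``k_f`` per axis); where the summed
    raw weight exceeds a small epsilon the maps are normalized to sum
    to 1, elsewhere the motion model is the identity.

    Returns
    -------
    weights : (M, nx, ny, nz) normalized maps (0 where unsupported)
    support : bool (nx, ny, nz), True where the fusion applies
    """
    if not bones:
        raise ValueError("bones list must be nonempty")
    labels = np.asarray(labels)
    half = config.k_f // 2
    x = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-0.5 * (x / config.sigma_f) ** 2)
    g1 /= g1.sum()

    raw = np.empty((len(bones),) + labels.shape)
    for i, b in enumerate(bones):
        m = (labels == b).astype(float)
        for ax in range(3):
            m = ndimage.correlate1d(m, g1, axis=ax, mode="constant")
        raw[i] = m
    total = raw.sum(axis=0)
    support = total > _EPS_SUPPORT
    weights = np.zeros_like(raw)
    np.divide(raw, total[None], out=weights, where=support[None])
    return weights, support


@dataclass
class PolyaffineModel:
    """Fused articulation model over M bones."""

    rotations: list[BoneRotation]
    weights: np.ndarray            # (M, nx, ny, nz) normalized
    support: np.ndarray            # bool grid
    config: FusionConfig
    shape: tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.shape = tuple(self.weights.shape[1:])

    def inverse(self) -> "PolyaffineModel":
        """Inverse motion: negate every rotation angle (approximate
        where weights blend; exact deep inside each bone)."""
        inv = [BoneRotation(r.bone, -r.eta_deg, r.origin.copy(), r.axis.copy())
               for r in self.rotations]
        return PolyaffineModel(inv, self.weights, self.support, self.config)

    def weights_at(self, points: np.ndarray) -> np.ndarray:
        """Tricubic lookup of each bone's weight map at world points."""
        return np.stack(
            [tricubic_interpolate(self.weights[i], points, world=True)
             for i in range(len(self.rotations))]
        )

    def save(self, path: str | Path) -> None:
        d = {
            "bones": [
                {"label": r.bone, "eta_deg": r.eta_deg,
                 "origin": list(r.origin), "axis": list(r.axis)}
                for r in self.rotations
            ],
            "S": self.config.S, "sigma_f": self.config.sigma_f, "k_f": self.config.k_f,
        }
        Path(path).write_text(json.dumps(d, indent=2))


def build_articulation_model(
    labels: np.ndarray,
    frames: list[BoneFrame],
    eta_deg: list[float],
    config: FusionConfig | None = None,
    weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> PolyaffineModel:
    """Model with per-bone pitches about each frame's transverse axis.

    ``weights`` may pass a precomputed ``fusion_weights`` result to
    avoid recomputing the Gaussian maps when only angles change.
    """
    cfg = config or FusionConfig()
    if len(frames) != len(eta_deg):
        raise ValueError("one pitch angle per bone frame required")
    rots = [
        BoneRotation(f.label, float(e), f.origin.copy(), f.e_z.copy())
        for f, e in zip(frames, eta_deg)
    ]
    if weights is None:
        w, s = fusion_weights(labels, [f.label for f in frames], cfg)
    else:
        w, s = weights
    return PolyaffineModel(rots, w, s, cfg)


def _blend_displacement(points: np.ndarray, w: np.ndarray, subs) -> np.ndarray:
    """Eq.-style weighted blend: x + sum_t w_t (e^{A_t/S} x - x) / sum_t w_t."""
    total = w.sum(axis=0)
    disp = np.zeros_like(points)
    for wt, (R_sub, t_sub) in zip(w, subs):
        moved = points @ R_sub.T + t_sub
        disp += wt[:, None] * (moved - points)
    out = points.copy()
    mask = total > _EPS_SUPPORT
    out[mask] += disp[mask] / total[mask, None]
    return out


def fusion_step(points: np.ndarray, model: PolyaffineModel, sign: float = 1.0,
                frozen_weights: np.ndarray | None = None) -> np.ndarray:
    """One 1/S sub-transformation of the 2nd-order fusion scheme.

    Weights are evaluated at the current positions by tricubic
    interpolation of the normalized maps (or taken from
    ``frozen_weights``, shape (M, n)); points without weight support
    are returned unchanged.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    w = model.weights_at(pts) if frozen_weights is None else frozen_weights
    subs = [r.substep_affine(model.config.S, sign) for r in model.rotations]
    return _blend_displacement(pts, w, subs)


def transform_points(
    points: np.ndarray,
    model: PolyaffineModel,
    k: int | None = None,
    sign: float = 1.0,
    freeze_weights: bool = False,
) -> np.ndarray:
    """k-fold composition of fusion sub-steps (k defaults to S).

    By default the fusion weights are re-sampled at each intermediate
    position, following the composition of sub-transformations; with
    ``freeze_weights`` they are evaluated once at the initial points,
    making each point's motion an exact affine map iterated k times
    (the mode used for reference-landmark co-transformation).
    """
    k = model.config.S if k is None else k
    if not (1 <= k <= model.config.S):
        raise ValueError("need 1 <= k <= S")
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    scalar_in = np.asarray(points).ndim == 1
    frozen = model.weights_at(pts) if freeze_weights else None
    for _ in range(k):
        pts = fusion_step(pts, model, sign=sign, frozen_weights=frozen)
    return pts[0] if scalar_in else pts


def warp_volume(volume: Volume, model: PolyaffineModel, chunk: int = 200_000) -> Volume:
    """Articulate a volume by inverse warping.

    Every target voxel is mapped back to its source position by
    composing the inverse model (negated angles) over S steps, and the
    source intensity is tricubically interpolated (0 outside the
    domain).  Voxels outside the weight support never move and are
    copied directly, which keeps the cost proportional to the joint
    region rather than the full grid.
    """
    data = volume.data
    out = data.astype(float).copy()
    idx = np.argwhere(model.support)
    if idx.shape[0] == 0:
        return Volume(out, volume.voxel_size)
    targets = index_to_world(idx.astype(float), data.shape)
    for lo in range(0, targets.shape[0], chunk):
        t = targets[lo:lo + chunk]
        src = transform_points(t, model, sign=-1.0)
        vals = tricubic_interpolate(data, src, world=True)
        sel = idx[lo:lo + chunk]
        out[sel[:, 0], sel[:, 1], sel[:, 2]] = vals
    return Volume(out, volume.voxel_size)


def warp_labels(labels: np.ndarray, model: PolyaffineModel, chunk: int = 200_000) -> np.ndarray:
    """Nearest-neighbor inverse warp of an integer label volume."""
    out = np.asarray(labels).copy()
    # labels move wherever the fusion has support, including into
    # previously-background voxels; warp the support region
    idx = np.argwhere(model.support)
    if idx.shape[0] == 0:
        return out
    targets = index_to_world(idx.astype(float), labels.shape)
    shape = np.array(labels.shape)
    for lo in range(0, targets.shape[0], chunk):
        t = targets[lo:lo + chunk]
        src = transform_points(t, model, sign=-1.0)
        src_idx = np.rint(world_to_index(src, labels.shape)).astype(int)
        valid = np.all((src_idx >= 0) & (src_idx < shape), axis=1)
        vals = np.zeros(t.shape[0], dtype=out.dtype)
        vals[valid] = np.asarray(labels)[tuple(src_idx[valid].T)]
        sel = idx[lo:lo + chunk]
        out[sel[:, 0], sel[:, 1], sel[:, 2]] = vals
    return out
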
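"""Synthetic two-bone articulated limb phantom.

Generates a limb-like test object with two elongated "bones" (capsules
with condyle-like spherical bulges at the distal end) meeting at a knee
joint, embedded in a soft-tissue ellipsoid.  The phantom provides the
ground truth a dissected-limb CT scan would: exact per-bone label masks,
joint origins, and a deterministic attenuation volume, so every
downstream stage (segmentation, frames, landmarks, articulation,
projection, registration) can be exercised with known answers.

Layout: the parent bone ("femur") runs from the upper part of the
volume down to the joint; the child bone ("tibia") continues from the
joint at a configurable inter-bone angle.  Joint ``j1`` (the parent
joint, hip-like) sits at the proximal femur end; joint ``j2`` (knee)
in the gap between the bones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_ops import Volume, index_to_world

__all__ = ["PhantomConfig", "make_limb_phantom"]


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (96, 96, 96)
    femur_half_length: float = 14.0
    femur_radius: float = 6.5
    tibia_half_length: float = 13.0
    tibia_radius: float = 5.0
    joint_gap: float = 24.0
    inter_bone_angle: float = 25.0      # degrees between bone long axes
    plane_tilt: float = 25.0            # tilt of the limb plane about the
                                        # vertical axis: keeps the bone
                                        # transverse axes oblique to the
                                        # projection axis, as in real limbs
    bulge_radius_frac: float = 1.25     # condyle radius / bone radius
    mu_background: float = 0.0
    mu_soft: float = 0.25
    mu_bone: float = 1.0
    soft_padding: float = 10.0          # ellipsoid margin around the bones
    noise_sd: float = 0.01              # soft-tissue texture noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mu_bone > self.mu_soft > self.mu_background >= 0):
            raise ValueError("attenuation must order bone > soft tissue > background >= 0")
        if self.joint_gap <= 0:
            raise ValueError("joint_gap must be positive")


def _capsule_mask(world: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    """Voxels within distance r of segment a-b (world coords, (...,3) grid)."""
    ab = b - a
    denom = float(ab @ ab)
    ap = world - a
    t = np.clip((ap @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    d2 = np.sum((world - closest) ** 2, axis=-1)
    return d2 <= r * r


def _sphere_mask(world: np.ndarray, c: np.ndarray, r: float) -> np.ndarray:
    return np.sum((world - c) ** 2, axis=-1) <= r * r


def _bone_mask(
    world: np.ndarray,
    proximal: np.ndarray,
    distal: np.ndarray,
    radius: float,
    bulge_radius: float,
    transverse: np.ndarray,
) -> np.ndarray:
    """Capsule plus two condyle bulges offset along the transverse axis."""
    mask = _capsule_mask(world, proximal, distal, radius)
    axis = distal - proximal
    axis = axis / np.linalg.norm(axis)
    off = 0.6 * radius
    center = distal - 0.5 * bulge_radius * axis
    mask |= _sphere_mask(world, center + off * transverse, bulge_radius)
    mask |= _sphere_mask(world, center - off * transverse, bulge_radius)
    return mask


def make_limb_phantom(config: PhantomConfig | None = None):
    """Build the phantom volume.

    Returns
    -------
    volume : Volume
        Attenuation volume (background < soft tissue < bone, with mild
        seeded texture noise inside the soft tissue).
    labels : ndarray of int
        Exact generative masks: 0 background, 1 femur, 2 tibia.
    joints : list of ndarray
        World coordinates of [O_j1 (proximal femur), O_j2 (knee)].
    """
    cfg = config or PhantomConfig()
    shape = tuple(cfg.shape)
    idx = np.indices(shape).astype(float)
    world = np.moveaxis(idx, 0, -1) - (np.array(shape, dtype=float) - 1.0) / 2.0

    # bone axes in the (tilted) limb plane; the limb is bent by the
    # inter-bone angle and the plane is rotated about the vertical axis
    half = np.deg2rad(cfg.inter_bone_angle) / 2.0
    tilt = np.deg2rad(cfg.plane_tilt)
    Rt = np.array([[np.cos(tilt), 0.0, np.sin(tilt)],
                   [0.0, 1.0, 0.0],
                   [-np.sin(tilt), 0.0, np.cos(tilt)]])
    d_femur = Rt @ np.array([np.sin(half), -np.cos(half), 0.0])   # pointing down-ish
    d_tibia = Rt @ np.array([-np.sin(half), -np.cos(half), 0.0])
    transverse = Rt @ np.array([0.0, 0.0, 1.0])

    knee = np.zeros(3)
    femur_distal = knee - (cfg.joint_gap / 2.0) * d_femur
    femur_proximal = femur_distal - 2.0 * cfg.femur_half_length * d_femur
    tibia_proximal = knee + (cfg.joint_gap / 2.0) * d_tibia
    tibia_distal = tibia_proximal + 2.0 * cfg.tibia_half_length * d_tibia

    lim = (np.array(shape, dtype=float) - 1.0) / 2.0
    for p, r in [
        (femur_proximal, cfg.femur_radius),
        (femur_distal, cfg.femur_radius * cfg.bulge_radius_frac),
        (tibia_distal, cfg.tibia_radius),
        (tibia_proximal, cfg.tibia_radius * cfg.bulge_radius_frac),
    ]:
        if np.any(np.abs(p) + r > lim):
            raise ValueError("bones do not fit inside the volume shape")

    femur = _bone_mask(world, femur_proximal, femur_distal,
                       cfg.femur_radius, cfg.bulge_radius_frac * cfg.femur_radius,
                       transverse)
    # tibia condyles sit at its proximal (knee) end
    tibia = _bone_mask(world, tibia_distal, tibia_proximal,
                       cfg.tibia_radius, cfg.bulge_radius_frac * cfg.tibia_radius,
                       transverse)
    if np.any(femur & tibia):
        raise ValueError("bones overlap: joint gap too small for the bulge radii")

    labels = np.zeros(shape, dtype=np.int32)
    labels[femur] = 1
    labels[tibia] = 2

    # soft-tissue ellipsoid around the whole bone extent
    ends = np.array([femur_proximal, femur_distal, tibia_proximal, tibia_distal])
    soft_center = ends.mean(axis=0)
    semi = (ends.max(axis=0) - ends.min(axis=0)) / 2.0 + \
        max(cfg.femur_radius, cfg.tibia_radius) * cfg.bulge_radius_frac + cfg.soft_padding
    semi = np.minimum(semi, lim - 0.5)
    soft = np.sum(((world - soft_center) / semi) ** 2, axis=-1) <= 1.0

    data = np.full(shape, cfg.mu_background, dtype=float)
    data[soft] = cfg.mu_soft
    data[labels > 0] = cfg.mu_bone
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(0.0, cfg.noise_sd, size=shape)
        tex = soft & (labels == 0)
        # keep the attenuation ordering strict: clip noise inside the band
        band = (cfg.mu_bone - cfg.mu_soft) * 0.45
        data[tex] += np.clip(noise[tex], -min(band, cfg.mu_soft - cfg.mu_background) * 0.9, band)

    joints = [femur_proximal.copy(), knee.copy()]
    return Volume(data), labels, joints
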
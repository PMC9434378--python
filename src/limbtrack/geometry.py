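"""Cone-beam acquisition geometry and rigid pose parameterization.

The acquisition frame is right-handed with its origin at the system
isocenter: ``x`` horizontal and parallel to the detector rows, ``y``
vertical, ``z`` the source-to-detector projection axis.  The X-ray point
source sits at ``(0, 0, -sod)`` and the flat detector plane at
``z = sdd - sod``; the perpendicular projection of the source coincides
with the detector center, i.e. the system is calibrated.

A rigid pose is parameterized by three translations (voxel units) and
rotations about the three frame axes: the in-plane angle ``theta`` about
``z``, the projection (gantry) angle ``phi`` about ``y``, and the pitch
``eta`` about ``x``.  The pitch of the whole object duplicates the
parent-joint articulation angle, so it is *not* a free registration
parameter; it is carried separately (``eta_o``) and fixed externally.
All public angles are degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ConeBeamGeometry",
    "PoseParameters",
    "rotation_matrix",
    "project_point",
    "apply_rigid",
    "apply_rigid_inverse",
]


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Calibrated cone-beam system.

    Parameters
    ----------
    sod, sdd : float
        Source-to-isocenter and source-to-detector distances, in voxel
        units of the reference volume.  Their ratio ``sdd/sod`` is the
        magnification at the isocenter plane.
    det_rows, det_cols : int
        Detector size in native (pre-binning) pixels.
    det_pitch : float
        Native detector pixel pitch in voxel units.
    binning : int
        Integer detector downsampling factor ``b >= 1``; downstream
        images are ``det_rows/b x det_cols/b`` and 2D coordinates are
        expressed in binned pixels.
    """

    sod: float
    sdd: float
    det_rows: int = 96
    det_cols: int = 96
    det_pitch: float = 1.0
    binning: int = 1

    def __post_init__(self) -> None:
        if not (self.sdd > self.sod > 0):
            raise ValueError(f"require sdd > sod > 0, got sod={self.sod}, sdd={self.sdd}")
        if self.det_pitch <= 0:
            raise ValueError("det_pitch must be positive")
        if self.binning < 1 or int(self.binning) != self.binning:
            raise ValueError("binning must be an integer >= 1")

    @property
    def magnification(self) -> float:
        return self.sdd / self.sod

    @property
    def image_shape(self) -> tuple[int, int]:
        """(rows, cols) of the binned radiograph."""
        return (self.det_rows // self.binning, self.det_cols // self.binning)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConeBeamGeometry":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ConeBeamGeometry":
        path = Path(path)
        d = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls.from_dict(d)


@dataclass
class PoseParameters:
    """Rigid pose vector; joint pitches append to make the 5+N parameters."""

    x_o: float = 0.0
    y_o: float = 0.0
    z_o: float = 0.0
    theta_o: float = 0.0  # degrees, about z (in-plane)
    phi_o: float = 0.0    # degrees, about y (projection angle)
    eta_joints: list[float] = field(default_factory=list)  # degrees, per joint

    @property
    def n_params(self) -> int:
        return 5 + len(self.eta_joints)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.x_o, self.y_o, self.z_o], dtype=float)

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.x_o, self.y_o, self.z_o, self.theta_o, self.phi_o, *self.eta_joints],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "PoseParameters":
        v = np.asarray(v, dtype=float)
        return cls(v[0], v[1], v[2], v[3], v[4], list(v[5:]))

    def to_dict(self) -> dict:
        return {
            "x_o": self.x_o, "y_o": self.y_o, "z_o": self.z_o,
            "theta_o": self.theta_o, "phi_o": self.phi_o,
            "eta_joints": list(self.eta_joints),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoseParameters":
        return cls(**d)


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_matrix(pose: PoseParameters, eta_o: float = 0.0) -> np.ndarray:
    """Rigid rotation ``R = R_y(phi) @ R_z(theta) @ R_x(eta)``.

    ``eta_o`` (degrees) is the whole-object pitch about the horizontal
    axis; it duplicates the parent-joint articulation and is therefore
    passed separately rather than read from the pose vector.
    """
    for a in (pose.theta_o, pose.phi_o, eta_o):
        if not np.isfinite(a):
            raise ValueError("pose angles must be finite")
    theta, phi, eta = np.deg2rad([pose.theta_o, pose.phi_o, eta_o])
    return _rot_y(phi) @ _rot_z(theta) @ _rot_x(eta)


def project_point(geom: ConeBeamGeometry, p: np.ndarray) -> np.ndarray:
    """Perspective projection of world point(s) onto the binned detector.

    Points are ``(..., 3)`` in world voxel units; the result is
    ``(..., 2)`` continuous binned-pixel coordinates ``(u, v)`` with the
    origin at the detector center.  A point at depth ``z`` projects with
    scale ``sdd / (sod + z)``; the isocenter maps to ``(0, 0)``.

    Raises
    ------
    ValueError
        If any point lies at or behind the source plane (``sod + z <= 0``),
        where the perspective map diverges.
    """
    p = np.asarray(p, dtype=float)
    depth = geom.sod + p[..., 2]
    if np.any(depth <= 0):
        raise ValueError("point at or behind the X-ray source: projection diverges")
    scale = geom.sdd / depth / (geom.det_pitch * geom.binning)
    return np.stack([p[..., 0] * scale, p[..., 1] * scale], axis=-1)


def apply_rigid(pose: PoseParameters, p: np.ndarray, eta_o: float = 0.0) -> np.ndarray:
    """Apply the rigid pose: ``p' = R p + t`` (vectorized over points)."""
    R = rotation_matrix(pose, eta_o)
    p = np.asarray(p, dtype=float)
    return p @ R.T + pose.translation


def apply_rigid_inverse(pose: PoseParameters, p: np.ndarray, eta_o: float = 0.0) -> np.ndarray:
    """Invert :func:`apply_rigid`: ``p = R.T (p' - t)``."""
    R = rotation_matrix(pose, eta_o)
    p = np.asarray(p, dtype=float)
    return (p - pose.translation) @ R
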
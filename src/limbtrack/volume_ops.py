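"""Volume container, bone segmentation, PCA bone frames, tricubic sampling.

World coordinates are grid indices re-centered so that the volume center
is the origin shared with :mod:`limbtrack.geometry`:
``world = index - (shape - 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Volume",
    "BoneFrame",
    "otsu_threshold",
    "segment_bones",
    "bone_frame",
    "tricubic_interpolate",
    "read_volume",
    "write_volume",
    "world_to_index",
    "index_to_world",
]

# 6-connectivity structuring element for component labeling
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class Volume:
    """3D scalar grid with the world origin at the grid center.

    ``voxel_size`` (micrometers) is carried as metadata only; all
    geometry downstream works in voxel units.
    """

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume requires a 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def center(self) -> np.ndarray:
        return (np.array(self.shape, dtype=float) - 1.0) / 2.0


def world_to_index(points: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    return np.asarray(points, dtype=float) + (np.array(shape, dtype=float) - 1.0) / 2.0


def index_to_world(idx: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    return np.asarray(idx, dtype=float) - (np.array(shape, dtype=float) - 1.0) / 2.0


def otsu_threshold(volume: Volume | np.ndarray, bins: int = 256) -> float:
    """Threshold maximizing between-class variance over a uniform histogram.

    The histogram spans ``[min, max]`` with ``bins`` bins; ties between
    equal-variance cuts break toward the lower threshold.  Returns the
    bin-edge value separating the two classes.
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    vmin, vmax = float(data.min()), float(data.max())
    if vmin == vmax:
        raise ValueError("degenerate histogram: volume is constant")
    hist, edges = np.histogram(data.ravel(), bins=bins, range=(vmin, vmax))
    hist = hist.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    m = np.cumsum(hist * centers)
    # class means for cut after bin i (bins 0..i vs i+1..)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    i = int(np.argmax(between))  # argmax takes first max: lower-threshold tie break
    return float(edges[i + 1])


def segment_bones(
    volume: Volume,
    min_voxels: int = 50,
    close_size: int = 9,
    threshold: float | None = None,
) -> np.ndarray:
    """Otsu-based bone segmentation with small-component removal and closing.

    Pipeline: binarize above the Otsu threshold, drop 6-connected
    components smaller than ``min_voxels``, morphologically close with a
    cubic ``close_size**3`` structuring element (fills internal
    cavities), then relabel by 6-connectivity with labels sorted by
    descending component size (label 1 = largest bone).
    """
    if close_size < 1 or close_size % 2 == 0:
        raise ValueError("close_size must be odd and >= 1")
    if threshold is None:
        threshold = otsu_threshold(volume)
    mask = volume.data > threshold
    if not mask.any():
        raise ValueError("empty segmentation: no voxels above threshold")

    lab, n = ndimage.label(mask, structure=_STRUCT6)
    if n:
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_voxels
        keep[0] = False
        mask = keep[lab]
    if not mask.any():
        raise ValueError("empty segmentation: all components below min_voxels")

    if close_size > 1:
        selem = np.ones((close_size,) * 3, dtype=bool)
        mask = ndimage.binary_closing(mask, structure=selem)

    lab, n = ndimage.label(mask, structure=_STRUCT6)
    if n == 0:
        raise ValueError("empty segmentation after closing")
    sizes = np.bincount(lab.ravel())[1:]
    order = np.argsort(-sizes, kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[lab]


@dataclass
class BoneFrame:
    """PCA bone coordinate system.

    ``axes`` rows are the orthonormal vertical/longitudinal/transverse
    unit vectors (``e_x``, ``e_y``, ``e_z``); ``eigenvalues`` are the
    voxel-coordinate variances sorted descending (sigma_max, sigma_mid,
    sigma_min).  ``origin`` is the joint origin: the segment center of
    mass slid along the longitudinal axis by the semi-axis length
    ``2 * sqrt(sigma_max)``, with the direction set by ``end_hint``.
    """

    origin: np.ndarray
    axes: np.ndarray          # rows: e_x (vertical), e_y (longitudinal), e_z (transverse)
    eigenvalues: np.ndarray   # descending: (sigma_max, sigma_mid, sigma_min)
    com: np.ndarray
    label: int = 0

    @property
    def e_x(self) -> np.ndarray:
        return self.axes[0]

    @property
    def e_y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def e_z(self) -> np.ndarray:
        return self.axes[2]

    @property
    def sigma_min(self) -> float:
        return float(self.eigenvalues[2])

    @property
    def sigma_max(self) -> float:
        return float(self.eigenvalues[0])


def bone_frame(labels: np.ndarray, bone: int, end_hint: int = +1) -> BoneFrame:
    """PCA frame of one labeled bone in world coordinates.

    Unweighted voxel coordinates are decomposed by PCA; the
    largest-variance eigenvector is the longitudinal axis ``e_y``, the
    smallest the transverse ``e_z``, and ``e_x = e_y x e_z`` completes a
    right-handed frame.  ``end_hint`` (+1/-1) picks which bone end the
    joint origin slides toward, replacing the visual check a human would
    do on real anatomy.

    Raises
    ------
    ValueError
        If the voxel cloud is isotropic (sigma_max within 1% of
        sigma_mid) and the longitudinal axis is ambiguous, or if the
        bone has fewer than 4 voxels.
    """
    idx = np.argwhere(np.asarray(labels) == bone)
    if idx.shape[0] == 0:
        raise ValueError(f"bone label {bone} is empty")
    if idx.shape[0] < 4:
        raise ValueError("bone label needs >= 4 voxels for a stable frame")
    if end_hint not in (+1, -1):
        raise ValueError("end_hint must be +1 or -1")

    coords = index_to_world(idx, labels.shape)
    com = coords.mean(axis=0)
    cov = np.cov(coords.T, bias=True)  # population variance of the voxel cloud
    evals, evecs = np.linalg.eigh(cov)      # ascending
    evals = evals[::-1]                     # descending
    evecs = evecs[:, ::-1]

    if evals[0] <= 0 or (evals[0] - evals[1]) / evals[0] < 0.01:
        raise ValueError("ambiguous frame: voxel cloud has no distinct major axis")

    e_y = evecs[:, 0]
    e_z = evecs[:, 2]
    # deterministic signs: largest-magnitude component positive
    for v in (e_y, e_z):
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1.0
    e_x = np.cross(e_y, e_z)

    L = 2.0 * np.sqrt(evals[0])
    origin = com + end_hint * L * e_y
    return BoneFrame(
        origin=origin,
        axes=np.vstack([e_x, e_y, e_z]),
        eigenvalues=evals.copy(),
        com=com,
        label=bone,
    )


def _lagrange_weights(t: np.ndarray) -> tuple[np.ndarray, ...]:
    """Cubic Lagrange weights for neighbor offsets (-1, 0, 1, 2) at fraction t."""
    w_m1 = -t * (t - 1.0) * (t - 2.0) / 6.0
    w_0 = (t + 1.0) * (t - 1.0) * (t - 2.0) / 2.0
    w_p1 = -(t + 1.0) * t * (t - 2.0) / 2.0
    w_p2 = (t + 1.0) * t * (t - 1.0) / 6.0
    return w_m1, w_0, w_p1, w_p2


def tricubic_interpolate(
    volume: Volume | np.ndarray,
    points: np.ndarray,
    world: bool = True,
) -> np.ndarray:
    """Local separable tricubic (Lagrange) interpolation.

    For each point the 3rd-order polynomial through the 4x4x4 integer
    neighborhood is evaluated, which reproduces per-axis cubic
    polynomials exactly in the interior and passes through the samples
    on the lattice.  Neighbor indices clamp at the grid edges (so
    lattice points remain exact on the boundary); points strictly
    outside the grid return the fill value 0.

    Parameters
    ----------
    points : (..., 3) array, world coordinates by default
        (``world=False`` takes raw grid-index coordinates).
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if any(s < 4 for s in data.shape):
        raise ValueError("tricubic interpolation needs shape >= 4 per axis")
    pts = np.asarray(points, dtype=float)
    scalar_in = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if world:
        pts = world_to_index(pts, data.shape)

    shape = np.array(data.shape)
    inside = np.all((pts >= 0.0) & (pts <= shape - 1.0), axis=-1)

    base = np.floor(pts).astype(np.int64)
    # lattice points at the upper edge: keep base in range
    base = np.minimum(base, shape - 2)
    frac = pts - base

    wx = _lagrange_weights(frac[:, 0])
    wy = _lagrange_weights(frac[:, 1])
    wz = _lagrange_weights(frac[:, 2])

    out = np.zeros(pts.shape[0])
    for a, wa in enumerate(wx):
        ia = np.clip(base[:, 0] + a - 1, 0, shape[0] - 1)
        acc_y = np.zeros_like(out)
        for b, wb in enumerate(wy):
            ib = np.clip(base[:, 1] + b - 1, 0, shape[1] - 1)
            acc_z = np.zeros_like(out)
            for c, wc in enumerate(wz):
                ic = np.clip(base[:, 2] + c - 1, 0, shape[2] - 1)
                acc_z += wc * data[ia, ib, ic]
            acc_y += wb * acc_z
        out += wa * acc_y

    out[~inside] = 0.0
    return out[0] if scalar_in else out


def write_volume(path: str | Path, volume: Volume | np.ndarray, voxel_size: float = 1.0) -> None:
    """Write a volume as MetaImage (.mha/.mhd) or NIfTI (.nii/.nii.gz)."""
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if isinstance(volume, Volume):
        voxel_size = volume.voxel_size
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))  # sitk is z,y,x
    img.SetSpacing((voxel_size,) * 3)
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> Volume:
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).T
    return Volume(np.ascontiguousarray(data), voxel_size=float(img.GetSpacing()[0]))
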
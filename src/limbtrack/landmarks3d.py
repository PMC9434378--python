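"""3D reference landmark extraction.

Two candidate pools feed the same selection scheme: ordinary bone voxels
("bounding" landmarks) and 3D scale-space difference-of-Gaussians
keypoints ("sift" landmarks).  Selection is greedy by distance to the
bone's center of mass with a pairwise distance floor derived from the
smallest PCA eigenvalue, which spreads landmarks near the bone surface
and keeps them mutually distant — the property that makes their 2D
projections distinguishable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_ops import BoneFrame, Volume, index_to_world

__all__ = [
    "SelectionConfig",
    "LandmarkSet3D",
    "candidate_bone_voxels",
    "dog_keypoints3d",
    "select_landmarks",
    "surface_voxels",
    "save_landmarks",
    "load_landmarks",
]


@dataclass
class SelectionConfig:
    """Parameters of the shortest-coordinate-variance selection scheme.

    ``lam`` is the heuristic scale threshold: a new landmark must be at
    least ``lam * s_min`` from every selected one, where ``s_min`` is
    ``sqrt(sigma_min)`` by default (``sigma_scale="sqrt"``), i.e. the
    standard deviation along the bone's minor axis.  ``sigma_scale=
    "variance"`` compares against the raw eigenvalue instead.
    """

    K: int = 20
    lam: float = 2.1
    sigma_scale: str = "sqrt"     # "sqrt" | "variance"
    tie_break: str = "lex"        # lowest lexicographic coordinate wins ties

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.sigma_scale not in ("sqrt", "variance"):
            raise ValueError("sigma_scale must be 'sqrt' or 'variance'")


@dataclass
class LandmarkSet3D:
    """Selected reference landmarks of one bone (world voxel units)."""

    bone: int
    kind: str                       # "bounding" | "sift"
    coordinates: np.ndarray         # (K, 3)
    sigma_min: float
    com: np.ndarray
    lam: float
    exhausted: bool = False         # fewer than K candidates qualified

    def __len__(self) -> int:
        return len(self.coordinates)


def candidate_bone_voxels(labels: np.ndarray, bone: int) -> np.ndarray:
    """All voxel centers of a bone label, world coords, lexicographic order."""
    idx = np.argwhere(np.asarray(labels) == bone)  # argwhere is lexicographic
    if idx.shape[0] == 0:
        raise ValueError(f"bone label {bone} is empty")
    return index_to_world(idx, labels.shape)


def surface_voxels(labels: np.ndarray, bone: int) -> np.ndarray:
    """Bone voxels with at least one 6-neighbor outside the bone."""
    mask = np.asarray(labels) == bone
    if not mask.any():
        raise ValueError(f"bone label {bone} is empty")
    interior = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1))
    idx = np.argwhere(mask & ~interior)
    return index_to_world(idx, labels.shape)


def dog_keypoints3d(
    volume: Volume | np.ndarray,
    labels: np.ndarray | None = None,
    bone: int | None = None,
    scales: tuple[float, ...] = (1.0, 1.6, 2.6, 4.0),
    contrast: float = 0.1,
    margin: int = 2,
) -> np.ndarray:
    """Local extrema of the 3D difference-of-Gaussians scale space.

    An extremum must dominate (or be dominated by) its 26 spatial
    neighbors in its own DoG level and the same neighborhoods in the
    adjacent levels, and exceed the contrast floor — ``contrast`` times
    the maximum |DoG| over the scale space — which suppresses the weak
    side lobes every blob response carries.  If a label mask
    is given, keypoints are restricted to within ``margin`` voxels of
    the bone.  Returns world coordinates ordered by |DoG| descending
    (descriptor computation is not needed: only positions feed the
    landmark selection).
    """
    data = (volume.data if isinstance(volume, Volume) else np.asarray(volume)).astype(float)
    if len(scales) < 2:
        raise ValueError("need at least 2 scales")
    smoothed = [ndimage.gaussian_filter(data, s) for s in scales]
    dog = np.stack([smoothed[i + 1] - smoothed[i] for i in range(len(scales) - 1)])

    fp = np.ones((3, 3, 3, 3), dtype=bool)
    mx = ndimage.maximum_filter(dog, footprint=fp, mode="nearest")
    mn = ndimage.minimum_filter(dog, footprint=fp, mode="nearest")
    # scale axis clamps at its ends (mode="nearest"), so extrema at the
    # outermost difference levels are kept; the contrast floor and the
    # spatial dedup below keep them from multiplying
    floor = max(contrast * np.abs(dog).max(), 1e-8)
    is_ext = ((dog >= mx) | (dog <= mn)) & (np.abs(dog) > floor)

    if labels is not None and bone is not None:
        region = ndimage.binary_dilation(
            np.asarray(labels) == bone,
            ndimage.generate_binary_structure(3, 1),
            iterations=margin,
        )
        is_ext &= region[None]

    pos = np.argwhere(is_ext)
    if pos.shape[0] == 0:
        return np.empty((0, 3))
    strength = np.abs(dog[tuple(pos.T)])
    order = np.lexsort((pos[:, 3], pos[:, 2], pos[:, 1], -strength))
    coords = pos[order][:, 1:]
    # deduplicate spatial positions found at several scales (keep strongest)
    _, first = np.unique(coords, axis=0, return_index=True)
    coords = coords[np.sort(first)]
    return index_to_world(coords.astype(float), np.asarray(data).shape)


def select_landmarks(
    candidates: np.ndarray,
    frame: BoneFrame,
    config: SelectionConfig,
    kind: str = "bounding",
) -> LandmarkSet3D:
    """Greedy shortest-coordinate-variance landmark selection.

    The first landmark is the candidate farthest from the bone CoM; each
    subsequent landmark is the farthest-from-CoM candidate whose
    distance to every already-selected landmark is at least
    ``lam * s_min``.  Stops at ``K`` landmarks or candidate exhaustion
    (``exhausted`` flag set).  Ties in CoM distance break toward the
    lowest lexicographic coordinate.
    """
    cands = np.asarray(candidates, dtype=float)
    if cands.ndim != 2 or cands.shape[0] == 0:
        raise ValueError("candidates must be a nonempty (n, 3) array")

    s_min = np.sqrt(frame.sigma_min) if config.sigma_scale == "sqrt" else frame.sigma_min
    floor = config.lam * s_min
    d_com = np.linalg.norm(cands - frame.com, axis=1)
    # sort by descending CoM distance, lexicographic tie-break
    order = np.lexsort((cands[:, 2], cands[:, 1], cands[:, 0], -d_com))
    ranked = cands[order]

    selected: list[np.ndarray] = [ranked[0]]
    for c in ranked[1:]:
        if len(selected) >= config.K:
            break
        d = np.linalg.norm(np.asarray(selected) - c, axis=1)
        if np.all(d >= floor):
            selected.append(c)

    return LandmarkSet3D(
        bone=frame.label,
        kind=kind,
        coordinates=np.asarray(selected),
        sigma_min=frame.sigma_min,
        com=frame.com.copy(),
        lam=config.lam,
        exhausted=len(selected) < config.K,
    )


def save_landmarks(path: str | Path, sets: list[LandmarkSet3D]) -> None:
    """CSV (bone,type,index,x,y,z) plus a JSON sidecar with the metadata."""
    path = Path(path)
    rows = []
    meta = {}
    for ls in sets:
        for i, (x, y, z) in enumerate(ls.coordinates):
            rows.append({"bone": ls.bone, "type": ls.kind, "index": i,
                         "x": x, "y": y, "z": z})
        meta[f"{ls.bone}:{ls.kind}"] = {
            "lambda": ls.lam, "sigma_min": ls.sigma_min,
            "com": list(ls.com), "exhausted": ls.exhausted,
        }
    pd.DataFrame(rows).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_landmarks(path: str | Path) -> list[LandmarkSet3D]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    out = []
    for (bone, kind), grp in df.groupby(["bone", "type"], sort=False):
        m = meta[f"{bone}:{kind}"]
        grp = grp.sort_values("index")
        out.append(LandmarkSet3D(
            bone=int(bone), kind=str(kind),
            coordinates=grp[["x", "y", "z"]].to_numpy(float),
            sigma_min=m["sigma_min"], com=np.array(m["com"]),
            lam=m["lambda"], exhausted=m["exhausted"],
        ))
    return out
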
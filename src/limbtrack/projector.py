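"""Radiograph simulation: ray-driven cone-beam projection and the
training-dataset plan.

Projection casts one ray per *binned* detector pixel from the point
source through the posed volume, accumulating trilinearly-sampled
attenuation at half-voxel steps (a digitally reconstructed radiograph).
Poisson noise follows the acquisition recipe used for network training
data: the noiseless projection is scaled so its maximum equals a photon
budget ``I0`` and every pixel is replaced by a Poisson draw with that
mean.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import ConeBeamGeometry, PoseParameters, rotation_matrix
from .volume_ops import Volume, world_to_index

__all__ = [
    "Radiograph",
    "AcquisitionPlan",
    "DatasetSample",
    "project_volume",
    "project_mask",
    "add_poisson_noise",
    "build_manifest",
    "generate_dataset",
    "write_dataset",
    "training_plan",
    "study_plan",
]


@dataclass
class Radiograph:
    image: np.ndarray
    geometry: ConeBeamGeometry
    pose: PoseParameters
    I0: float | None = None


def _ray_grid(geom: ConeBeamGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Binned pixel-center coordinates (u, v) in binned pixels, detector-center origin."""
    rows, cols = geom.image_shape
    v = np.arange(rows, dtype=float) - (rows - 1) / 2.0
    u = np.arange(cols, dtype=float) - (cols - 1) / 2.0
    uu, vv = np.meshgrid(u, v)
    return uu, vv


def _march(values_fn, geom: ConeBeamGeometry, pose: PoseParameters, eta_o: float,
           radius: float, step: float = 0.5):
    """Generic ray march: yields (sample block, step length) accumulation.

    Rays run from the source ``(0,0,-sod)`` to each binned pixel center
    on the detector plane; sampling is restricted to the sphere of
    ``radius`` voxels about the isocenter that bounds the posed volume.
    ``values_fn`` maps world sample positions (n, 3) to values.
    """
    uu, vv = _ray_grid(geom)
    pix = geom.det_pitch * geom.binning
    det = np.stack([uu * pix, vv * pix, np.full_like(uu, geom.sdd - geom.sod)], axis=-1)
    src = np.array([0.0, 0.0, -geom.sod])
    d = det - src
    d /= np.linalg.norm(d, axis=-1, keepdims=True)

    # ray / bounding-sphere intersection (sphere centered at pose translation)
    oc = src - pose.translation
    b = d @ oc
    c = oc @ oc - radius * radius
    disc = b * b - c
    hit = disc > 0
    sq = np.sqrt(np.maximum(disc, 0.0))
    t0 = np.maximum(-b - sq, 0.0)
    t1 = -b + sq

    img = np.zeros(uu.shape)
    if not hit.any():
        return img
    n_steps = int(np.ceil((t1[hit].max() - t0[hit].min()) / step))
    hit_idx = np.argwhere(hit)
    dirs = d[hit]
    starts = t0[hit]
    ends = t1[hit]
    acc = np.zeros(dirs.shape[0])
    ts = starts.copy()
    # march all hit rays in lockstep; each ray accumulates only within [t0, t1]
    for _ in range(n_steps):
        active = ts < ends
        if not active.any():
            break
        pos = src + dirs * ts[:, None]
        vals = np.zeros(dirs.shape[0])
        vals[active] = values_fn(pos[active])
        acc += vals * step
        ts = ts + step
    img[hit] = acc
    return img


def _volume_sampler(volume_data: np.ndarray, pose: PoseParameters, eta_o: float, order: int = 1):
    R = rotation_matrix(pose, eta_o)
    t = pose.translation
    shape = volume_data.shape

    def fn(world_pts: np.ndarray) -> np.ndarray:
        local = (world_pts - t) @ R  # R^{-1} = R^T applied from the right
        idx = world_to_index(local, shape)
        return ndimage.map_coordinates(volume_data, idx.T, order=order,
                                       mode="constant", cval=0.0, prefilter=False)
    return fn


def _bounding_radius(shape) -> float:
    return float(np.linalg.norm((np.array(shape, dtype=float) - 1) / 2.0)) + 1.0


def project_volume(volume: Volume, geom: ConeBeamGeometry,
                   pose: PoseParameters | None = None, eta_o: float = 0.0,
                   step: float = 0.5) -> Radiograph:
    """Cone-beam line-integral radiograph of a rigidly posed volume."""
    pose = pose or PoseParameters()
    fn = _volume_sampler(volume.data.astype(float), pose, eta_o)
    img = _march(fn, geom, pose, eta_o, _bounding_radius(volume.shape), step)
    return Radiograph(img, geom, pose)


def project_mask(labels: np.ndarray, bone: int, geom: ConeBeamGeometry,
                 pose: PoseParameters | None = None, eta_o: float = 0.0,
                 step: float = 0.5) -> np.ndarray:
    """Binary 2D mask: pixel is 1 iff the ray meets any material of the bone."""
    pose = pose or PoseParameters()
    mask3d = (np.asarray(labels) == bone).astype(float)
    fn = _volume_sampler(mask3d, pose, eta_o)
    img = _march(fn, geom, pose, eta_o, _bounding_radius(mask3d.shape), step)
    return img > 1e-9


def add_poisson_noise(radiograph: Radiograph | np.ndarray, I0: float, seed: int = 0) -> Radiograph | np.ndarray:
    """Scale the projection to maximum ``I0`` and draw Poisson counts."""
    img = radiograph.image if isinstance(radiograph, Radiograph) else np.asarray(radiograph)
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    m = img.max()
    if m <= 0:
        raise ValueError("all-zero projection: cannot scale to I0")
    # interpolation undershoot can leave tiny negative integrals; a
    # Poisson mean is a photon count and cannot be negative
    scaled = np.clip(img * (I0 / m), 0.0, None)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(scaled).astype(float)
    if isinstance(radiograph, Radiograph):
        return Radiograph(noisy, radiograph.geometry, radiograph.pose, I0=I0)
    return noisy


@dataclass
class AcquisitionPlan:
    """Enumeration of the simulated acquisition campaign.

    ``articulation_grids`` lists, per joint, the pitch angles sampled;
    their product defines the articulated volumes.  ``angle_centers``
    are projection-angle interval centers (degrees) with jitter
    ``angle_half_width``; each interval yields ``projections_per_interval``
    radiographs whose remaining parameters are drawn uniformly from the
    stated jitter ranges.
    """

    articulation_grids: list[list[float]]
    angle_centers: list[float]
    angle_half_width: float
    projections_per_interval: int
    sod: tuple[float, float] = (6550.0, 180.0)      # mean, half-range
    sdd: tuple[float, float] = (10000.0, 540.0)
    xyz_range: tuple[float, float, float] = (180.0, 120.0, 180.0)
    tilt_range: float = 15.0                         # theta and eta jitter, degrees
    I0: tuple[float, float] = (2000.0, 350.0)
    split_fractions: tuple[float, float, float] = (0.75, 0.20, 0.05)
    seed: int = 0

    @property
    def n_volumes(self) -> int:
        return int(np.prod([len(g) for g in self.articulation_grids]))

    @property
    def n_entries(self) -> int:
        return self.n_volumes * len(self.angle_centers) * self.projections_per_interval


def training_plan(seed: int = 0) -> AcquisitionPlan:
    """The full training-data campaign: 6x5 articulation grid, 40
    projection-angle intervals (20 per gantry side, +/-1.5 deg), 13
    projections each -> 30 volumes, 15,600 radiographs."""
    return AcquisitionPlan(
        articulation_grids=[list(np.linspace(-30.0, 35.0, 6)),
                            list(np.linspace(-20.0, 35.0, 5))],
        angle_centers=list(np.linspace(-30.0, 30.0, 20)) + list(np.linspace(150.0, 210.0, 20)),
        angle_half_width=1.5,
        projections_per_interval=13,
        seed=seed,
    )


def study_plan(seed: int = 0) -> AcquisitionPlan:
    """The held-out study campaign: 3x3 articulation grid (9 volumes),
    8 +/-7.5-deg intervals, shifted source/detector distances."""
    return AcquisitionPlan(
        articulation_grids=[list(np.linspace(-19.0, 30.0, 3)),
                            list(np.linspace(-16.0, 30.0, 3))],
        angle_centers=list(np.linspace(-30.0, 30.0, 4)) + list(np.linspace(150.0, 210.0, 4)),
        angle_half_width=7.5,
        projections_per_interval=25,
        sod=(6450.0, 180.0),
        sdd=(10200.0, 540.0),
        seed=seed,
    )


def build_manifest(plan: AcquisitionPlan) -> list[dict]:
    """Enumerate every acquisition with its jittered parameters.

    One entry per (articulated volume x angle interval x projection):
    joint pitches, rigid pose, source/detector distances, photon budget
    and split tag, all drawn from the plan's seeded ranges.
    """
    rng = np.random.default_rng(plan.seed)
    entries = []
    volumes = list(itertools.product(*plan.articulation_grids))
    for vol_id, etas in enumerate(volumes):
        for int_id, center in enumerate(plan.angle_centers):
            for proj_id in range(plan.projections_per_interval):
                u = rng.uniform(-1.0, 1.0, size=9)
                entries.append({
                    "volume_id": vol_id,
                    "interval_id": int_id,
                    "projection_id": proj_id,
                    "eta_joints": list(etas),
                    "phi": center + u[0] * plan.angle_half_width,
                    "x": u[1] * plan.xyz_range[0],
                    "y": u[2] * plan.xyz_range[1],
                    "z": u[3] * plan.xyz_range[2],
                    "theta": u[4] * plan.tilt_range,
                    "eta": u[5] * plan.tilt_range,
                    "sod": plan.sod[0] + u[6] * plan.sod[1],
                    "sdd": plan.sdd[0] + u[7] * plan.sdd[1],
                    "I0": plan.I0[0] + u[8] * plan.I0[1],
                })
    # seeded shuffle for split assignment
    order = rng.permutation(len(entries))
    n = len(entries)
    n_train = int(round(plan.split_fractions[0] * n))
    n_val = int(round(plan.split_fractions[1] * n))
    splits = np.empty(n, dtype=object)
    splits[order[:n_train]] = "train"
    splits[order[n_train:n_train + n_val]] = "val"
    splits[order[n_train + n_val:]] = "test"
    for e, s in zip(entries, splits):
        e["split"] = s
    return entries


@dataclass
class DatasetSample:
    """One simulated acquisition with full ground truth."""

    radiograph: Radiograph
    masks: dict[int, np.ndarray]                  # per-bone binary 2D masks
    landmarks_2d: dict[tuple[int, str], np.ndarray]  # (bone, kind) -> (K, 2)
    landmarks_in_view: dict[tuple[int, str], np.ndarray]
    pose: PoseParameters
    eta_o: float
    entry: dict
    split: str


def generate_dataset(
    manifest: list[dict],
    volume: Volume,
    labels: np.ndarray,
    landmark_sets,
    model_builder,
    det_shape: tuple[int, int] = (96, 96),
    det_pitch: float = 1.0,
    binning: int = 1,
    noise: bool = True,
    warp_volumes: bool = True,
) -> list[DatasetSample]:
    """Materialize manifest entries into samples with ground truth.

    ``model_builder(eta_joints)`` must return the articulation
    :class:`~limbtrack.polyaffine.PolyaffineModel` for the grid angles.
    Articulated volumes and label masks are cached per ``volume_id``;
    reference landmarks are co-transformed with the same model (weights
    frozen at the reference positions, the mode the registration
    forward model replays), then rigidly posed and projected.
    """
    from .geometry import apply_rigid, project_point
    from .polyaffine import transform_points, warp_volume as _warp, warp_labels as _warpl

    cache: dict[int, tuple] = {}
    samples = []
    for entry in manifest:
        vid = entry["volume_id"]
        if vid not in cache:
            model = model_builder(entry["eta_joints"])
            pts3d = {
                (ls.bone, ls.kind): transform_points(ls.coordinates, model, freeze_weights=True)
                for ls in landmark_sets
            }
            if warp_volumes:
                wvol = _warp(volume, model)
                wlab = _warpl(labels, model)
            else:
                wvol, wlab = volume, labels
            cache[vid] = (wvol, wlab, pts3d)
        wvol, wlab, pts3d = cache[vid]

        geom = ConeBeamGeometry(
            sod=entry["sod"], sdd=entry["sdd"],
            det_rows=det_shape[0] * binning, det_cols=det_shape[1] * binning,
            det_pitch=det_pitch, binning=binning,
        )
        pose = PoseParameters(entry["x"], entry["y"], entry["z"],
                              entry["theta"], entry["phi"], list(entry["eta_joints"]))
        eta_o = entry["eta"]

        rad = project_volume(wvol, geom, pose, eta_o=eta_o)
        if noise:
            seed = abs(hash((vid, entry["interval_id"], entry["projection_id"]))) % (2**31)
            rad = add_poisson_noise(rad, entry["I0"], seed=seed)
        bones = sorted({ls.bone for ls in landmark_sets})
        masks = {b: project_mask(wlab, b, geom, pose, eta_o=eta_o) for b in bones}

        lm2d, inview = {}, {}
        rows, cols = geom.image_shape
        for key, p3 in pts3d.items():
            posed = apply_rigid(pose, p3, eta_o=eta_o)
            uv = project_point(geom, posed)
            lm2d[key] = uv
            inview[key] = (np.abs(uv[:, 0]) <= (cols - 1) / 2) & \
                          (np.abs(uv[:, 1]) <= (rows - 1) / 2)
        samples.append(DatasetSample(rad, masks, lm2d, inview, pose, eta_o,
                                     entry, entry.get("split", "train")))
    return samples


def write_dataset(samples: list[DatasetSample], out_dir: str | Path) -> Path:
    """Write samples to disk: 16-bit TIFF radiographs, PNG masks, and a
    JSON-lines manifest with poses and 2D ground-truth landmarks.

    Returns the manifest path.  Radiographs are scaled to the 16-bit
    range per file (the scale is recorded in the manifest line).
    """
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    (out / "radiographs").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    manifest_path = out / "manifest.jsonl"
    with manifest_path.open("w") as fh:
        for i, s in enumerate(samples):
            img = s.radiograph.image
            scale = 65535.0 / img.max() if img.max() > 0 else 1.0
            rad_path = out / "radiographs" / f"{i:05d}.tif"
            tifffile.imwrite(rad_path, (img * scale).astype(np.uint16))
            mask_paths = {}
            for b, m in s.masks.items():
                mp = out / "masks" / f"{i:05d}_bone{b}.png"
                iio.imwrite(mp, (m.astype(np.uint8) * 255))
                mask_paths[str(b)] = str(mp.relative_to(out))
            line = {
                "radiograph": str(rad_path.relative_to(out)),
                "intensity_scale": scale,
                "masks": mask_paths,
                "pose": s.pose.to_dict(),
                "eta_o": s.eta_o,
                "I0": s.radiograph.I0,
                "split": s.split,
                "landmarks_2d": {f"{b}:{k}": uv.tolist()
                                 for (b, k), uv in s.landmarks_2d.items()},
                "in_view": {f"{b}:{k}": v.tolist()
                            for (b, k), v in s.landmarks_in_view.items()},
            }
            fh.write(json.dumps(line) + "\n")
    return manifest_path
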
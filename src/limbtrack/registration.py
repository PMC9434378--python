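"""Landmark-based 2D/3D pose reconstruction.

The pose vector ``tau = {x, y, z, theta, phi, eta_j1..eta_jN}`` is
recovered by minimizing the covariance-weighted sum of squared pixel
residuals between measured 2D landmarks and the projections of the
articulated, rigidly-posed 3D reference landmarks.  To sidestep local
minima the parameters are estimated in stages — projection angle phi,
then the vertical offset y, then all three offsets, then the joint
pitches, then the remaining orientations — and the stage cycle repeats
until parameter updates and the cost stall below tolerance.  Source and
detector distances and the whole-object pitch ``eta_o`` are taken as
known (calibrated / fixed to ground truth), and all free parameters
start from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import ConeBeamGeometry, PoseParameters, apply_rigid, project_point
from .landmarks3d import LandmarkSet3D
from .polyaffine import PolyaffineModel, BoneRotation
from .volume_ops import BoneFrame

__all__ = [
    "ObservationSet",
    "RegistrationConfig",
    "PoseEstimate",
    "ArticulatedForwardModel",
    "forward_landmarks",
    "cost",
    "register",
    "evaluate_errors",
]


@dataclass
class ObservationSet:
    """Measured 2D landmarks (voted means) with their weights.

    ``uv`` stacks the per-landmark detector coordinates (n, 2) over all
    bones/joints; ``weights`` are the Mahalanobis weights (inverse voted
    covariance).  ``eta_o`` is the fixed whole-object pitch.
    """

    uv: np.ndarray
    weights: np.ndarray
    eta_o: float = 0.0

    def __post_init__(self) -> None:
        self.uv = np.asarray(self.uv, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("observation weights must be positive")
        if self.uv.shape[0] < 6:
            raise ValueError("pose observability requires >= 6 landmarks")


@dataclass
class RegistrationConfig:
    tol: float = 1e-8
    max_outer: int = 60
    phi_grid_step: float = 5.0           # deg, stage-1 global sweep
    phi_bounds: tuple[float, float] = (-60.0, 240.0)
    xyz_bounds: tuple[float, float, float] = (360.0, 240.0, 360.0)  # +/- bounds
    theta_bound: float = 30.0
    eta_bounds: list[tuple[float, float]] = field(
        default_factory=lambda: [(-60.0, 70.0), (-40.0, 70.0)])
    articulation: str = "polyaffine"     # "polyaffine" | "rigid_chain"
    joint_refine: bool = True            # full-vector polish closing each cycle


@dataclass
class PoseEstimate:
    pose: PoseParameters
    cost: float
    trajectory: list[dict]
    converged: bool
    partial: bool = False


class ArticulatedForwardModel:
    """Projects reference landmarks for a candidate pose.

    Articulation uses the same polyaffine landmark motion that generated
    the data, with fusion weights frozen at the reference positions:
    each landmark's articulated position is an exact affine map (the
    weight-blended sub-step exponential) iterated S times, so the
    residual is smooth in the joint pitches.  A hierarchical
    ``rigid_chain`` mode instead rotates each bone rigidly about its
    joint with the parent pitch carrying the child bone too.
    """

    def __init__(
        self,
        landmark_sets: list[LandmarkSet3D],
        frames: list[BoneFrame],
        geom: ConeBeamGeometry,
        model: PolyaffineModel,
        mode: str = "polyaffine",
    ):
        self.geom = geom
        self.mode = mode
        self.frames = frames
        self.S = model.config.S
        self.points = np.vstack([ls.coordinates for ls in landmark_sets])
        self.slices = []
        lo = 0
        for ls in landmark_sets:
            self.slices.append((ls.bone, ls.kind, slice(lo, lo + len(ls))))
            lo += len(ls)
        # frozen fusion weights at the reference landmark positions
        self.frozen_w = model.weights_at(self.points)      # (M, n)
        self.rotations = model.rotations
        self.bone_of_frame = [f.label for f in frames]

    def articulate(self, eta_joints: list[float]) -> np.ndarray:
        if self.mode == "rigid_chain":
            return self._articulate_chain(eta_joints)
        pts = self.points.copy()
        subs = []
        for r, eta in zip(self.rotations, eta_joints):
            rr = BoneRotation(r.bone, float(eta), r.origin, r.axis)
            subs.append(rr.substep_affine(self.S))
        w = self.frozen_w
        total = w.sum(axis=0)
        mask = total > 1e-8
        for _ in range(self.S):
            disp = np.zeros_like(pts)
            for wt, (R_sub, t_sub) in zip(w, subs):
                disp += wt[:, None] * ((pts @ R_sub.T + t_sub) - pts)
            pts[mask] += disp[mask] / total[mask, None]
        return pts

    def _articulate_chain(self, eta_joints: list[float]) -> np.ndarray:
        from .polyaffine import rodrigues
        pts = self.points.copy()
        # parent joint rotates everything; each child joint rotates its
        # own bone's landmarks on top
        for i, (r, eta) in enumerate(zip(self.rotations, eta_joints)):
            R = rodrigues(r.axis, np.deg2rad(float(eta)))
            if i == 0:
                pts = (pts - r.origin) @ R.T + r.origin
            else:
                for bone, _, sl in self.slices:
                    if bone == r.bone:
                        pts[sl] = (pts[sl] - r.origin) @ R.T + r.origin
        return pts

    def project(self, tau: PoseParameters, eta_o: float = 0.0) -> np.ndarray:
        """(n, 2) projected (u, v); landmarks behind the source get NaN."""
        pts = self.articulate(tau.eta_joints)
        posed = apply_rigid(tau, pts, eta_o=eta_o)
        depth = self.geom.sod + posed[:, 2]
        out = np.full((pts.shape[0], 2), np.nan)
        ok = depth > 0
        if ok.any():
            out[ok] = project_point(self.geom, posed[ok])
        return out


def forward_landmarks(
    tau: PoseParameters,
    landmark_sets: list[LandmarkSet3D],
    frames: list[BoneFrame],
    model: PolyaffineModel,
    geom: ConeBeamGeometry,
    eta_o: float = 0.0,
    mode: str = "polyaffine",
) -> np.ndarray:
    """Projected 2D positions of the reference landmarks under ``tau``."""
    fm = ArticulatedForwardModel(landmark_sets, frames, geom, model, mode=mode)
    return fm.project(tau, eta_o=eta_o)


def cost(tau: PoseParameters, observations: ObservationSet,
         forward: ArticulatedForwardModel) -> float:
    """Weighted sum of squared pixel residuals (flagged landmarks excluded)."""
    uv = forward.project(tau, eta_o=observations.eta_o)
    r = uv - observations.uv
    ok = np.all(np.isfinite(r), axis=1)
    return float(np.sum(observations.weights[ok] * np.sum(r[ok] ** 2, axis=1)))


_STAGES = (
    ("phi",),
    ("y",),
    ("x", "y", "z"),
    ("eta",),            # all joint pitches
    ("theta", "phi"),
)
_PARAM_IDX = {"x": 0, "y": 1, "z": 2, "theta": 3, "phi": 4}


def register(
    observations: ObservationSet,
    landmark_sets: list[LandmarkSet3D],
    frames: list[BoneFrame],
    model: PolyaffineModel,
    geom: ConeBeamGeometry,
    config: RegistrationConfig | None = None,
    init: PoseParameters | None = None,
) -> PoseEstimate:
    """Staged weighted least-squares pose reconstruction.

    Stage order: phi (with a coarse global sweep before the local
    refine, since the gantry angle may sit on either side of the
    object), then y, then {x, y, z}, then the joint pitches, then
    {theta, phi}; the cycle repeats until the largest parameter update
    and the cost change drop below tolerance.  Each stage is a
    trust-region-reflective least-squares solve with a forward-difference
    Jacobian over only that stage's parameters.

    With fewer than 3 landmarks per joint the rotation stages are
    refused and a partial (translation-only) estimate is returned.
    """
    cfg = config or RegistrationConfig()
    n_joints = len(model.rotations)
    fwd = ArticulatedForwardModel(landmark_sets, frames, geom, model,
                                  mode=cfg.articulation)
    per_joint = min(len(ls.coordinates) for ls in landmark_sets)
    rotations_ok = per_joint >= 3

    vec = (init or PoseParameters(eta_joints=[0.0] * n_joints)).to_vector()
    if len(vec) != 5 + n_joints:
        vec = np.concatenate([vec[:5], np.zeros(n_joints)])
    sqw = np.sqrt(observations.weights)

    def residuals(v: np.ndarray) -> np.ndarray:
        uv = fwd.project(PoseParameters.from_vector(v), eta_o=observations.eta_o)
        r = (uv - observations.uv)
        r[~np.isfinite(r)] = 0.0
        return (sqw[:, None] * r).ravel()

    def total_cost(v: np.ndarray) -> float:
        return float(np.sum(residuals(v) ** 2))

    def bounds_for(names):
        lo, hi = [], []
        for nm in names:
            if nm == "x":
                lo.append(-cfg.xyz_bounds[0]); hi.append(cfg.xyz_bounds[0])
            elif nm == "y":
                lo.append(-cfg.xyz_bounds[1]); hi.append(cfg.xyz_bounds[1])
            elif nm == "z":
                lo.append(-cfg.xyz_bounds[2]); hi.append(cfg.xyz_bounds[2])
            elif nm == "theta":
                lo.append(-cfg.theta_bound); hi.append(cfg.theta_bound)
            elif nm == "phi":
                lo.append(cfg.phi_bounds[0]); hi.append(cfg.phi_bounds[1])
        return np.array(lo), np.array(hi)

    trajectory: list[dict] = []
    prev_cost = total_cost(vec)
    converged = False

    stages = _STAGES + (("all",),) if cfg.joint_refine else _STAGES
    for outer in range(cfg.max_outer):
        start_vec = vec.copy()
        for stage in stages:
            if stage == ("eta",) or stage == ("all",):
                if stage == ("eta",) and (not rotations_ok or n_joints == 0):
                    continue
                eta_lo = np.array([cfg.eta_bounds[min(i, len(cfg.eta_bounds) - 1)][0]
                                   for i in range(n_joints)])
                eta_hi = np.array([cfg.eta_bounds[min(i, len(cfg.eta_bounds) - 1)][1]
                                   for i in range(n_joints)])
                if stage == ("eta",):
                    idx = list(range(5, 5 + n_joints))
                    lo, hi = eta_lo, eta_hi
                else:
                    if rotations_ok:
                        idx = list(range(5 + n_joints))
                        blo, bhi = bounds_for(("x", "y", "z", "theta", "phi"))
                        lo = np.concatenate([blo, eta_lo])
                        hi = np.concatenate([bhi, eta_hi])
                    else:
                        idx = [0, 1, 2]
                        lo, hi = bounds_for(("x", "y", "z"))
            else:
                if not rotations_ok and any(nm in ("theta", "phi") for nm in stage):
                    continue
                idx = [_PARAM_IDX[nm] for nm in stage]
                lo, hi = bounds_for(stage)

            if stage == ("phi",) and outer == 0:
                # global sweep across the allowed gantry range; each
                # candidate angle gets a quick translation fit so the
                # sweep ranks alignment, not the unknown offsets
                grid = np.arange(cfg.phi_bounds[0], cfg.phi_bounds[1] + 1e-9,
                                 cfg.phi_grid_step)
                t_lo, t_hi = bounds_for(("x", "y", "z"))
                best = (np.inf, vec[4], vec[:3].copy())
                for g in grid:
                    v = vec.copy()
                    v[4] = g

                    def t_res(t3, v=v):
                        vv = v.copy()
                        vv[:3] = t3
                        return residuals(vv)

                    ts = least_squares(t_res, np.clip(v[:3], t_lo, t_hi),
                                       bounds=(t_lo, t_hi), method="trf",
                                       max_nfev=20)
                    c = float(np.sum(ts.fun ** 2))
                    if c < best[0]:
                        best = (c, g, ts.x.copy())
                if best[0] < prev_cost:
                    vec[4] = best[1]
                    vec[:3] = best[2]

            def stage_res(sub: np.ndarray) -> np.ndarray:
                v = vec.copy()
                v[idx] = sub
                return residuals(v)

            x0 = np.clip(vec[idx], lo, hi)
            sol = least_squares(stage_res, x0, bounds=(lo, hi), method="trf",
                                xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol)
            if np.sum(sol.fun ** 2) <= total_cost(vec):
                vec[idx] = sol.x
            trajectory.append({"outer": outer, "stage": "+".join(stage),
                               "cost": float(np.sum(sol.fun ** 2))})

        c = total_cost(vec)
        if max(np.max(np.abs(vec - start_vec)), 0.0) < cfg.tol or abs(prev_cost - c) < cfg.tol:
            prev_cost = c
            converged = True
            break
        prev_cost = c

    return PoseEstimate(
        pose=PoseParameters.from_vector(vec),
        cost=prev_cost,
        trajectory=trajectory,
        converged=converged,
        partial=not rotations_ok,
    )


def evaluate_errors(estimates: list[PoseParameters],
                    truths: list[PoseParameters]) -> pd.DataFrame:
    """Per-parameter absolute-error statistics behind the boxplots.

    Columns: median, q1, q3, whisker_lo/hi (1.5 IQR fences clipped to
    the data), and the outlier list beyond the fences.
    """
    if len(estimates) != len(truths):
        raise ValueError("estimates and truths must have equal length")
    n_j = max(len(t.eta_joints) for t in truths) if truths else 0
    names = ["x_o", "y_o", "z_o", "theta_o", "phi_o"] + \
        [f"eta_j{i+1}" for i in range(n_j)]
    errs = {nm: [] for nm in names}
    for e, t in zip(estimates, truths):
        ve, vt = e.to_vector(), t.to_vector()
        for i, nm in enumerate(names):
            errs[nm].append(abs(ve[i] - vt[i]) if i < len(ve) else np.nan)
    rows = []
    for nm in names:
        a = np.asarray(errs[nm], dtype=float)
        a = a[np.isfinite(a)]
        q1, med, q3 = np.percentile(a, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = a[(a >= lo_fence) & (a <= hi_fence)]
        rows.append({
            "parameter": nm,
            "median": med, "q1": q1, "q3": q3,
            "whisker_lo": inside.min() if inside.size else np.nan,
            "whisker_hi": inside.max() if inside.size else np.nan,
            "outliers": sorted(a[(a < lo_fence) | (a > hi_fence)].tolist()),
            "n": int(a.size),
        })
    return pd.DataFrame(rows).set_index("parameter")
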
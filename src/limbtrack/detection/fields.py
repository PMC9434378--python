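"""Voting vector fields: encoding 2D landmarks and decoding them back.

A landmark's position is represented by a 2-channel field of unit
vectors, one per bone-mask pixel, each pointing at the landmark.  The
representation survives partial occlusion and local prediction errors
because the landmark is re-estimated globally: pairs of pixels cast
ray-intersection hypotheses, each hypothesis is scored by how many mask
pixels' vectors agree with it angularly, and the scored hypotheses are
condensed into a mean, a scalar covariance, and an inverse-covariance
weight for the downstream pose fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VectorFieldTarget",
    "VotingConfig",
    "LandmarkObservation2D",
    "encode_vector_field",
    "vote_landmark",
    "uv_to_pixel",
    "pixel_to_uv",
]


def uv_to_pixel(uv: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Detector-centered (u, v) -> (row, col) array coordinates."""
    uv = np.asarray(uv, dtype=float)
    rows, cols = image_shape
    return np.stack([uv[..., 1] + (rows - 1) / 2.0, uv[..., 0] + (cols - 1) / 2.0], axis=-1)


def pixel_to_uv(rc: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    rc = np.asarray(rc, dtype=float)
    rows, cols = image_shape
    return np.stack([rc[..., 1] - (cols - 1) / 2.0, rc[..., 0] - (rows - 1) / 2.0], axis=-1)


@dataclass
class VectorFieldTarget:
    """Ground-truth (or predicted) voting field for one landmark.

    ``field`` has shape (2, rows, cols): channels are the (row, col)
    components of the unit vector from each mask pixel toward the
    landmark; zero outside the mask and at the landmark pixel itself.
    """

    field: np.ndarray
    mask: np.ndarray
    landmark_rc: np.ndarray | None = None


@dataclass
class VotingConfig:
    n_hypotheses: int = 256
    inlier_cos: float = 0.99
    quorum: float = 0.9       # hypotheses below quorum * best score get no vote
    eps: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hypotheses < 1:
            raise ValueError("n_hypotheses must be >= 1")
        if not (0 < self.inlier_cos <= 1):
            raise ValueError("inlier_cos must lie in (0, 1]")
        if not (0 <= self.quorum <= 1):
            raise ValueError("quorum must lie in [0, 1]")


@dataclass
class LandmarkObservation2D:
    """Voted landmark: mean, scalar covariance, Mahalanobis weight."""

    mu_hat: np.ndarray     # (row, col) pixels
    sigma: float           # px^2, score-weighted mean squared distance to mu_hat
    omega: float           # 1 / (sigma + eps)


def encode_vector_field(mask: np.ndarray, landmark_rc: np.ndarray) -> VectorFieldTarget:
    """Unit vectors from every mask pixel toward the landmark."""
    mask = np.asarray(mask, dtype=bool)
    lm = np.asarray(landmark_rc, dtype=float)
    if not np.all(np.isfinite(lm)):
        raise ValueError("landmark coordinates must be finite")
    if not mask.any():
        raise ValueError("mask is empty")
    field = np.zeros((2,) + mask.shape)
    rr, cc = np.nonzero(mask)
    d = lm[None, :] - np.stack([rr, cc], axis=1).astype(float)
    norm = np.linalg.norm(d, axis=1)
    nz = norm > 0
    d[nz] /= norm[nz, None]
    d[~nz] = 0.0
    field[0, rr, cc] = d[:, 0]
    field[1, rr, cc] = d[:, 1]
    return VectorFieldTarget(field, mask, lm)


def vote_landmark(field: np.ndarray | VectorFieldTarget, mask: np.ndarray | None = None,
                  config: VotingConfig | None = None) -> LandmarkObservation2D:
    """RANSAC-style voting decode of a landmark from its vector field.

    Samples ``n_hypotheses`` pixel pairs; each pair's two rays are
    intersected into a hypothesis point; a hypothesis's score is the
    number of mask pixels whose vector points at it within the angular
    inlier threshold.  Returns the score-weighted hypothesis mean, the
    scalar covariance (weighted mean squared distance), and the
    Mahalanobis weight ``1 / (sigma + eps)``.

    Raises
    ------
    ValueError
        If fewer than 2 mask pixels carry usable vectors, or every
        vector pair is parallel (no ray intersections exist).
    """
    cfg = config or VotingConfig()
    if isinstance(field, VectorFieldTarget):
        mask = field.mask if mask is None else mask
        field = field.field
    field = np.asarray(field, dtype=float)
    mask = np.asarray(mask, dtype=bool)

    rr, cc = np.nonzero(mask)
    pix = np.stack([rr, cc], axis=1).astype(float)
    vec = field[:, rr, cc].T
    norms = np.linalg.norm(vec, axis=1)
    usable = norms > 1e-9
    pix, vec = pix[usable], vec[usable] / norms[usable, None]
    n = pix.shape[0]
    if n < 2:
        raise ValueError("degenerate voting: fewer than 2 usable mask pixels")

    rng = np.random.default_rng(cfg.seed)
    i = rng.integers(0, n, size=cfg.n_hypotheses)
    j = rng.integers(0, n, size=cfg.n_hypotheses)
    same = i == j
    j[same] = (j[same] + 1) % n

    p1, v1 = pix[i], vec[i]
    p2, v2 = pix[j], vec[j]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    ok = np.abs(cross) > 1e-9
    if not ok.any():
        raise ValueError("degenerate voting: all sampled vector pairs are parallel")
    dp = p2 - p1
    denom = np.where(ok, cross, 1.0)
    t1 = (dp[:, 0] * v2[:, 1] - dp[:, 1] * v2[:, 0]) / denom
    t2 = (dp[:, 0] * v1[:, 1] - dp[:, 1] * v1[:, 0]) / denom
    # vectors point toward the landmark: both ray parameters must be
    # nonnegative for a geometrically valid intersection
    ok &= (t1 >= 0) & (t2 >= 0)
    if not ok.any():
        raise ValueError("degenerate voting: no forward ray intersections")
    hyp = (p1 + t1[:, None] * v1)[ok]

    # score: inlier count over all usable mask pixels
    diff = hyp[:, None, :] - pix[None, :, :]          # (H, n, 2)
    dist = np.linalg.norm(diff, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("hnd,nd->hn", diff, vec) / np.where(dist > 0, dist, 1.0)
    inlier = (cosang >= cfg.inlier_cos) | (dist == 0)
    scores = inlier.sum(axis=1).astype(float)
    # any hypothesis near the mask collects a baseline of accidental
    # inliers; only the consensus cluster near the best score votes
    scores[scores < cfg.quorum * scores.max()] = 0.0

    if scores.sum() <= 0:
        scores[:] = 1.0
    w = scores / scores.sum()
    mu = w @ hyp
    sigma = float(w @ np.sum((hyp - mu) ** 2, axis=1))
    return LandmarkObservation2D(mu_hat=mu, sigma=sigma, omega=1.0 / (sigma + cfg.eps))
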
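"""Desk-scale training harness for BoneNet.

One model per (bone, landmark-type), following the study protocol;
training minimizes the masked smooth-L1 field loss plus segmentation
cross entropy with Adam and a multistep schedule that multiplies the
base learning rate by ``0.5**e`` over the first five epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bonenet import BoneNet, BoneNetConfig, bonenet_loss, build_bonenet
from .fields import LandmarkObservation2D, VotingConfig, encode_vector_field, uv_to_pixel, vote_landmark
from .nn import Adam

__all__ = ["TrainConfig", "train_bonenet", "detect_landmarks",
           "make_training_arrays", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    base_lr: float = 1e-5
    decay_epochs: int = 5           # lr = base * 0.5**min(e, decay_epochs)
    max_epochs: int = 30            # full protocol runs to 600
    batch_size: int = 4
    seed: int = 0
    delta: float = 1.0
    val_fraction: float = 0.2

    def lr_at(self, epoch: int) -> float:
        return self.base_lr * 0.5 ** min(epoch, self.decay_epochs)


def make_training_arrays(samples, bone: int, kind: str):
    """Stack dataset samples into (images, target fields, masks).

    Images are normalized to [0, 1] per sample; target vector fields are
    encoded in (row, col) channel pairs per landmark over the bone mask.
    """
    xs, fs, ms = [], [], []
    for s in samples:
        img = s.radiograph.image.astype(float)
        rng = img.max() - img.min()
        img = (img - img.min()) / (rng if rng > 0 else 1.0)
        mask = s.masks[bone]
        uv = s.landmarks_2d[(bone, kind)]
        rc = uv_to_pixel(uv, img.shape)
        chans = []
        for lm in rc:
            tgt = encode_vector_field(mask, lm)
            chans.append(tgt.field)
        xs.append(img[None])
        fs.append(np.concatenate(chans, axis=0))
        ms.append(mask.astype(float))
    return np.stack(xs), np.stack(fs), np.stack(ms)


def train_bonenet(
    images: np.ndarray,
    target_fields: np.ndarray,
    target_masks: np.ndarray,
    net_config: BoneNetConfig | None = None,
    train_config: TrainConfig | None = None,
    net: BoneNet | None = None,
):
    """Train on (N, 1, H, W) images; returns (net, history dict).

    History carries per-epoch training and validation losses (the
    validation split is carved from the tail of the sample array).
    Aborts with a diagnostic if the loss turns non-finite.
    """
    cfg = train_config or TrainConfig()
    if images.shape[0] < 1:
        raise ValueError("need at least one training sample")
    K = target_fields.shape[1] // 2
    if net is None:
        nc = net_config or BoneNetConfig(input_size=images.shape[2], K=K)
        net = build_bonenet(nc)

    n = images.shape[0]
    n_val = int(round(cfg.val_fraction * n)) if n > 2 else 0
    tr = slice(0, n - n_val)
    va = slice(n - n_val, n) if n_val else None

    opt = Adam(net.parameters(), net.gradients(), lr=cfg.base_lr)
    rng = np.random.default_rng(cfg.seed)
    history = {"train": [], "val": [], "field": [], "ce": []}

    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(np.arange(tr.start, tr.stop))
        ep_loss, ep_field, ep_ce, nb = 0.0, 0.0, 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            pf, ps = net.forward(images[sel], train=True)
            total, fl, ce, dpf, dps = bonenet_loss(
                pf, ps, target_fields[sel], target_masks[sel],
                delta=cfg.delta, return_grads=True)
            if not np.isfinite(total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={total}")
            opt.zero_grad()
            net.backward(dpf, dps)
            opt.step()
            ep_loss += total
            ep_field += fl
            ep_ce += ce
            nb += 1
        history["train"].append(ep_loss / nb)
        history["field"].append(ep_field / nb)
        history["ce"].append(ep_ce / nb)
        if va is not None:
            pf, ps = net.forward(images[va], train=False)
            vl, _, _ = bonenet_loss(pf, ps, target_fields[va], target_masks[va],
                                    delta=cfg.delta)
            history["val"].append(vl)
    return net, history


def detect_landmarks(
    net: BoneNet,
    image: np.ndarray,
    voting: VotingConfig | None = None,
) -> list[LandmarkObservation2D]:
    """Infer voting fields + segment, then vote each landmark."""
    img = np.asarray(image, dtype=float)
    rngv = img.max() - img.min()
    img = (img - img.min()) / (rngv if rngv > 0 else 1.0)
    pf, ps = net.forward(img[None, None], train=False)
    mask = ps[0].argmax(axis=0) > 0
    cfg = voting or VotingConfig()
    obs = []
    for k in range(net.config.K):
        obs.append(vote_landmark(pf[0, 2 * k:2 * k + 2], mask, cfg))
    return obs


def save_checkpoint(net: BoneNet, path) -> None:
    """Serialize parameters + config (numpy archive, this framework's
    native format)."""
    from dataclasses import asdict
    import json as _json
    arrays = {f"p{i}": p for i, p in enumerate(net.parameters())}
    np.savez(path, config=_json.dumps(asdict(net.config)), **arrays)


def load_checkpoint(path) -> BoneNet:
    import json as _json
    data = np.load(path, allow_pickle=False)
    cfg = _json.loads(str(data["config"]))
    cfg["depths"] = tuple(cfg["depths"])
    cfg["widths"] = tuple(cfg["widths"])
    net = build_bonenet(BoneNetConfig(**cfg))
    for i, p in enumerate(net.parameters()):
        p[...] = data[f"p{i}"]
    return net
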
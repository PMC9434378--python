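"""BoneNet: residual encoder-decoder for landmark vector fields.

A ResNet18-style encoder deepened for X-ray data: the four residual
stages carry [3, 3, 4, 3] basic blocks (the baseline keypoint-voting
encoder uses [2, 2, 2, 2]; one, one, two and one extra blocks are added
respectively), spatial resolution bottoms out at 1/8 of the input (the
final stage trades stride for dilation), and the decoder recovers full
resolution with three upsample+convolution steps whose first skip
connection is sourced from the 3rd stage rather than the 2nd.  Heads
emit 2K vector-field channels plus 2 segmentation logits at input
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BasicBlock, BatchNorm2d, Conv2d, ReLU, Upsample2x

__all__ = ["BoneNetConfig", "BoneNet", "build_bonenet", "bonenet_loss", "count_parameters"]

BASELINE_DEPTHS = (2, 2, 2, 2)
BONENET_DEPTHS = (3, 3, 4, 3)


@dataclass
class BoneNetConfig:
    input_size: int = 64
    K: int = 8                                  # landmarks -> 2K field channels
    depths: tuple[int, int, int, int] = BONENET_DEPTHS
    widths: tuple[int, int, int, int] = (8, 16, 32, 64)
    decoder_width: int = 16
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8 (1/8 bottleneck)")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def out_channels(self) -> int:
        return 2 * self.K + 2


class _ConvBNReLU:
    def __init__(self, cin, cout, rng):
        self.conv = Conv2d(cin, cout, 3, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()

    def gradients(self):
        return self.conv.gradients() + self.bn.gradients()


class BoneNet:
    """Encoder-decoder with explicit forward/backward graph."""

    def __init__(self, config: BoneNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.widths
        d = config.depths

        self.stem = _ConvBNReLU.__new__(_ConvBNReLU)
        self.stem.conv = Conv2d(config.in_channels, w[0], 3, stride=2, bias=False, rng=rng)
        self.stem.bn = BatchNorm2d(w[0])
        self.stem.relu = ReLU()

        def stage(cin, cout, depth, stride, dilation=1):
            blocks = [BasicBlock(cin, cout, stride=stride, dilation=dilation, rng=rng)]
            blocks += [BasicBlock(cout, cout, dilation=dilation, rng=rng)
                       for _ in range(depth - 1)]
            return blocks

        self.stage1 = stage(w[0], w[0], d[0], 1)            # 1/2
        self.stage2 = stage(w[0], w[1], d[1], 2)            # 1/4
        self.stage3 = stage(w[1], w[2], d[2], 2)            # 1/8
        self.stage4 = stage(w[2], w[3], d[3], 1, dilation=2)  # 1/8, dilated

        wd = config.decoder_width
        # first decoder conv fuses stage4 with the stage-3 skip (both at 1/8)
        self.dec1 = _ConvBNReLU(w[3] + w[2], wd, rng)
        self.up1 = Upsample2x()
        self.dec2 = _ConvBNReLU(wd + w[1], wd, rng)
        self.up2 = Upsample2x()
        self.dec3 = _ConvBNReLU(wd + w[0], wd, rng)
        self.up3 = Upsample2x()
        self.head = Conv2d(wd, config.out_channels, 1, pad=0, rng=rng)

    # -- graph ---------------------------------------------------------

    def _modules(self):
        return ([self.stem] + self.stage1 + self.stage2 + self.stage3 + self.stage4
                + [self.dec1, self.dec2, self.dec3, self.head])

    def parameters(self):
        return [p for m in self._modules() for p in m.parameters()]

    def gradients(self):
        return [g for m in self._modules() for g in m.gradients()]

    def forward(self, x: np.ndarray, train: bool = True):
        """Input (N, C, H, W) -> (fields (N, 2K, H, W), seg logits (N, 2, H, W))."""
        x = np.asarray(x, dtype=float)
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("input spatial size must be divisible by 8")
        h = self.stem.forward(x, train)
        for b in self.stage1:
            h = b.forward(h, train)
        s1 = h                                   # 1/2
        for b in self.stage2:
            h = b.forward(h, train)
        s2 = h                                   # 1/4
        for b in self.stage3:
            h = b.forward(h, train)
        s3 = h                                   # 1/8
        for b in self.stage4:
            h = b.forward(h, train)

        h = self.dec1.forward(np.concatenate([h, s3], axis=1), train)
        h = self.up1.forward(h, train)
        h = self.dec2.forward(np.concatenate([h, s2], axis=1), train)
        h = self.up2.forward(h, train)
        h = self.dec3.forward(np.concatenate([h, s1], axis=1), train)
        h = self.up3.forward(h, train)
        out = self.head.forward(h, train)
        K2 = 2 * self.config.K
        return out[:, :K2], out[:, K2:]

    def backward(self, dfields: np.ndarray, dseg: np.ndarray) -> None:
        w = self.config.widths
        dout = np.concatenate([dfields, dseg], axis=1)
        d = self.head.backward(dout)
        d = self.up3.backward(d)
        d = self.dec3.backward(d)
        d, dskip1 = d[:, :-w[0]], d[:, -w[0]:]
        d = self.up2.backward(d)
        d = self.dec2.backward(d)
        d, dskip2 = d[:, :-w[1]], d[:, -w[1]:]
        d = self.up1.backward(d)
        d = self.dec1.backward(d)
        d, dskip3 = d[:, :-w[2]], d[:, -w[2]:]
        for b in reversed(self.stage4):
            d = b.backward(d)
        d = d + dskip3
        for b in reversed(self.stage3):
            d = b.backward(d)
        d = d + dskip2
        for b in reversed(self.stage2):
            d = b.backward(d)
        d = d + dskip1
        for b in reversed(self.stage1):
            d = b.backward(d)
        self.stem.backward(d)


def build_bonenet(config: BoneNetConfig | None = None) -> BoneNet:
    return BoneNet(config or BoneNetConfig())


def count_parameters(net: BoneNet) -> int:
    return int(sum(p.size for p in net.parameters()))


def _smooth_l1(r: np.ndarray, delta: float = 1.0):
    a = np.abs(r)
    loss = np.where(a < delta, 0.5 * r * r, delta * (a - 0.5 * delta))
    grad = np.clip(r, -delta, delta)
    return loss, grad


def bonenet_loss(
    pred_fields: np.ndarray,
    pred_seg: np.ndarray,
    target_fields: np.ndarray,
    target_mask: np.ndarray,
    delta: float = 1.0,
    ce_sign: float = +1.0,
    return_grads: bool = False,
):
    """Masked smooth-L1 field loss plus segmentation cross entropy.

    The vector-field term is the smooth-L1 (Huber, transition ``delta``)
    difference between predicted and target fields restricted to the
    ground-truth mask, averaged over masked pixels; the segmentation
    term is the mean 2-class cross entropy of the predicted logits
    against the mask.  The two terms are summed (``ce_sign=-1`` switches
    to the literal subtracted form, retained only for comparison).

    Returns ``(total, field_term, ce_term)`` and, with
    ``return_grads``, the gradients w.r.t. the two predictions.
    """
    mask = np.asarray(target_mask, dtype=float)
    if mask.ndim == 3:
        mask_b = mask[:, None]
    else:
        mask_b = mask
        mask = mask_b[:, 0]
    n_mask = max(mask_b.sum() * pred_fields.shape[1], 1.0)

    r = (pred_fields - target_fields) * mask_b
    l_elem, g_elem = _smooth_l1(r, delta)
    field_term = float(l_elem.sum() / n_mask)
    dfields = g_elem * mask_b / n_mask

    # 2-class softmax cross entropy against the mask
    z = pred_seg - pred_seg.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    t = np.stack([1.0 - mask, mask], axis=1)
    n_pix = float(np.prod(mask.shape))
    ce = float(-(t * np.log(np.clip(p, 1e-12, None))).sum() / n_pix)
    dseg = ce_sign * (p - t) / n_pix

    total = field_term + ce_sign * ce
    if return_grads:
        return total, field_term, ce, dfields, dseg
    return total, field_term, ce
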
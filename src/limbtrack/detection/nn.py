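"""Minimal CPU neural-network layers with explicit backpropagation.

Just enough machinery for a residual encoder-decoder at desk scale:
2D convolution (stride/dilation) via im2col, batch normalization, ReLU,
nearest-neighbor upsampling and the Adam optimizer.  Parameters are
float64 numpy arrays; every layer caches what its backward pass needs.
Determinism follows from seeding the initializer and the batch order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "Upsample2x", "BasicBlock", "Adam"]


class Layer:
    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.dilation = stride, dilation
        self.pad = pad if pad is not None else dilation * (k - 1) // 2
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.b = np.zeros(cout) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None

    def _geometry(self, H: int, W: int):
        eff = self.dilation * (self.k - 1) + 1
        Ho = (H + 2 * self.pad - eff) // self.stride + 1
        Wo = (W + 2 * self.pad - eff) // self.stride + 1
        return eff, Ho, Wo

    def _indices(self, H: int, W: int):
        eff, Ho, Wo = self._geometry(H, W)
        kr = np.arange(self.k) * self.dilation
        r0 = np.arange(Ho) * self.stride
        c0 = np.arange(Wo) * self.stride
        rows = (kr[:, None, None, None] + r0[None, None, :, None])  # (k,1,Ho,1)
        cols = (kr[None, :, None, None] + c0[None, None, None, :])  # (1,k,1,Wo)
        rows = np.broadcast_to(rows, (self.k, self.k, Ho, Wo))
        cols = np.broadcast_to(cols, (self.k, self.k, Ho, Wo))
        return rows.reshape(self.k * self.k, Ho * Wo), cols.reshape(self.k * self.k, Ho * Wo), Ho, Wo

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        rows, cols, Ho, Wo = self._indices(H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols_mat = xp[:, :, rows, cols]                        # (N, C, k*k, L)
        cols_mat = cols_mat.reshape(N, C * self.k * self.k, -1)
        Wm = self.W.reshape(self.cout, -1)
        y = np.einsum("of,nfl->nol", Wm, cols_mat)
        if self.b is not None:
            y += self.b[None, :, None]
        self._cache = (cols_mat, x.shape, rows, cols, Ho, Wo)
        return y.reshape(N, self.cout, Ho, Wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols_mat, xshape, rows, cols, Ho, Wo = self._cache
        N, C, H, W = xshape
        dyf = dy.reshape(N, self.cout, -1)
        Wm = self.W.reshape(self.cout, -1)
        self.dW += np.einsum("nol,nfl->of", dyf, cols_mat).reshape(self.W.shape)
        if self.b is not None:
            self.db += dyf.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", Wm, dyf).reshape(N, C, self.k * self.k, -1)
        dxp = np.zeros((N, C, H + 2 * self.pad, W + 2 * self.pad))
        np.add.at(dxp, (slice(None), slice(None), rows, cols), dcols)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def gradients(self):
        return [self.dW] + ([self.db] if self.b is not None else [])


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.dgamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return term * inv[None, :, None, None]

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Upsample2x(Layer):
    """Nearest-neighbor 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = dy.shape
        return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class BasicBlock(Layer):
    """Two-convolution residual unit (conv-bn-relu-conv-bn + shortcut)."""

    def __init__(self, cin: int, cout: int, stride: int = 1, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, dilation=dilation, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, dilation=dilation, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.short_conv = Conv2d(cin, cout, 1, stride=stride, pad=0, bias=False, rng=rng)
            self.short_bn = BatchNorm2d(cout)
        else:
            self.short_conv = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.short_conv is not None:
            s = self.short_bn.forward(self.short_conv.forward(x, train), train)
        else:
            s = x
        return self.relu2.forward(y + s, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        ds = d
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        if self.short_conv is not None:
            dshort = self.short_conv.backward(self.short_bn.backward(ds))
        else:
            dshort = ds
        return dmain + dshort

    def _sublayers(self):
        subs = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.short_conv is not None:
            subs += [self.short_conv, self.short_bn]
        return subs

    def parameters(self):
        return [p for s in self._sublayers() for p in s.parameters()]

    def gradients(self):
        return [g for s in self._sublayers() for g in s.gradients()]


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
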
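"""Minimal CPU neural-network building blocks (numpy, float32).

Provides exactly what the pipeline's stage models need: 3x3 "same"
convolutions, 2x average pooling, nearest-neighbor upsampling, dense
layers, a small bidirectional recurrent layer for cine sequences, an
encoder-decoder with skip connections, stochastic-gradient-descent with
momentum, and the stage losses (softmax cross-entropy, masked MSE,
cross-entropy + Dice).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    __slots__ = ("value", "grad", "vel")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self.vel = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, d: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) same-padded convolution over (N, C, H, W)."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, scale, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k = k

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        k, p = self.k, self.k // 2
        self._in_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        v = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
        n, c, h, w = x.shape
        self._cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)
                                          ).reshape(n, h, w, c * k * k)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        out = self._cols @ wmat.T + self.b.value
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, d):
        n, c, h, w = self._in_shape
        k, p = self.k, self.k // 2
        cout = self.W.value.shape[0]
        d2 = d.transpose(0, 2, 3, 1).reshape(-1, cout)
        cols2 = self._cols.reshape(-1, c * k * k)
        self.W.grad += (d2.T @ cols2).reshape(self.W.value.shape)
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.W.value.reshape(cout, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + h, kj:kj + w] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, d):
        return d * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, d):
        return np.where(self._mask, d, self.alpha * d)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization with learnable gain/bias.

    Stabilizes the deeper encoder-decoder stacks, which otherwise train
    poorly without any normalization.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gain = Param(np.ones(channels))
        self.bias = Param(np.zeros(channels))
        self.eps = eps

    def params(self):
        return [self.gain, self.bias]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return (self.gain.value[None, :, None, None] * self._xhat
                + self.bias.value[None, :, None, None])

    def backward(self, d):
        xhat, istd = self._xhat, self._istd
        self.gain.grad += (d * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += d.sum(axis=(0, 2, 3))
        dxhat = d * self.gain.value[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return istd * (dxhat - m1 - xhat * m2)


class AvgPool2(Layer):
    """2x2 average pooling (input H, W must be even)."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, d):
        n, c, h, w = self._shape
        return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) * F32(0.25)


class AvgPoolK(Layer):
    """kxk average pooling used as a cheap input downsampler."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        self._shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, d):
        k = self.k
        return np.repeat(np.repeat(d, k, axis=2), k, axis=3) * F32(1.0 / (k * k))


class Up2(Layer):
    """2x nearest-neighbor upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, d):
        n, c, h, w = d.shape
        return d.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, d):
        n, c, h, w = self._shape
        return (d / (h * w))[:, :, None, None] * np.ones(self._shape, dtype=F32)


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / nin), (nout, nin)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, d):
        self.W.grad += d.T @ self._x
        self.b.grad += d.sum(axis=0)
        return d @ self.W.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for lyr in self.layers for p in lyr.params()]

    def forward(self, x):
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, d):
        for lyr in reversed(self.layers):
            d = lyr.backward(d)
        return d


class EncoderDecoder(Layer):
    """Small U-shaped network with skip connections.

    Input (N, cin, S, S) with S divisible by 8; output (N, cout, S, S).
    Channel widths are intentionally small so training stays practical
    on a single CPU.
    """

    def __init__(self, cin: int, cout: int, rng=None, widths=(12, 24, 32)):
        rng = rng or np.random.default_rng(0)
        w0, w1, w2 = widths

        def block(ci, co):
            return [Conv2d(ci, co, rng=rng), InstanceNorm2d(co), LeakyReLU()]

        self.enc0 = Sequential(*block(cin, w0), *block(w0, w0))
        self.enc1 = Sequential(AvgPool2(), *block(w0, w1), *block(w1, w1))
        self.enc2 = Sequential(AvgPool2(), *block(w1, w2), *block(w2, w2))
        self.up1 = Up2()
        self.dec1 = Sequential(*block(w2 + w1, w1))
        self.up0 = Up2()
        self.dec0 = Sequential(*block(w1 + w0, w0), Conv2d(w0, cout, rng=rng))
        self._parts = [self.enc0, self.enc1, self.enc2, self.dec1, self.dec0]

    def params(self):
        return [p for part in self._parts for p in part.params()]

    def forward(self, x):
        e0 = self.enc0.forward(x)
        e1 = self.enc1.forward(e0)
        e2 = self.enc2.forward(e1)
        self._w0, self._w1, self._w2 = e0.shape[1], e1.shape[1], e2.shape[1]
        u1 = np.concatenate([self.up1.forward(e2), e1], axis=1)
        d1 = self.dec1.forward(u1)
        u0 = np.concatenate([self.up0.forward(d1), e0], axis=1)
        return self.dec0.forward(u0)

    def backward(self, d):
        w0, w1, w2 = self._w0, self._w1, self._w2
        du0 = self.dec0.backward(d)
        d_d1 = self.up0.backward(du0[:, :w1])
        de0_skip = du0[:, w1:]
        du1 = self.dec1.backward(d_d1)
        d_e2 = self.up1.backward(du1[:, :w2])
        de1 = self.enc2.backward(d_e2) + du1[:, w2:]
        de0 = self.enc1.backward(de1) + de0_skip
        return self.enc0.backward(de0)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            p.vel[...] = self.momentum * p.vel - self.lr * p.grad
            p.value += p.vel


# ---------------------------------------------------------------------------
# losses (each returns loss value and gradient w.r.t. its first argument)


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Sparse categorical cross-entropy over (N, K) logits."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(F32)

def mse_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray | None = None):
    """Mean squared error; optional broadcastable weight/validity mask."""
    diff = (pred - target).astype(F32)
    if mask is not None:
        diff = diff * mask
        denom = float(np.sum(mask * np.ones_like(diff))) or 1.0
    else:
        denom = diff.size
    loss = float((diff ** 2).sum() / denom)
    return loss, (2.0 * diff / denom).astype(F32)


def cross_entropy_dice(logits: np.ndarray, labels: np.ndarray, eps: float = 1.0):
    """Sum of pixel-wise CE and soft Dice over (N, C, H, W) logits.

    ``labels`` are integer class maps (N, H, W).  Returns loss and the
    gradient with respect to the logits.
    """
    n, c, h, w = logits.shape
    p = softmax(logits, axis=1)
    onehot = np.zeros_like(p)
    idx = np.ogrid[:n, :h, :w]
    onehot[idx[0], labels, idx[1], idx[2]] = 1.0

    npx = n * h * w
    ce = -np.log(p[idx[0], labels, idx[1], idx[2]] + 1e-12).mean()
    dce_dp = np.zeros_like(p)
    dce_dp[idx[0], labels, idx[1], idx[2]] = -1.0 / (
        p[idx[0], labels, idx[1], idx[2]] + 1e-12) / npx

    inter = (p * onehot).sum(axis=(0, 2, 3))
    sums = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice_c = (2.0 * inter + eps) / (sums + eps)
    dice_loss = 1.0 - dice_c.mean()
    ddice_dp = -(2.0 * onehot * (sums + eps)[None, :, None, None]
                 - (2.0 * inter + eps)[None, :, None, None]) \
        / ((sums + eps) ** 2)[None, :, None, None] / c

    dl_dp = dce_dp + ddice_dp
    # chain rule through the softmax
    dz = p * (dl_dp - (dl_dp * p).sum(axis=1, keepdims=True))
    return float(ce + dice_loss), dz.astype(F32)


class BiRNN(Layer):
    """Bidirectional Elman recurrence over (N, T, F) feature sequences."""

    def __init__(self, nin: int, hidden: int, rng=None):
        rng = rng or np.random.default_rng(0)
        s = np.sqrt(1.0 / max(nin, hidden))
        self.Wx_f = Param(rng.normal(0, s, (hidden, nin)))
        self.Wh_f = Param(rng.normal(0, s, (hidden, hidden)))
        self.b_f = Param(np.zeros(hidden))
        self.Wx_b = Param(rng.normal(0, s, (hidden, nin)))
        self.Wh_b = Param(rng.normal(0, s, (hidden, hidden)))
        self.b_b = Param(np.zeros(hidden))
        self.hidden = hidden

    def params(self):
        return [self.Wx_f, self.Wh_f, self.b_f, self.Wx_b, self.Wh_b, self.b_b]

    def _run(self, x, Wx, Wh, b, reverse: bool):
        n, t, _ = x.shape
        hs = np.zeros((n, t, self.hidden), dtype=F32)
        h = np.zeros((n, self.hidden), dtype=F32)
        order = range(t - 1, -1, -1) if reverse else range(t)
        for ti in order:
            h = np.tanh(x[:, ti] @ Wx.value.T + h @ Wh.value.T + b.value)
            hs[:, ti] = h
        return hs

    def forward(self, x):
        self._x = x.astype(F32)
        self._hf = self._run(self._x, self.Wx_f, self.Wh_f, self.b_f, False)
        self._hb = self._run(self._x, self.Wx_b, self.Wh_b, self.b_b, True)
        return np.concatenate([self._hf, self._hb], axis=2)

    def _bptt(self, d, hs, Wx, Wh, b, reverse: bool):
        x = self._x
        n, t, _ = x.shape
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, self.hidden), dtype=F32)
        order = range(t) if reverse else range(t - 1, -1, -1)
        for ti in order:
            dh = d[:, ti] + dh_next
            prev = ti - 1 if not reverse else ti + 1
            h_prev = (hs[:, prev] if 0 <= prev < t else
                      np.zeros((n, self.hidden), dtype=F32))
            da = dh * (1.0 - hs[:, ti] ** 2)
            Wx.grad += da.T @ x[:, ti]
            Wh.grad += da.T @ h_prev
            b.grad += da.sum(axis=0)
            dx[:, ti] += da @ Wx.value
            dh_next = da @ Wh.value
        return dx

    def backward(self, d):
        h = self.hidden
        dx = self._bptt(d[:, :, :h], self._hf, self.Wx_f, self.Wh_f, self.b_f, False)
        dx += self._bptt(d[:, :, h:], self._hb, self.Wx_b, self.Wh_b, self.b_b, True)
        return dx
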
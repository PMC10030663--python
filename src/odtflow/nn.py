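"""Minimal CPU conv-net framework (numpy + BLAS) with manual backprop.

Supports exactly what the two desk-scale self-supervised models need:
stride-1 'same' 2D/3D convolutions (im2col + matmul), gated convolutions,
ELU/ReLU/sigmoid, 2x average pooling, nearest-neighbor upsampling, channel
concatenation, Adam, and npz (de)serialization.  All parameters are float32;
every source of randomness goes through one ``numpy.random.Generator`` so a
fixed seed reproduces training bit-for-bit on one platform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

SERIALIZATION_VERSION = 1


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


def _windows(x: np.ndarray, k: int, nd: int) -> np.ndarray:
    """Zero-pad (B, C, *S) and return im2col matrix (B*prod(S), C*k^nd)."""
    p = k // 2
    pad = ((0, 0), (0, 0)) + ((p, p),) * nd
    xp = np.pad(x, pad)
    win = sliding_window_view(xp, (k,) * nd, axis=tuple(range(2, 2 + nd)))
    # win: (B, C, *S, *k) -> (B, *S, C, *k) -> (B*P, C*k^nd)
    order = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    win = win.transpose(order)
    B = x.shape[0]
    P = int(np.prod(x.shape[2:]))
    return np.ascontiguousarray(win).reshape(B * P, -1)


class Conv(Layer):
    """Stride-1 'same' convolution, 2D or 3D."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, nd: int = 2):
        self.cin, self.cout, self.k, self.nd = cin, cout, k, nd
        fan_in = cin * k ** nd
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       (cout, cin) + (k,) * nd)
        self.w = Param(w)
        self.b = Param(np.zeros(cout))
        self._cols = None
        self._spatial = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[2:]
        B = x.shape[0]
        cols = _windows(x.astype(np.float32, copy=False), self.k, self.nd)
        self._cols = cols
        wm = self.w.value.reshape(self.cout, -1)
        y = cols @ wm.T + self.b.value
        y = y.reshape((B,) + self._spatial + (self.cout,))
        return np.moveaxis(y, -1, 1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        B = g.shape[0]
        gm = np.moveaxis(g, 1, -1).reshape(-1, self.cout)
        self.w.grad += (gm.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += gm.sum(axis=0)
        # grad wrt input: correlate g with spatially flipped kernels
        wf = self.w.value
        for ax in range(2, 2 + self.nd):
            wf = np.flip(wf, axis=ax)
        wf = np.ascontiguousarray(wf.transpose((1, 0) + tuple(range(2, 2 + self.nd))))
        gcols = _windows(g.astype(np.float32, copy=False), self.k, self.nd)
        dx = gcols @ wf.reshape(self.cin, -1).T
        dx = dx.reshape((B,) + self._spatial + (self.cin,))
        self._cols = None
        return np.moveaxis(dx, -1, 1)


class _Act(Layer):
    pass


class ReLU(_Act):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class LeakyReLU(_Act):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x).astype(np.float32)

    def backward(self, g):
        return (g * np.where(self._mask, 1.0, self.alpha)).astype(np.float32)


class ELU(_Act):
    def forward(self, x):
        self._neg = x <= 0
        self._expm = np.where(self._neg, np.expm1(np.minimum(x, 0.0)), 0.0)
        return np.where(self._neg, self._expm, x).astype(np.float32)

    def backward(self, g):
        return (g * np.where(self._neg, self._expm + 1.0, 1.0)).astype(np.float32)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GatedConv(Layer):
    """phi(feature) * sigmoid(gate): convolution pair with soft gating."""

    def __init__(self, cin, cout, rng, k=3, nd=2):
        self.feat = Conv(cin, cout, rng, k, nd)
        self.gate = Conv(cin, cout, rng, k, nd)
        self.act = ELU()

    def params(self):
        return self.feat.params() + self.gate.params()

    def forward(self, x):
        f = self.act.forward(self.feat.forward(x))
        self._g = sigmoid(self.gate.forward(x))
        self._f = f
        return f * self._g

    def backward(self, g):
        df = g * self._g
        dgate_pre = g * self._f * self._g * (1.0 - self._g)
        dx = self.feat.backward(self.act.backward(df))
        dx += self.gate.backward(dgate_pre.astype(np.float32))
        return dx


class AvgPool(Layer):
    """2x average pooling over all spatial axes."""

    def __init__(self, nd=2):
        self.nd = nd

    def forward(self, x):
        self._shape = x.shape
        B, C = x.shape[:2]
        s = x.shape[2:]
        if self.nd == 2:
            y = x.reshape(B, C, s[0] // 2, 2, s[1] // 2, 2).mean(axis=(3, 5))
        else:
            y = x.reshape(B, C, s[0] // 2, 2, s[1] // 2, 2,
                          s[2] // 2, 2).mean(axis=(3, 5, 7))
        return y.astype(np.float32)

    def backward(self, g):
        rep = g / (2 ** self.nd)
        for ax in range(2, 2 + self.nd):
            rep = np.repeat(rep, 2, axis=ax)
        return rep.astype(np.float32)


class Upsample(Layer):
    """2x nearest-neighbor upsampling over all spatial axes."""

    def __init__(self, nd=2):
        self.nd = nd

    def forward(self, x):
        y = x
        for ax in range(2, 2 + self.nd):
            y = np.repeat(y, 2, axis=ax)
        return y

    def backward(self, g):
        B, C = g.shape[:2]
        s = g.shape[2:]
        if self.nd == 2:
            return g.reshape(B, C, s[0] // 2, 2, s[1] // 2, 2).sum(axis=(3, 5))
        return g.reshape(B, C, s[0] // 2, 2, s[1] // 2, 2,
                         s[2] // 2, 2).sum(axis=(3, 5, 7))


class UNet(Layer):
    """3-level U-shaped encoder-decoder with skip connections.

    ``gated=True`` uses gated convolutions (the inpainting flavour),
    otherwise plain Conv+ReLU (the volumetric enhancer flavour).
    Spatial sizes must be divisible by 4.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 nd: int = 2, base: int = 8, gated: bool = False):
        self.nd = nd

        def block(ci, co):
            if gated:
                return GatedConv(ci, co, rng, nd=nd)
            return _ConvAct(ci, co, rng, nd=nd)

        self.e1 = block(cin, base)
        self.p1 = AvgPool(nd)
        self.e2 = block(base, 2 * base)
        self.p2 = AvgPool(nd)
        self.mid = block(2 * base, 2 * base)
        self.u2 = Upsample(nd)
        self.d2 = block(4 * base, 2 * base)
        self.u1 = Upsample(nd)
        self.d1 = block(3 * base, base)
        self.out = Conv(base, cout, rng, k=3, nd=nd)

    def params(self):
        ps = []
        for lyr in (self.e1, self.e2, self.mid, self.d2, self.d1, self.out):
            ps += lyr.params()
        return ps

    def forward(self, x):
        f1 = self.e1.forward(x)
        f2 = self.e2.forward(self.p1.forward(f1))
        m = self.mid.forward(self.p2.forward(f2))
        u2 = self.u2.forward(m)
        d2 = self.d2.forward(np.concatenate([u2, f2], axis=1))
        u1 = self.u1.forward(d2)
        d1 = self.d1.forward(np.concatenate([u1, f1], axis=1))
        self._ch = (u2.shape[1], f2.shape[1], u1.shape[1], f1.shape[1])
        return self.out.forward(d1)

    def backward(self, g):
        c_u2, c_f2, c_u1, c_f1 = self._ch
        g = self.out.backward(g)
        g = self.d1.backward(g)
        g_u1, g_f1 = g[:, :c_u1], g[:, c_u1:]
        g = self.u1.backward(g_u1)
        g = self.d2.backward(g)
        g_u2, g_f2 = g[:, :c_u2], g[:, c_u2:]
        g = self.u2.backward(g_u2)
        g = self.p2.backward(self.mid.backward(g))
        g = self.e2.backward(g + g_f2)
        g = self.p1.backward(g)
        g = self.e1.backward(g + g_f1)
        return g


class _ConvAct(Layer):
    """Conv + leaky ReLU.  The leak keeps gradients alive in very small
    nets trained for few iterations, where plain ReLU units die
    irrecoverably and the net collapses to a constant."""

    def __init__(self, cin, cout, rng, nd=2):
        self.conv = Conv(cin, cout, rng, nd=nd)
        self.act = LeakyReLU(0.1)

    def params(self):
        return self.conv.params()

    def forward(self, x):
        return self.act.forward(self.conv.forward(x))

    def backward(self, g):
        return self.conv.backward(self.act.backward(g))


class Adam:
    """Adam with global-norm gradient clipping and an optional externally
    driven learning rate (set ``lr`` before each step for schedules)."""

    def __init__(self, params: list[Param], lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 1.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.clip_norm = clip_norm
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        if self.clip_norm is not None:
            total = math.sqrt(sum(float(np.sum(p.grad ** 2))
                                  for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    p.grad *= scale
        b1, b2 = self.betas
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m[...] = b1 * p.m + (1 - b1) * p.grad
            p.v[...] = b2 * p.v + (1 - b2) * p.grad ** 2
            p.value -= (self.lr * (p.m / bias1)
                        / (np.sqrt(p.v / bias2) + self.eps))


# ---------------------------------------------------------------------------
# Serialization

def save_model(stem, net: Layer, manifest: dict) -> None:
    """Write ``<stem>.npz`` (parameters) and ``<stem>.json`` (version header
    plus training manifest)."""
    stem = str(stem)
    arrays = {f"p{i}": p.value for i, p in enumerate(net.params())}
    with open(stem + ".npz", "wb") as fh:
        np.savez(fh, **arrays)
    head = {"format": "odtflow-model", "version": SERIALIZATION_VERSION}
    with open(stem + ".json", "w") as fh:
        json.dump({**head, "manifest": manifest}, fh, indent=1)


def load_model(stem, net: Layer) -> dict:
    """Load ``<stem>.npz`` into ``net`` (architecture must match); returns
    the training manifest."""
    stem = str(stem)
    with np.load(stem + ".npz") as data:
        for i, p in enumerate(net.params()):
            val = data[f"p{i}"]
            if val.shape != p.value.shape:
                raise ValueError("architecture mismatch while loading model")
            p.value[...] = val
    with open(stem + ".json") as fh:
        obj = json.load(fh)
    if obj.get("format") != "odtflow-model":
        raise ValueError("not an odtflow model file")
    return obj["manifest"]
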
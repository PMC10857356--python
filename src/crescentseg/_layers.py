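"""Minimal CPU neural-network layers with hand-written backward passes.

Everything operates on float32 arrays shaped (batch, channels, rows, cols).
Each layer caches what its backward pass needs on the instance, so one
layer object serves exactly one position in the network graph.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv2d:
    """k x k convolution, stride 1, 'same' padding for odd k (im2col)."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, ksize
        self.pad = ksize // 2
        scale = np.sqrt(2.0 / (cin * ksize * ksize))  # He init for relu nets
        self.W = Param((rng.standard_normal((cout, cin * ksize * ksize)) * scale).astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B * H * W, C * k * k)
        out = cols @ self.W.value.T + self.b.value
        self._cols = cols
        self._xshape = x.shape
        return out.reshape(B, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._xshape
        k, p = self.k, self.pad
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.grad += dyf.T @ self._cols
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value).reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling; ties share the gradient equally (deterministic)."""

    def forward(self, x):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        sel = xr == out[:, :, :, None, :, None]
        self._sel = sel / sel.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, dy):
        B, C, H, W = self._shape
        d = dy[:, :, :, None, :, None] * self._sel
        return d.reshape(B, C, H, W)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class DoubleConv:
    """conv3x3 -> relu -> conv3x3 -> relu."""

    def __init__(self, cin, cout, rng):
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(cout, cout, 3, rng)
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float, weight_decay: float = 0.0):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad + weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
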
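"""Minimal NumPy neural-network engine with reverse-mode gradients.

Implements exactly the layers the model needs — 3-D convolution (stride 1,
extent-preserving padding), batch normalisation, ReLU, ceil-mode max-pooling,
dense layers — plus an Adam optimiser with optional decoupled L2 weight decay.
All gradients are hand-derived and checked against central finite differences
in the test-suite.

Conventions: activations are float32 arrays of shape ``(N, C, D, H, W)`` for
volumetric layers and ``(N, F)`` for dense layers.  Each layer caches what its
backward pass needs during ``forward(training=True)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator.

    ``decay`` marks the parameter as subject to L2 weight decay (weights yes,
    biases and batch-norm scales no).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = False, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3-D convolution, stride 1, symmetric zero padding ``(k-1)//2``.

    Only odd kernels (extent-preserving) are supported; the backbone uses
    kernel 3 throughout.  Forward builds an im2col matrix once (BLAS matmul);
    the matrix is cached so the weight gradient reuses it, and the input
    gradient is a col2im scatter-add over the k^3 kernel offsets.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("Conv3d supports odd kernels only (extent-preserving)")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel, kernel, kernel))
        self.w = Param(w, decay=True, name="conv.w")
        self.b = Param(np.zeros(out_channels), name="conv.b")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        self._col: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def _offsets(self):
        k = self.kernel
        return [(dz, dy, dx) for dz in range(k) for dy in range(k) for dx in range(k)]

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, cin, d, h, w = x.shape
        p = self.pad
        # channels-last padded copy: every spatial slab below is a cheap
        # chunked memcpy and every GEMM runs over a contiguous (voxels, Cin)
        xcl = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))
        xp = np.pad(xcl, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        wo = np.ascontiguousarray(self.w.value.transpose(2, 3, 4, 1, 0))  # (k,k,k,Cin,Cout)
        ndhw = n * d * h * w
        acc = np.broadcast_to(self.b.value, (ndhw, self.out_channels)).copy()
        tmp = np.empty((ndhw, self.out_channels), dtype=DTYPE)
        for dz, dy, dx in self._offsets():
            slab = np.ascontiguousarray(
                xp[:, dz:dz + d, dy:dy + h, dx:dx + w, :]).reshape(ndhw, cin)
            np.matmul(slab, wo[dz, dy, dx], out=tmp)
            acc += tmp
        if training:
            self._xp, self._shape = xp, (n, cin, d, h, w)
        out = acc.reshape(n, d, h, w, self.out_channels)
        return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def backward(self, gout):
        n, cin, d, h, w = self._shape
        k, p = self.kernel, self.pad
        xp = self._xp
        ndhw = n * d * h * w
        g2 = np.ascontiguousarray(gout.transpose(0, 2, 3, 4, 1),
                                  dtype=DTYPE).reshape(ndhw, self.out_channels)
        wo = np.ascontiguousarray(self.w.value.transpose(2, 3, 4, 1, 0))
        gwo = np.zeros_like(wo)
        gxp = np.zeros_like(xp)
        tmp = np.empty((ndhw, cin), dtype=DTYPE)
        for dz, dy, dx in self._offsets():
            slab = np.ascontiguousarray(
                xp[:, dz:dz + d, dy:dy + h, dx:dx + w, :]).reshape(ndhw, cin)
            gwo[dz, dy, dx] += slab.T @ g2
            np.matmul(g2, wo[dz, dy, dx].T, out=tmp)
            gxp[:, dz:dz + d, dy:dy + h, dx:dx + w, :] += tmp.reshape(n, d, h, w, cin)
        self.w.grad += gwo.transpose(4, 3, 0, 1, 2)
        self.b.grad += g2.sum(axis=0)
        self._xp = self._shape = None
        gx = gxp[:, p:p + d, p:p + h, p:p + w, :] if p else gxp
        return np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3))


class BatchNorm3d(Layer):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises with batch statistics and updates the running
    mean/variance with the given momentum; inference mode uses the running
    statistics, so repeated inference passes are deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), name="bn.gamma")
        self.beta = Param(np.zeros(channels), name="bn.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes, dtype=np.float64)
            var = x.var(axis=axes, dtype=np.float64)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        mean = mean.astype(DTYPE)
        xhat = (x - mean[None, :, None, None, None]) * invstd[None, :, None, None, None]
        out = self.gamma.value[None, :, None, None, None] * xhat + self.beta.value[None, :, None, None, None]
        if training:
            self._cache = (xhat, invstd)
        return out.astype(DTYPE)

    def backward(self, gout):
        xhat, invstd = self._cache
        axes = (0, 2, 3, 4)
        n = gout.size // gout.shape[1]
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        s1 = gout.sum(axis=axes)[None, :, None, None, None]
        s2 = (gout * xhat).sum(axis=axes)[None, :, None, None, None]
        gx = (g * invstd[None, :, None, None, None] / n) * (n * gout - s1 - xhat * s2)
        self._cache = None
        return gx.astype(DTYPE)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        out = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, gout):
        gx = gout * self._mask
        self._mask = None
        return gx


class PadMaxPool3d(Layer):
    """Ceil-mode max-pooling: odd extents are padded (high side, -inf) so the
    output extent is ``ceil(extent / stride)``.  Kernel equals stride."""

    def __init__(self, kernel: int = 2):
        self.k = kernel
        self._cache = None

    @staticmethod
    def out_extent(extent: int, stride: int) -> int:
        return -(-extent // stride)

    def forward(self, x, training=False):
        k = self.k
        nb, c, d, h, w = x.shape
        d2, h2, w2 = (self.out_extent(e, k) for e in (d, h, w))
        pads = (d2 * k - d, h2 * k - h, w2 * k - w)
        xp = np.pad(x, ((0, 0), (0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2])),
                    constant_values=-np.inf)
        xr = xp.reshape(nb, c, d2, k, h2, k, w2, k).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        xr = np.ascontiguousarray(xr).reshape(nb, c, d2, h2, w2, k ** 3)
        idx = np.argmax(xr, axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape, pads)
        return np.ascontiguousarray(out, dtype=DTYPE)

    def backward(self, gout):
        idx, in_shape, pads = self._cache
        k = self.k
        nb, c, d, h, w = in_shape
        d2, h2, w2 = gout.shape[2:]
        gxr = np.zeros((nb, c, d2, h2, w2, k ** 3), dtype=DTYPE)
        np.put_along_axis(gxr, idx[..., None], gout[..., None], axis=-1)
        gxp = gxr.reshape(nb, c, d2, h2, w2, k, k, k).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gxp = np.ascontiguousarray(gxp).reshape(nb, c, d2 * k, h2 * k, w2 * k)
        self._cache = None
        return gxp[:, :, :d, :h, :w]


class Flatten(Layer):
    """Channel-major flatten: element (c, z, y, x) lands at
    ``((c*D + z)*H + y)*W + x`` (C-order ravel)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Linear(Layer):
    """Dense layer ``y = x @ W + b`` with W of shape (n_in, n_out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 init: str = "he"):
        rng = rng or np.random.default_rng()
        if init == "he":
            std = np.sqrt(2.0 / n_in)
        elif init == "xavier":
            std = np.sqrt(2.0 / (n_in + n_out))
        elif init == "zeros":
            std = 0.0
        else:
            raise ValueError(f"unknown init {init!r}")
        w = rng.normal(0.0, std, size=(n_in, n_out)) if std > 0 else np.zeros((n_in, n_out))
        self.w = Param(w, decay=True, name="linear.w")
        self.b = Param(np.zeros(n_out), name="linear.b")
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if training:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gout):
        gout = np.ascontiguousarray(gout, dtype=DTYPE)
        self.w.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        gx = gout @ self.w.value.T
        self._x = None
        return gx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training=training)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam with the usual bias correction; L2 decay is added to the gradient
    of parameters flagged ``decay`` before the moment update."""

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0
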
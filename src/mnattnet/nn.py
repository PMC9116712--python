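"""Minimal numpy neural-network layers with hand-written backpropagation.

All tensors are float32 in NCHW layout. Convolutions run as im2col + BLAS
matmul; each layer caches what its backward pass needs, so the usage pattern
is strictly forward-then-backward per batch. Parameters are plain numpy
arrays exposed through ``parameters()`` as (name, value, gradient) triples
that the :class:`SGD` optimizer updates in place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "Conv1x1",
    "ReLU",
    "MaxPool2d",
    "BilinearUpsample",
    "GlobalAvgPool",
    "Linear",
    "Sigmoid",
    "SGD",
    "he_init",
    "interp_matrix",
    "softmax",
]


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Kaiming-normal initialization for ReLU stacks."""
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base class; layers without parameters inherit the empty default."""

    def parameters(self):
        return []

    def zero_grad(self) -> None:
        for _, _, g in self.parameters():
            g[...] = 0.0


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold NCHW input into (N*Ho*Wo, C*k*k) patch rows."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = he_init(rng, (c_out, c_in, kernel, kernel), fan_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        n = x.shape[0]
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.W.reshape(self.c_out, -1)
        y = cols @ wmat.T
        y += self.b
        y = y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape, ho, wo, need_input_grad)
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray | None:
        cols, x_shape, ho, wo, need_input_grad = self._cache
        n, c, h, w = x_shape
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.gW += (g2.T @ cols).reshape(self.W.shape)
        self.gb += g2.sum(axis=0)
        if not need_input_grad:
            return None
        gcols = (g2 @ self.W.reshape(self.c_out, -1)).reshape(
            n, ho, wo, c, self.k, self.k).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcols[:, :, :, :, i, j]
        if self.pad:
            gx = gx[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return np.ascontiguousarray(gx)


class Conv1x1(Layer):
    """Pointwise convolution: a per-pixel linear map over channels."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        self.c_in, self.c_out = c_in, c_out
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = he_init(rng, (c_out, c_in), c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def parameters(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.tensordot(self.W, x, axes=([1], [1])).transpose(1, 0, 2, 3)
        return y + self.b[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        self.gW += np.tensordot(gy, x, axes=([0, 2, 3], [0, 2, 3]))
        self.gb += gy.sum(axis=(0, 2, 3))
        return np.tensordot(self.W.T, gy, axes=([1], [1])).transpose(1, 0, 2, 3)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, np.float32(0.0))


class MaxPool2d(Layer):
    """Overlapping max pooling (AlexNet uses kernel 3, stride 2)."""

    def __init__(self, kernel: int = 3, stride: int = 2):
        self.k, self.stride = kernel, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        flat = win.reshape(*win.shape[:4], k * k)
        self._argmax = flat.argmax(axis=-1)
        self._x_shape = x.shape
        return np.ascontiguousarray(flat.max(axis=-1))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        k, s = self.k, self.stride
        ho, wo = gy.shape[2], gy.shape[3]
        gx = np.zeros((n, c, h, w), dtype=np.float32)
        for pos in range(k * k):
            i, j = divmod(pos, k)
            sel = self._argmax == pos
            if not sel.any():
                continue
            gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += np.where(sel, gy, np.float32(0.0))
        return gx


def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix, half-pixel-centers convention.

    Output sample i reads source coordinate (i + 0.5) * n_in / n_out - 0.5,
    clamped to the valid range (the convention used by image libraries when
    align_corners is off). Returned shape is (n_out, n_in).
    """
    a = np.zeros((n_out, n_in), dtype=np.float32)
    for i in range(n_out):
        srcf = (i + 0.5) * n_in / n_out - 0.5
        srcf = min(max(srcf, 0.0), n_in - 1.0)
        lo = int(np.floor(srcf))
        hi = min(lo + 1, n_in - 1)
        t = srcf - lo
        a[i, lo] += 1.0 - t
        a[i, hi] += t
    return a


class BilinearUpsample(Layer):
    """Separable bilinear resampling as two fixed matrix products.

    y = R x C^T per channel, so the backward pass is the exact transpose
    R^T g C — no approximation, and the same matrices serve as the oracle
    convention everywhere in the package.
    """

    def __init__(self, in_hw: tuple[int, int], out_hw: tuple[int, int]):
        self.R = interp_matrix(in_hw[0], out_hw[0])
        self.C = interp_matrix(in_hw[1], out_hw[1])

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.einsum("oi,ncij->ncoj", self.R, x, optimize=True)
        return np.einsum("pj,ncoj->ncop", self.C, y, optimize=True)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = np.einsum("pj,ncop->ncoj", self.C, gy, optimize=True)
        return np.einsum("oi,ncoj->ncij", self.R, g, optimize=True)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            (gy / self._hw)[:, :, None, None], (n, c, h, w)).astype(np.float32)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = he_init(rng, (n_out, n_in), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gW += gy.T @ self._x
        self.gb += gy.sum(axis=0)
        return gy @ self.W


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # piecewise-stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._y = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._y * (1.0 - self._y)


class FeatureNorm(Layer):
    """Parameter-free standardization of a feature vector (batch-norm style,
    no affine terms — any scale/shift is absorbed by the affine layer that
    follows, so the function class is unchanged).

    Training mode standardizes by batch statistics and backpropagates
    through them, which projects the common-mode (DC) component out of the
    upstream gradient; evaluation uses running statistics, making inference
    a fixed affine map.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        y = (x - mean) / std
        self._cache = (y.astype(np.float32), std.astype(np.float32),
                       train and x.shape[0] > 1)
        return self._cache[0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        y, std, batch_stats = self._cache
        if not batch_stats:
            return gy / std
        return (gy - gy.mean(axis=0) - y * (gy * y).mean(axis=0)) / std

    def set_stats(self, mean: np.ndarray, var: np.ndarray) -> None:
        """Overwrite the running statistics (post-epoch recalibration)."""
        self.running_mean = mean.astype(np.float32)
        self.running_var = var.astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params, momentum: float = 0.9, weight_decay: float = 5e-4,
                 clip_norm: float | None = 1.0, nesterov: bool = True):
        # params: list of (name, value, grad) triples from the model
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.nesterov = nesterov
        self.velocity = [np.zeros_like(v) for _, v, _ in params]

    def step(self, lr: float) -> float:
        """Apply one update; returns the pre-clip global gradient norm."""
        sq = 0.0
        for _, _, g in self.params:
            sq += float(np.vdot(g, g))
        gnorm = float(np.sqrt(sq))
        scale = 1.0
        if self.clip_norm is not None and gnorm > self.clip_norm > 0:
            scale = self.clip_norm / (gnorm + 1e-12)
        for vel, (name, value, grad) in zip(self.velocity, self.params):
            g = grad * scale
            if self.weight_decay and not name.endswith("b"):
                g = g + self.weight_decay * value
            vel *= self.momentum
            vel -= lr * g
            if self.nesterov:
                value += self.momentum * vel - lr * g
            else:
                value += vel
        return gnorm

    def zero_grad(self) -> None:
        for _, _, g in self.params:
            g[...] = 0.0
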
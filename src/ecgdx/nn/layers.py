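"""Minimal numpy layer zoo with manual backpropagation.

Activations are channels-last ``(batch, length, channels)`` float32
throughout — with this layout the im2col matrix, the convolution output
and the backward scatter are all naturally contiguous, so every layer
reduces to BLAS matmuls plus elementwise work with no transposes.
Only what the residual network needs is implemented.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _same_pad(length: int, k: int, stride: int) -> tuple[int, int, int]:
    """'Same' padding: output length = ceil(L / stride)."""
    out_len = -(-length // stride)
    total = max((out_len - 1) * stride + k - length, 0)
    return out_len, total // 2, total - total // 2


def _im2col(xp: np.ndarray, k: int, stride: int, out_len: int) -> np.ndarray:
    """(B, Lp, C) -> contiguous (B*out_len, k*C) column matrix."""
    b, _, c = xp.shape
    sb, sl, sc = xp.strides
    patches = as_strided(
        xp, shape=(b, out_len, k, c), strides=(sb, stride * sl, sl, sc)
    )
    return np.ascontiguousarray(patches).reshape(b * out_len, k * c)


class Conv1d(Layer):
    """1-D convolution, 'same' zero padding, optional stride.

    Weights use He initialization (normal with std sqrt(2 / (C_in * k)));
    biases start at zero.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (c_in * k))
        self.w = Param(rng.normal(0.0, std, size=(c_out, k * c_in)), f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.name = name
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, length, c = x.shape
        out_len, padl, padr = _same_pad(length, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (padl, padr), (0, 0)))
        cols = _im2col(xp, self.k, self.stride, out_len)
        out = cols @ self.w.value.T
        out += self.b.value
        if training:
            self._cols = cols
            self._shape = (b, length, out_len, padl, xp.shape[1])
        return out.reshape(b, out_len, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._shape is not None
        b, length, out_len, padl, lp = self._shape
        g = grad.reshape(b * out_len, self.c_out)
        self.w.grad += g.T @ self._cols
        self.b.grad += g.sum(axis=0)
        dcols = (g @ self.w.value).reshape(b, out_len, self.k, self.c_in)
        dxp = np.zeros((b, lp, self.c_in), dtype=np.float32)
        # 'Same' padding guarantees t + stride*(out_len-1) < padded length.
        for t in range(self.k):
            dxp[:, t : t + self.stride * out_len : self.stride, :] += dcols[:, :, t, :]
        self._cols = None
        return dxp[:, padl : padl + length, :]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps, self.name = momentum, eps, name
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean.astype(np.float32)) * invstd
        if training:
            self._cache = (xhat, invstd, x.shape[0] * x.shape[1])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, invstd, n = self._cache
        dgamma = (grad * xhat).sum(axis=(0, 1))
        dbeta = grad.sum(axis=(0, 1))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        coeff = self.gamma.value * invstd / np.float32(n)
        dx = coeff * (n * grad - dbeta - xhat * dgamma)
        self._cache = None
        return dx.astype(np.float32, copy=False)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        out = grad * self._mask
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout; ``rate`` is the probability of zeroing a unit."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = np.float32(1.0 - self.rate)
        self._mask = (
            self.rng.random(x.shape, dtype=np.float32) < keep
        ).astype(np.float32)
        self._mask /= keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool1d(Layer):
    """Non-overlapping max pooling; length must divide the pool size."""

    def __init__(self, k: int) -> None:
        self.k = k
        self._argmax: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, length, c = x.shape
        if length % self.k:
            raise ValueError(f"length {length} not divisible by pool {self.k}")
        xr = x.reshape(b, length // self.k, self.k, c)
        if training:
            self._argmax = xr.argmax(axis=2)
            self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._argmax is not None and self._shape is not None
        b, length, c = self._shape
        out = np.zeros((b, length // self.k, self.k, c), dtype=np.float32)
        np.put_along_axis(out, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        self._argmax = None
        return out.reshape(b, length, c)


class Dense(Layer):
    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator | None = None, name: str = "dense"
    ) -> None:
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, std, size=(n_out, n_in)), f"{name}.w")
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        out = grad @ self.w.value
        self._x = None
        return out


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
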
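"""NumPy building blocks for 3D convolutional networks with manual backprop.

Each layer caches whatever its backward pass needs during ``forward`` and
returns the input gradient from ``backward`` while accumulating parameter
gradients in place. Multichannel convolutions are evaluated by
shift-and-accumulate (one BLAS matmul per kernel offset over contiguous
spatial slabs); large single-channel kernels go through FFT convolution.

Array layout is (N, C, L, W, H) throughout — batch, channels, then the three
spatial axes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Kaiming-normal initialisation: N(0, sqrt(2 / fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


# ---------------------------------------------------------------------------
# 3D convolution primitives
#
# Multichannel kernels use shift-and-accumulate: one (Cout, Cin) matmul per
# kernel offset over contiguous spatial slabs, which beats an unfolded
# im2col matrix on both memory traffic and cache behaviour. Single-channel
# kernels of size >= 5 (the spatial-attention 7x7x7 convs) go through FFT
# convolution instead.
# ---------------------------------------------------------------------------

def _conv3d_fft_single(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    from scipy.signal import fftconvolve

    n_batch = x.shape[0]
    k = w.shape[2]
    kernel = w[0, 0, ::-1, ::-1, ::-1]
    start = k - 1 - pad
    Lo = [s + 2 * pad - k + 1 for s in x.shape[2:]]
    out = np.empty((n_batch, 1, *Lo), dtype=np.result_type(x, w))
    for n in range(n_batch):
        full = fftconvolve(x[n, 0], kernel, mode="full")
        out[n, 0] = full[
            start : start + Lo[0], start : start + Lo[1], start : start + Lo[2]
        ]
    return out


def _conv3d_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Cross-correlate (N,Cin,L,W,H) with (Cout,Cin,k,k,k); stride 1."""
    n_batch, c_in, L, W, H = x.shape
    c_out, _, k, _, _ = w.shape
    if c_in == 1 and c_out == 1 and k >= 5:
        return _conv3d_fft_single(x, w, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Lo, Wo, Ho = L + 2 * pad - k + 1, W + 2 * pad - k + 1, H + 2 * pad - k + 1
    out = np.zeros((n_batch, c_out, Lo, Wo, Ho), dtype=np.result_type(x, w))
    yf = out.reshape(n_batch, c_out, -1)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                xs = np.ascontiguousarray(xp[:, :, a : a + Lo, b : b + Wo, c : c + Ho])
                xs = xs.reshape(n_batch, c_in, -1)
                wk = w[:, :, a, b, c]
                for n in range(n_batch):
                    yf[n] += wk @ xs[n]
    return out


def _conv3d_weight_grad(x: np.ndarray, dy: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Gradient of _conv3d_raw w.r.t. the kernel."""
    n_batch, c_in = x.shape[:2]
    c_out = dy.shape[1]
    if c_in == 1 and c_out == 1 and k >= 5:
        from scipy.signal import fftconvolve

        dw = np.zeros((k, k, k), dtype=np.result_type(x, dy))
        for n in range(n_batch):
            xpn = np.pad(x[n, 0], pad)
            dw += fftconvolve(xpn, dy[n, 0][::-1, ::-1, ::-1], mode="valid")
        return dw.reshape(1, 1, k, k, k)
    Lo, Wo, Ho = dy.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    dw = np.zeros((c_out, c_in, k, k, k), dtype=np.result_type(x, dy))
    dyf = np.ascontiguousarray(dy).reshape(n_batch, c_out, -1)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                xs = np.ascontiguousarray(xp[:, :, a : a + Lo, b : b + Wo, c : c + Ho])
                xs = xs.reshape(n_batch, c_in, -1)
                acc = dw[:, :, a, b, c]
                for n in range(n_batch):
                    acc += dyf[n] @ xs[n].T
    return dw


class Conv3d(Layer):
    """3D convolution, stride 1, symmetric zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        pad: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = c_in * kernel**3
        self.w = Param(he_normal(rng, (c_out, c_in, kernel, kernel, kernel), fan_in), "conv3d.w")
        self.b = Param(np.zeros(c_out, dtype=np.float32), "conv3d.b") if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        y = _conv3d_raw(x, self.w.value, self.pad)
        if self.b is not None:
            y += self.b.value.reshape(1, -1, 1, 1, 1)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "forward(training=True) must precede backward"
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        self.w.grad += _conv3d_weight_grad(x, dy, self.kernel, self.pad)
        w_flip = self.w.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        dxp = _conv3d_raw(dy, w_flip, self.kernel - 1)
        p = self.pad
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return np.ascontiguousarray(dxp)


class ConvTranspose3d(Layer):
    """Transpose convolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(he_normal(rng, (c_in, c_out, 2, 2, 2), c_in * 8), "upconv.w")
        self.b = Param(np.zeros(c_out, dtype=np.float32), "upconv.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        n, _, L, W, H = x.shape
        y = np.einsum("ncijk,coabd->noiajbkd", x, self.w.value, optimize=True)
        y = y.reshape(n, self.c_out, 2 * L, 2 * W, 2 * H)
        y += self.b.value.reshape(1, -1, 1, 1, 1)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        n, c_out, L2, W2, H2 = dy.shape
        dyb = dy.reshape(n, c_out, L2 // 2, 2, W2 // 2, 2, H2 // 2, 2)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        self.w.grad += np.einsum("ncijk,noiajbkd->coabd", x, dyb, optimize=True)
        return np.einsum("noiajbkd,coabd->ncijk", dyb, self.w.value, optimize=True)


class Conv1d(Layer):
    """Single-channel 1D convolution over a (N, length) sequence."""

    def __init__(self, kernel: int, rng: np.random.Generator | None = None) -> None:
        if kernel % 2 == 0:
            raise ValueError(f"1D attention kernel must be odd, got {kernel}")
        rng = rng or np.random.default_rng()
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        self.w = Param(he_normal(rng, (kernel,), kernel), "conv1d.w")
        self.b = Param(np.zeros(1, dtype=np.float32), "conv1d.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        xp = np.pad(x, ((0, 0), (self.pad, self.pad)))
        win = sliding_window_view(xp, self.kernel, axis=1)
        return win @ self.w.value + self.b.value[0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        xp = np.pad(x, ((0, 0), (self.pad, self.pad)))
        win = sliding_window_view(xp, self.kernel, axis=1)
        self.w.grad += np.einsum("nl,nlk->k", dy, win)
        self.b.grad += dy.sum(keepdims=True).reshape(1)
        dyp = np.pad(dy, ((0, 0), (self.kernel - 1 - self.pad,) * 2))
        dwin = sliding_window_view(dyp, self.kernel, axis=1)
        return dwin @ self.w.value[::-1]


class BatchNorm3d(Layer):
    """Per-channel batch normalisation over (N, L, W, H)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels, dtype=np.float32), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(shape)) * inv_std.reshape(shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shape) * inv_std.reshape(shape)
        mean_dy = dy.mean(axis=axes).reshape(shape)
        mean_dy_xhat = (dy * xhat).sum(axis=axes).reshape(shape) / m
        return g * (dy - mean_dy - xhat * mean_dy_xhat)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return dy * self._mask


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        y = sigmoid(x)
        if training:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._y is not None
        return dy * self._y * (1.0 - self._y)


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2; spatial dims must be even."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, L, W, H = x.shape
        if L % 2 or W % 2 or H % 2:
            raise ValueError(f"max-pool requires even spatial dims, got {(L, W, H)}")
        xr = (
            x.reshape(n, c, L // 2, 2, W // 2, 2, H // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, L // 2, W // 2, H // 2, 8)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        idx, (n, c, L, W, H) = self._cache
        dxr = np.zeros((n, c, L // 2, W // 2, H // 2, 8), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        return (
            dxr.reshape(n, c, L // 2, W // 2, H // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, L, W, H)
        )


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def global_average_pool(f: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean: (N, C, L, W, H) -> (N, C)."""
    return f.mean(axis=(2, 3, 4))
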
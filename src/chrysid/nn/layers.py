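"""Minimal NumPy layers with manual backpropagation.

Convolutions use im2col/col2im built from 9 (or k^2) strided-slice copies,
which keeps both directions as large GEMMs.  Arrays are float32 NCHW.
Each layer owns ``params`` and matching ``grads`` dicts; ``forward`` caches
what ``backward`` needs, so a layer instance is not re-entrant within one
forward/backward pair (fine for a sequential trainer).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d",
           "GlobalAvgPool", "Linear", "Add"]


class Layer:
    """Base class: parameterless identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _out_size(h: int, k: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*OH*OW, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    # written directly in GEMM layout to avoid a second full-size copy
    cols = np.empty((n, oh, ow, c, k, k), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, :, i, j] = xp[:, :, i:i + stride * oh:stride,
                                        j:j + stride * ow:stride].transpose(0, 2, 3, 1)
    return cols.reshape(n * oh * ow, c * k * k)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of im2col (scatter-add of patch gradients)."""
    n, c, h, w = x_shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    cols = cols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


class Conv2d(Layer):
    """k x k convolution, no bias (batch norm follows in residual blocks)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: int | None = None) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k // 2) if pad is None else pad
        self.params["W"] = np.zeros((out_ch, in_ch, k, k), dtype=np.float32)
        self.zero_grads()

    @property
    def fan_in(self) -> int:
        return self.in_ch * self.k * self.k

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, _, h, w = x.shape
        oh, ow = _out_size(h, self.k, self.stride, self.pad), _out_size(w, self.k, self.stride, self.pad)
        cols = im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.params["W"].reshape(self.out_ch, -1).T
        self._cache = (cols, x.shape) if training else (None, x.shape)
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, oc, oh, ow = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, oc)
        self.grads["W"] += (dmat.T @ cols).reshape(self.params["W"].shape)
        dcols = dmat @ self.params["W"].reshape(oc, -1)
        return col2im(dcols, x_shape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(ch, dtype=np.float32)
        self.params["beta"] = np.zeros(ch, dtype=np.float32)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        # standard batchnorm backward, fused over (N, H, W)
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mask = x > 0
        if training:
            self._cache = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._cache


class MaxPool2d(Layer):
    """k x k max pooling (used only by the full-size stem)."""

    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1) -> None:
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = _out_size(h, self.k, self.stride, self.pad), _out_size(w, self.k, self.stride, self.pad)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                    constant_values=-np.inf)
        cols = np.empty((n, c, self.k * self.k, oh, ow), dtype=x.dtype)
        idx = 0
        for i in range(self.k):
            for j in range(self.k):
                cols[:, :, idx] = xp[:, :, i:i + self.stride * oh:self.stride,
                                     j:j + self.stride * ow:self.stride]
                idx += 1
        arg = cols.argmax(axis=2)
        out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]
        if training:
            self._cache = (arg, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, x_shape = self._cache
        n, c, h, w = x_shape
        oh, ow = dout.shape[2], dout.shape[3]
        cols = np.zeros((n, c, self.k * self.k, oh, ow), dtype=dout.dtype)
        np.put_along_axis(cols, arg[:, :, None], dout[:, :, None], axis=2)
        xp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=dout.dtype)
        idx = 0
        for i in range(self.k):
            for j in range(self.k):
                xp[:, :, i:i + self.stride * oh:self.stride,
                   j:j + self.stride * ow:self.stride] += cols[:, :, idx]
                idx += 1
        return xp[:, :, self.pad:self.pad + h, self.pad:self.pad + w]


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C): the flatten feature of the backbone."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._cache
        return np.broadcast_to(dout[:, :, None, None] / (h * w), (n, c, h, w)).astype(dout.dtype)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int) -> None:
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.params["W"] = np.zeros((out_f, in_f), dtype=np.float32)
        self.params["b"] = np.zeros(out_f, dtype=np.float32)
        self.zero_grads()

    @property
    def fan_in(self) -> int:
        return self.in_f

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._cache = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] += dout.T @ x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]
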
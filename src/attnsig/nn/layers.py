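"""Layer primitives with explicit forward/backward passes.

All tensors are float32 NCHW. Each layer caches what its backward pass
needs on ``forward`` and releases it on ``backward``; layers are therefore
not re-entrant, which is fine for the sequential training loop used here.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    """Base class: parameter discovery and train/eval mode switching."""

    def __init__(self) -> None:
        self.training = False

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (N,C,H,W) into (N, C*k*k, oh*ow) patch columns."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow, _, _ = v.shape
    cols = v.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int,
           oh: int, ow: int) -> np.ndarray:
    """Scatter-add patch columns back onto the (padded) input grid."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:hp - pad, pad:wp - pad]
    return dx


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        super().__init__()
        if pad is None:
            pad = k // 2
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(c_out), f"{name}.bias")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, oh, ow = im2col(x, self.k, self.stride, self.pad)
        out = np.matmul(self.weight.value, cols) + self.bias.value[:, None]
        self._cache = (cols, x.shape, oh, ow)
        return out.reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, oh, ow = self._cache
        self._cache = None
        n = dy.shape[0]
        dyf = dy.reshape(n, self.c_out, oh * ow)
        self.weight.grad += np.einsum("nop,nkp->ok", dyf, cols, optimize=True)
        self.bias.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.value.T, dyf)
        return col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn") -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        self._cache = (xhat, invstd)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[:, None, None]
        if not self.training:
            return dy * g * invstd[:, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return term * invstd[:, None, None]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return dy * mask


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = self._out
        self._out = None
        return dy * out * (1.0 - out)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, name: str = "fc") -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(n_out), f"{name}.bias")
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Dropout(Module):
    """Inverted dropout; active only in training mode. Draws from the
    generator attached via ``rng`` (shared across the network)."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator = np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        mask = self._mask
        self._mask = None
        return dy * mask


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def bilinear_matrices(h_in: int, w_in: int, h_out: int, w_out: int):
    """Separable corner-aligned bilinear interpolation matrices.

    Returns (R, C) with R (h_out, h_in) and C (w_out, w_in) so that the
    upsampled image is R @ X @ C.T. Corner-aligned: output corners hit
    input corners exactly.
    """
    def axis_weights(n_in: int, n_out: int) -> np.ndarray:
        m = np.zeros((n_out, n_in), dtype=DTYPE)
        if n_in == 1 or n_out == 1:
            src = np.zeros(n_out)
        else:
            src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        frac = src - i0
        for j in range(n_out):
            m[j, i0[j]] += 1.0 - frac[j]
            m[j, i1[j]] += frac[j]
        return m

    return axis_weights(h_in, h_out), axis_weights(w_in, w_out)


def upsample_bilinear(x: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
    """Corner-aligned bilinear upsampling of (..., H, W) arrays."""
    h_in, w_in = x.shape[-2], x.shape[-1]
    r, c = bilinear_matrices(h_in, w_in, h_out, w_out)
    return np.einsum("ij,...jk,lk->...il", r, x, c, optimize=True)


class BilinearUpsample(Module):
    """Upsample (N,C,h,w) to a fixed (H,W) with corner-aligned bilinear
    interpolation; backward is the exact transpose operator."""

    def __init__(self, h_out: int, w_out: int) -> None:
        super().__init__()
        self.h_out, self.w_out = h_out, w_out
        self._mats = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        r, c = bilinear_matrices(x.shape[-2], x.shape[-1], self.h_out, self.w_out)
        self._mats = (r, c)
        return np.einsum("ij,ncjk,lk->ncil", r, x, c, optimize=True)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        r, c = self._mats
        self._mats = None
        return np.einsum("ji,ncjk,kl->ncil", r, dy, c, optimize=True)
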
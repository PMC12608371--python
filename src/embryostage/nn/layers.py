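"""Layers with explicit forward/backward passes.

Array convention: activations are ``float32`` NCHW tensors
``(batch, channels, height, width)``; fully connected activations are
``(batch, features)``.  Each layer caches in ``forward(train=True)``
whatever its ``backward`` needs; evaluation passes cache nothing.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base class: parameter bookkeeping plus the forward/backward contract."""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # checkpointing -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the layer's state (parameters + buffers)."""
        return [p.data for p in self.params()]

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.params()]

    def state_arrays(self) -> list[np.ndarray]:
        return [a for l in self.layers for a in l.state_arrays()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Kaiming-normal initialisation suited to ReLU networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, padding
        fan_in = in_ch * kernel * kernel
        self.W = Parameter(he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in), "conv.W")
        self.b = Parameter(np.zeros(out_ch, dtype=np.float32), "conv.b") if bias else None
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        k, s, p = self.k, self.s, self.p
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, C, Ho, Wo, k, k) view, subsampled by stride
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        b, c, ho, wo = win.shape[:4]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * ho * wo, c * k * k
        )
        return cols, (ho, wo)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        b = x.shape[0]
        cols, (ho, wo) = self._im2col(x)
        out = cols @ self.W.data.reshape(self.out_ch, -1).T
        if self.b is not None:
            out += self.b.data
        out = out.reshape(b, ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape, ho, wo) if train else None
        return np.ascontiguousarray(out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        b = x_shape[0]
        k, s, p = self.k, self.s, self.p
        gy_flat = gy.transpose(0, 2, 3, 1).reshape(b * ho * wo, self.out_ch)
        self.W.grad += (gy_flat.T @ cols).reshape(self.W.data.shape)
        if self.b is not None:
            self.b.grad += gy_flat.sum(axis=0)
        gcols = (gy_flat @ self.W.data.reshape(self.out_ch, -1)).reshape(
            b, ho, wo, self.in_ch, k, k
        )
        hp, wp = x_shape[2] + 2 * p, x_shape[3] + 2 * p
        gx = np.zeros((b, self.in_ch, hp, wp), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + s * ho : s, j : j + s * wo : s] += gcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if p:
            gx = gx[:, :, p:-p, p:-p]
        self._cache = None
        return gx


class ConvTranspose2d(Layer):
    """Transposed convolution with kernel == stride (non-overlapping upsampling)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 2,
        stride: int = 2,
        rng: np.random.Generator | None = None,
    ):
        if kernel != stride:
            raise ValueError("only kernel == stride upsampling is supported")
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.W = Parameter(
            he_init(rng, (in_ch, out_ch, kernel, kernel), in_ch), "convT.W"
        )
        self.b = Parameter(np.zeros(out_ch, dtype=np.float32), "convT.b")
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        b, c, h, w = x.shape
        k = self.k
        out = np.einsum("bchw,cokl->bohkwl", x, self.W.data, optimize=True)
        out = out.reshape(b, self.out_ch, h * k, w * k)
        out += self.b.data[None, :, None, None]
        self._cache = x if train else None
        return np.ascontiguousarray(out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._cache
        b, c, h, w = x.shape
        k = self.k
        gy6 = gy.reshape(b, self.out_ch, h, k, w, k)
        self.W.grad += np.einsum("bchw,bohkwl->cokl", x, gy6, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        gx = np.einsum("bohkwl,cokl->bchw", gy6, self.W.data, optimize=True)
        self._cache = None
        return np.ascontiguousarray(gx, dtype=np.float32)


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics for eval."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(ch, dtype=np.float32), "bn.gamma")
        self.beta = Parameter(np.zeros(ch, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def state_arrays(self) -> list[np.ndarray]:
        return [self.gamma.data, self.beta.data, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                np.float32
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivstd[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        self._cache = (xhat, ivstd) if train else None
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, ivstd = self._cache
        n = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        sum_gy = gy.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        gx = (
            g
            * ivstd[None, :, None, None]
            / n
            * (n * gy - sum_gy - xhat * sum_gy_xhat)
        )
        self._cache = None
        return gx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = (x > 0.0) if train else None
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._mask
        self._mask = None
        return gx


class MaxPool2d(Layer):
    """Max pooling with arbitrary kernel/stride/padding (padding with -inf)."""

    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        self.k = kernel
        self.s = stride or kernel
        self.p = padding
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        x = np.asarray(x, dtype=np.float32)
        if p:
            x_p = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        else:
            x_p = x
        win = sliding_window_view(x_p, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        b, c, ho, wo = win.shape[:4]
        flat = win.reshape(b, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape, (ho, wo)) if train else None
        return np.ascontiguousarray(out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        arg, x_shape, (ho, wo) = self._cache
        k, s, p = self.k, self.s, self.p
        b, c = x_shape[0], x_shape[1]
        hp, wp = x_shape[2] + 2 * p, x_shape[3] + 2 * p
        gx = np.zeros((b, c, hp, wp), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                sel = arg == (i * k + j)
                if not sel.any():
                    continue
                gx[:, :, i : i + s * ho : s, j : j + s * wo : s] += gy * sel
        if p:
            gx = gx[:, :, p:-p, p:-p]
        self._cache = None
        return gx


class Dropout(Layer):
    """Inverted dropout; a no-op when rate is 0 or in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        self._mask = mask
        return x * mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        gx = gy * self._mask
        self._mask = None
        return gx


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Parameter(he_init(rng, (out_f, in_f), in_f), "linear.W")
        self.b = Parameter(np.zeros(out_f, dtype=np.float32), "linear.b")
        self._x = None

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        self._x = x if train else None
        return x @ self.W.data.T + self.b.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.W.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        gx = gy @ self.W.data
        self._x = None
        return gx


class GlobalAvgPool(Layer):
    """NCHW -> NC global average pooling."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None], (b, c, h, w)) / (h * w)


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)
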
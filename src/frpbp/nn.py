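"""Minimal CNN engine: layers, backprop, Adam.

The regression networks in this package are small enough to train on a
single CPU, so the layer zoo is implemented directly on numpy: stride-1
same-padded 1-D/2-D convolutions via im2col + GEMM (their input gradients
are themselves same-padded convolutions with the transposed, flipped
kernel), batch normalisation with running statistics, average pooling with
floor semantics, inverted dropout, dense layers, and an Adam optimiser.
Every source of randomness (weight init, dropout masks) is owned by a
seeded generator, so two builds from the same seed are bitwise identical.

Layout conventions: 1-D tensors are (batch, channels, length); 2-D tensors
are (batch, channels, height, width); dense inputs are (batch, features).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv1D", "Conv2D", "BatchNorm", "ReLU", "AvgPool1D", "AvgPool2D",
    "Dropout", "Flatten", "Dense", "Sequential", "Adam",
]


class Layer:
    """Base layer: forward caches what backward needs; params/grads by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _conv1d_same(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """y[b,o,l] = sum_{c,t} w[o,c,t] x[b,c,l+t-p]; returns (y, im2col cache)."""
    b, c, length = x.shape
    out_ch, _, k = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    win = sliding_window_view(xp, k, axis=2)  # (B, C, L, k)
    cols = win.transpose(0, 2, 1, 3).reshape(b, length, c * k)
    y = cols @ w.reshape(out_ch, c * k).T  # (B, L, O)
    return np.ascontiguousarray(y.transpose(0, 2, 1)), cols


def _conv2d_same(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b, c, h, wd = x.shape
    out_ch, _, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B, C, H, W, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * wd, c * kh * kw)
    y = cols @ w.reshape(out_ch, c * kh * kw).T  # (B, HW, O)
    return np.ascontiguousarray(y.transpose(0, 2, 1).reshape(b, out_ch, h, wd)), cols


class Conv1D(Layer):
    """Stride-1, same-padded 1-D convolution (odd kernel)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel length must be odd for symmetric same-padding")
        if out_ch < 1 or in_ch < 1:
            raise ValueError("channel counts must be positive")
        self.kernel = kernel
        self.params["w"] = _he_init(rng, (out_ch, in_ch, kernel), in_ch * kernel, dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def forward(self, x, training):
        y, self._cols = _conv1d_same(x, self.params["w"])
        return y + self.params["b"][None, :, None]

    def backward(self, grad):
        w = self.params["w"]
        out_ch, in_ch, k = w.shape
        b, _, length = grad.shape
        g = grad.transpose(0, 2, 1).reshape(b * length, out_ch)
        self.grads["w"] = (g.T @ self._cols.reshape(b * length, in_ch * k)).reshape(w.shape)
        self.grads["b"] = grad.sum(axis=(0, 2))
        w_t = np.ascontiguousarray(w.transpose(1, 0, 2)[:, :, ::-1])
        dx, _ = _conv1d_same(grad, w_t)
        self._cols = None
        return dx


class Conv2D(Layer):
    """Stride-1, same-padded 2-D convolution (odd kernel)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int | tuple[int, int],
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if kh % 2 != 1 or kw % 2 != 1:
            raise ValueError("kernel sides must be odd for symmetric same-padding")
        if out_ch < 1 or in_ch < 1:
            raise ValueError("channel counts must be positive")
        self.kernel = (kh, kw)
        self.params["w"] = _he_init(rng, (out_ch, in_ch, kh, kw), in_ch * kh * kw, dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def forward(self, x, training):
        y, self._cols = _conv2d_same(x, self.params["w"])
        return y + self.params["b"][None, :, None, None]

    def backward(self, grad):
        w = self.params["w"]
        out_ch, in_ch, kh, kw = w.shape
        b, _, h, wd = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(b * h * wd, out_ch)
        self.grads["w"] = (g.T @ self._cols.reshape(b * h * wd, in_ch * kh * kw)).reshape(w.shape)
        self.grads["b"] = grad.sum(axis=(0, 2, 3))
        w_t = np.ascontiguousarray(w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        dx, _ = _conv2d_same(grad, w_t)
        self._cols = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def _axes(self, x):
        return tuple(i for i in range(x.ndim) if i != 1)

    def _shape(self, x, v):
        shape = [1] * x.ndim
        shape[1] = v.size
        return v.reshape(shape)

    def forward(self, x, training):
        axes = self._axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(x, mean)) * self._shape(x, inv)
        if training:
            self._xhat, self._inv, self._m = xhat, inv, x.size // x.shape[1]
        return self._shape(x, self.params["gamma"]) * xhat + self._shape(x, self.params["beta"])

    def backward(self, grad):
        axes = self._axes(grad)
        xhat, inv, m = self._xhat, self._inv, self._m
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        dxhat = grad * self._shape(grad, self.params["gamma"])
        s1 = dxhat.sum(axis=axes)
        s2 = (dxhat * xhat).sum(axis=axes)
        dx = (dxhat - self._shape(grad, s1 / m) - xhat * self._shape(grad, s2 / m)) * self._shape(grad, inv)
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class AvgPool1D(Layer):
    """Average pooling by an integer factor; trailing remainder dropped."""

    def __init__(self, factor: int = 2):
        super().__init__()
        if factor < 2:
            raise ValueError("pooling factor must be >= 2")
        self.factor = factor

    def forward(self, x, training):
        b, c, length = x.shape
        self._in_len = length
        lout = length // self.factor
        return x[:, :, : lout * self.factor].reshape(b, c, lout, self.factor).mean(axis=3)

    def backward(self, grad):
        b, c, lout = grad.shape
        dx = np.zeros((b, c, self._in_len), dtype=grad.dtype)
        dx[:, :, : lout * self.factor] = np.repeat(grad / self.factor, self.factor, axis=2)
        return dx


class AvgPool2D(Layer):
    def __init__(self, factor: int = 2):
        super().__init__()
        if factor < 2:
            raise ValueError("pooling factor must be >= 2")
        self.factor = factor

    def forward(self, x, training):
        b, c, h, w = x.shape
        self._in_shape = (h, w)
        f = self.factor
        ho, wo = h // f, w // f
        return x[:, :, : ho * f, : wo * f].reshape(b, c, ho, f, wo, f).mean(axis=(3, 5))

    def backward(self, grad):
        b, c, ho, wo = grad.shape
        h, w = self._in_shape
        f = self.factor
        dx = np.zeros((b, c, h, w), dtype=grad.dtype)
        g = np.repeat(np.repeat(grad / (f * f), f, axis=2), f, axis=3)
        dx[:, :, : ho * f, : wo * f] = g
        return dx


class Dropout(Layer):
    """Inverted dropout with a layer-owned seeded generator."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if in_features < 1 or out_features < 1:
            raise ValueError("feature counts must be positive")
        self.params["w"] = _he_init(rng, (out_features, in_features), in_features, dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, grad):
        self.grads["w"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        dx = grad @ self.params["w"]
        self._x = None
        return dx


class Sequential:
    """A plain layer chain with forward/backward and parameter traversal."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def named_params(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{prefix}{i}.{name}", layer, name


class Adam:
    """Adam over a list of (key, layer, param-name) triples."""

    def __init__(self, triples, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.triples = list(triples)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(layer.params[p]) for k, layer, p in self.triples}
        self.v = {k: np.zeros_like(layer.params[p]) for k, layer, p in self.triples}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for key, layer, pname in self.triples:
            g = layer.grads.get(pname)
            if g is None:
                continue
            m = self.m[key] = b1 * self.m[key] + (1 - b1) * g
            v = self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            layer.params[pname] -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
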
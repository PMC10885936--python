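"""Minimal CPU neural-network engine used by the spinal-canal segmenter.

Plain-numpy layers with explicit forward/backward passes: 3x3 convolution
(im2col + matmul), batch normalisation, ReLU, 2x2 max pooling, dropout,
stride-2 transposed convolution, and an Adam optimiser.  Every backward pass
is verified against central finite differences in the test suite.

Arrays are ``(N, C, H, W)`` float64 throughout; float64 keeps the gradient
checks tight and is fast enough at the matrix sizes this package trains on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "ConvTranspose2d", "BatchNorm2d", "ReLU", "MaxPool2d",
    "Dropout", "Sequential", "Adam", "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _conv_valid(xp: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of padded input ``xp`` (N,C,Hp,Wp) with
    ``w`` (O,C,k,k); computed via an einsum over the strided window view."""
    k = w.shape[-1]
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    y = np.einsum("ncijhw,ochw->noij", win, w, optimize=True)
    return y + b[:, None, None]


def _conv_backward(xp: np.ndarray, w: np.ndarray, dy: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`_conv_valid`: returns (dxp, dw, db)."""
    k = w.shape[-1]
    n, _, ho, wo = dy.shape
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    dw = np.einsum("noij,ncijhw->ochw", dy, win, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    # input gradient: shift-and-add matmuls in channels-last layout
    dyl = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))
    dxpl = np.zeros((n, xp.shape[2], xp.shape[3], xp.shape[1]), dtype=dy.dtype)
    for di in range(k):
        for dj in range(k):
            dxpl[:, di:di + ho, dj:dj + wo, :] += dyl @ w[:, :, di, dj].astype(dy.dtype)
    return dxpl.transpose(0, 3, 1, 2), dw, db


class Conv2d(Layer):
    """k x k convolution, stride 1, symmetric zero padding (same output size
    when ``pad = k // 2``).  Computation runs in the dtype of the input, so
    float32 batches train fast while float64 inputs keep gradient checks
    exact."""

    def __init__(self, cin: int, cout: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.k, self.pad = k, k // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))      # He init for ReLU nets
        self.params["w"] = rng.normal(0.0, scale, (cout, cin, k, k))
        self.params["b"] = np.zeros(cout)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.pad
        self._xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        return _conv_valid(self._xp, self.params["w"].astype(x.dtype),
                           self.params["b"].astype(x.dtype))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dxp, dw, db = _conv_backward(self._xp, self.params["w"], dy)
        self.grads["w"], self.grads["b"] = dw, db
        p = self.pad
        return dxp[:, :, p:-p or None, p:-p or None] if p else dxp


class ConvTranspose2d(Layer):
    """Transposed convolution, kernel 3, stride 2, doubling spatial size.

    Implemented as zero interleaving (stride-2 dilation of the input)
    followed by an ordinary valid 3x3 convolution; the interleave /
    de-interleave pair is linear, so the backward pass reuses the
    convolution machinery.
    """

    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.k = 3
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * self.k * self.k))
        self.params["w"] = rng.normal(0.0, scale, (cout, cin, self.k, self.k))
        self.params["b"] = np.zeros(cout)

    def _stuff(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        # zero-interleave then pad (1 top/left, 2 bottom/right) so that a
        # valid 3x3 convolution yields exactly (2h, 2w)
        z = np.zeros((n, c, 2 * h + 2, 2 * w + 2), dtype=x.dtype)
        z[:, :, 1:2 * h:2, 1:2 * w:2] = x
        return z

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        self._z = self._stuff(x)
        return _conv_valid(self._z, self.params["w"].astype(x.dtype),
                           self.params["b"].astype(x.dtype))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz, dw, db = _conv_backward(self._z, self.params["w"], dy)
        self.grads["w"], self.grads["b"] = dw, db
        _, _, h, w = self._in_shape
        return dz[:, :, 1:2 * h:2, 1:2 * w:2]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(x.dtype)
        self._xhat = (x - mu.astype(x.dtype)[:, None, None]) / self._std[:, None, None]
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        self._train = train
        g = self.params["gamma"].astype(x.dtype)
        b = self.params["beta"].astype(x.dtype)
        return g[:, None, None] * self._xhat + b[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, m = self._xhat, self._std, self._m
        self.grads["gamma"] = np.sum(dy * xhat, axis=(0, 2, 3))
        self.grads["beta"] = np.sum(dy, axis=(0, 2, 3))
        dxhat = dy * self.params["gamma"].astype(dy.dtype)[:, None, None]
        if not self._train:
            return dxhat / std[:, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3)
        return (dxhat - s1.transpose(1, 0, 2, 3) / m
                - xhat * s2.transpose(1, 0, 2, 3) / m) / std[:, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; spatial size must be even."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._mask = xr == y[:, :, :, None, :, None]
        self._xr_shape = xr.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, _, w2, _ = self._xr_shape
        dxr = self._mask * dy[:, :, :, None, :, None]
        # split gradient evenly across ties
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        dxr = dxr / counts
        return dxr.reshape(n, c, h2 * 2, w2 * 2)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def iter_layers(layer: Layer):
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_layers(sub)
    else:
        yield layer


class Adam:
    """Adam with a mutable learning rate (for plateau scheduling)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = [l for root in layers for l in iter_layers(root) if l.params]
        self.lr = lr
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / c1) / (np.sqrt(v[k] / c2) + self.eps)
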
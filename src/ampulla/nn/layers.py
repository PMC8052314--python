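"""Minimal CNN layers with explicit forward/backward passes.

All tensors are ``float32`` arrays in NCHW layout.  Each layer caches what it
needs during ``forward`` and consumes it in ``backward``; parameters and
their gradients live in the ``params`` / ``grads`` dicts so an optimizer can
iterate over them generically.  Convolution is implemented as im2col +
matmul, which is the fastest portable route on a single CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "UpsampleNearest2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
]


class Layer:
    """Base class: parameter-free layers inherit as-is."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Layer):
    """3x3 (by default) same-padded convolution via im2col.

    Weights use He initialization, appropriate for ReLU networks.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(0.0, std, size=(fan_in, out_ch)).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self._xp: np.ndarray | None = None

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        # xp: (N, C, H+2p, W+2p) -> (N, H*W, C*k*k)
        win = sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))
        n = xp.shape[0]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, self.in_ch * self.kernel * self.kernel)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = xp
        self._hw = (h, w)
        cols = self._im2col(xp, h, w)
        y = cols @ self.params["W"] + self.params["b"]
        return y.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xp is not None
        n = dy.shape[0]
        h, w = self._hw
        k, p = self.kernel, self.pad
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, self.out_ch)
        cols = self._im2col(self._xp, h, w).reshape(n * h * w, -1)
        self.grads["W"] = (cols.T @ dy2).astype(np.float32)
        self.grads["b"] = dy2.sum(axis=0)
        dcols = (dy2 @ self.params["W"].T).reshape(n, h, w, self.in_ch, k, k)
        dxp = np.zeros_like(self._xp)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        self._xp = None
        if p == 0:
            return dxp
        return dxp[:, :, p:-p, p:-p]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; gradient routes to the argmax pixel."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xr = x.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._idx = np.argmax(xr, axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        ho, wo = h // 2, w // 2
        dxr = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleNearest2d(Layer):
    """Nearest-neighbour 2x upsampling; gradient sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    """Spatial mean: (N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, std, size=(in_features, out_features)).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return (dy @ self.params["W"].T).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
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

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer
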
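"""Minimal 2-D CNN layers with explicit forward/backward passes.

Everything operates on single-precision ``(C, H, W)`` tensors (the
zero-shot scheme trains on exactly one image, so there is no batch
axis).  Each layer caches what its backward pass needs; parameters and
their gradients live on the layer as ``params`` / ``grads`` dicts so a
single optimizer loop can update the whole network.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "Upsample2d",
]


class Layer:
    """Base class: parameter-free layers leave ``params`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def num_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2d(Layer):
    """k x k convolution, stride 1, zero 'same' padding, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        std = np.sqrt(2.0 / (in_ch * ksize * ksize))
        w = rng.normal(0.0, std, size=(out_ch, in_ch, ksize, ksize))
        self.params = {
            "w": w.astype(np.float32),
            "b": np.zeros(out_ch, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k, pad = self.ksize, self.ksize // 2
        c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
        # im2col: (h*w, c*k*k) patch matrix, then one GEMM
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4)).reshape(h * w, c * k * k)
        wmat = self.params["w"].reshape(self.out_ch, -1).T  # (c*k*k, out)
        y = cols @ wmat + self.params["b"]
        if training:
            self._cols = cols
            self._shape = (h, w)
        return y.reshape(h, w, self.out_ch).transpose(2, 0, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, pad = self.ksize, self.ksize // 2
        h, w = self._shape
        dyf = dy.transpose(1, 2, 0).reshape(h * w, self.out_ch)
        self.grads["w"] += (self._cols.T @ dyf).T.reshape(self.params["w"].shape)
        self.grads["b"] += dyf.sum(axis=0)
        wmat = self.params["w"].reshape(self.out_ch, -1)
        dcols = (dyf @ wmat).reshape(h, w, self.in_ch, k, k)
        # col2im: scatter the 9 (or k*k) shifted patch planes back
        dxp = np.zeros((self.in_ch, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + h, kj : kj + w] += dcols[:, :, :, ki, kj].transpose(2, 0, 1)
        self._cols = None
        return dxp[:, pad : pad + h, pad : pad + w]


class BatchNorm2d(Layer):
    """Per-channel normalization over the spatial axes.

    With batch size 1 the statistics are spatial; at inference the
    running averages are used so the denoiser output does not depend on
    the statistics of the frame being denoised.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * inv[:, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[1] * dy.shape[2]
        dgamma = (dy * xhat).sum(axis=(1, 2))
        dbeta = dy.sum(axis=(1, 2))
        self.grads["gamma"] += dgamma
        self.grads["beta"] += dbeta
        g = self.params["gamma"] * inv
        dx = g[:, None, None] * (
            dy - dbeta[:, None, None] / m - xhat * dgamma[:, None, None] / m
        )
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """2 x 2 max pooling; spatial dims must be even (the network pads)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c, h, w = x.shape
        xr = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(
            c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._shape = (c, h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        dxr = np.zeros((c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)


class Upsample2d(Layer):
    """Nearest-neighbour x2 upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = dy.shape
        return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))
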
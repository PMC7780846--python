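"""Minimal 3D convolutional network engine (numpy, explicit backprop).

The analysis needs three things a generic black-box fit does not give:
(1) gradients of the prediction score with respect to every input voxel
(saliency maps), (2) the ability to cut gradient flow through an arbitrary
subset of the learned predictor variables (confounder-free saliency), and
(3) full determinism under a seed.  A compact explicit-backprop engine on
small cubic grids provides all three; layers cover exactly what the model
uses: 3x3x3 same-padded convolutions, ReLU, 2x average pooling, flatten,
and dense layers, trained with Adam on binary cross-entropy.

Convolutions are evaluated as 27 shifted tensor contractions, which keeps
peak memory proportional to the activations rather than to an im2col
buffer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "PointwiseConv3d",
    "ReLU",
    "AvgPool3d",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
]

_K = 3  # convolution kernel edge (fixed, same padding)


class Layer:
    """Base class: forward caches what backward needs; params/grads align."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        raise NotImplementedError  # pragma: no cover - interface


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, zero same-padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * _K**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, _K, _K, _K))
        self.w = w.astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, g = x.shape[0], x.shape[1], x.shape[2]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        self._xp = xp
        y = np.empty((n, self.w.shape[0], g, g, g), dtype=np.float32)
        y[:] = self.b[None, :, None, None, None]
        for i in range(_K):
            for j in range(_K):
                for k in range(_K):
                    patch = xp[:, :, i : i + g, j : j + g, k : k + g]
                    y += np.einsum(
                        "oc,ncxyz->noxyz", self.w[:, :, i, j, k], patch, optimize=True
                    )
        return y

    def backward(self, gy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        xp = self._xp
        assert xp is not None, "forward must run before backward"
        g = gy.shape[2]
        gw, gb = self.grads
        gb += gy.sum(axis=(0, 2, 3, 4))
        gxp = np.zeros_like(xp) if need_input_grad else None
        for i in range(_K):
            for j in range(_K):
                for k in range(_K):
                    patch = xp[:, :, i : i + g, j : j + g, k : k + g]
                    gw[:, :, i, j, k] += np.einsum(
                        "noxyz,ncxyz->oc", gy, patch, optimize=True
                    )
                    if gxp is not None:
                        gxp[:, :, i : i + g, j : j + g, k : k + g] += np.einsum(
                            "oc,noxyz->ncxyz", self.w[:, :, i, j, k], gy, optimize=True
                        )
        if gxp is None:
            return None
        return gxp[:, :, 1:-1, 1:-1, 1:-1]


class ReLU(Layer):
    """Rectifier with a small leak so units cannot die irrecoverably."""

    def __init__(self, leak: float = 0.01) -> None:
        super().__init__()
        self.leak = leak
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.leak * x).astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        return np.where(self._mask, gy, self.leak * gy).astype(np.float32, copy=False)


class AvgPool3d(Layer):
    """2x2x2 average pooling (grid edge must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, g = x.shape[0], x.shape[1], x.shape[2]
        if g % 2:
            raise ValueError(f"grid edge {g} not divisible by 2")
        h = g // 2
        self._in_edge = g
        return x.reshape(n, c, h, 2, h, 2, h, 2).mean(axis=(3, 5, 7))

    def backward(self, gy: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        rep = np.repeat(np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3), 2, axis=4)
        return (rep / 8.0).astype(np.float32, copy=False)


class PointwiseConv3d(Layer):
    """1x1x1 convolution: a per-voxel linear map across channels.

    Used as the predictor readout: it keeps the spatial grid intact so each
    output unit (channel x position) summarizes one receptive field rather
    than the whole volume.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in))
        self.w = w.astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.einsum("oc,ncxyz->noxyz", self.w, x, optimize=True)
        return y + self.b[None, :, None, None, None]

    def backward(self, gy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        gw, gb = self.grads
        gw += np.einsum("noxyz,ncxyz->oc", gy, self._x, optimize=True)
        gb += gy.sum(axis=(0, 2, 3, 4))
        if not need_input_grad:
            return None
        return np.einsum("oc,noxyz->ncxyz", self.w, gy, optimize=True)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        return gy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.w = w.astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, gy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        gw, gb = self.grads
        gw += self._x.T @ gy
        gb += gy.sum(axis=0)
        if not need_input_grad:
            return None
        return gy @ self.w.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers
        for lay in layers:
            self.params.extend(lay.params)
            self.grads.extend(lay.grads)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, gy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        for idx in range(len(self.layers) - 1, -1, -1):
            last = idx == 0 and not need_input_grad
            gy = self.layers[idx].backward(gy, need_input_grad=not last)
        return gy

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Adam:
    """Adam with per-parameter moment buffers (float32 state)."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.grads = grads
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
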
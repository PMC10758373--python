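"""Minimal CNN layer library with explicit forward/backward passes.

All layers operate on ``float64`` numpy arrays in NCHW layout.  The library
is deliberately small: it provides exactly the layer vocabulary needed by
the SmallNet / SonoNet / VGG16 families (convolution with 'same' padding,
batch normalisation, ReLU, 2x2 max pooling, adaptive and global average
pooling, a dense layer) plus the Adam optimizer with an optional
exponential learning-rate / weight-decay schedule.

Gradients are accumulated into per-parameter ``.grad`` buffers by
``backward``; call :meth:`Layer.zero_grad` (or ``Adam.zero_grad``) between
steps.  Everything is deterministic given the ``numpy.random.Generator``
used at initialisation, and runs single-threaded on CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "AdaptiveAvgPool2d",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "adaptive_avg_pool2d",
]


@dataclass
class Parameter:
    """A trainable array together with its gradient accumulator."""

    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base class: a differentiable map with cached forward state."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Conv2d(Layer):
    """2-D convolution, stride 1, 'same' zero padding, optional bias.

    Weights are He-initialised.  The forward/backward passes use a
    shift-and-add formulation (one tensor contraction per kernel offset),
    which is exact and fast for the small kernels used here (k <= 7).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        *,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        if in_channels < 1 or out_channels < 1 or kernel_size < 1:
            raise ValueError("Conv2d dimensions must be positive")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = kernel_size // 2
        self._xp: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        p, k = self.pad, self.kernel_size
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        y = np.zeros((n, self.out_channels, h, w))
        for i in range(k):
            for j in range(k):
                y += np.einsum(
                    "nchw,oc->nohw", xp[:, :, i : i + h, j : j + w], self.weight.value[:, :, i, j]
                )
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._xp = xp if train else None
        self._out_hw = (h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._xp is None:
            raise RuntimeError("backward called without a training-mode forward")
        xp, (h, w), k, p = self._xp, self._out_hw, self.kernel_size, self.pad
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                self.weight.grad[:, :, i, j] += np.einsum(
                    "nohw,nchw->oc", dy, xp[:, :, i : i + h, j : j + w]
                )
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "nohw,oc->nchw", dy, self.weight.value[:, :, i, j]
                )
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p : p + h, p : p + w]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics.

    Four stored entries per channel (scale, shift, running mean, running
    variance), matching the parameter-accounting convention used by the
    architecture summaries.
    """

    def __init__(self, channels: int, *, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv_std) if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a training-mode forward")
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = (x > 0.0) if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called without a training-mode forward")
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        if h2 == 0 or w2 == 0:
            raise ValueError("input too small for 2x2 max pooling")
        xc = x[:, :, : 2 * h2, : 2 * w2]
        xr = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        else:
            self._cache = None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a training-mode forward")
        idx, (n, c, h, w) = self._cache
        h2, w2 = h // 2, w // 2
        dz = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dz, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dz.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx


def _pool_bins(in_size: int, out_size: int) -> list[tuple[int, int]]:
    return [
        (int(np.floor(i * in_size / out_size)), int(np.ceil((i + 1) * in_size / out_size)))
        for i in range(out_size)
    ]


class AdaptiveAvgPool2d(Layer):
    """Average pooling to an arbitrary target spatial size.

    When the target equals the input size this is the identity.  Bin edges
    follow the usual adaptive convention (floor/ceil), so sizes need not
    divide evenly.
    """

    def __init__(self, out_hw: tuple[int, int]) -> None:
        oh, ow = out_hw
        if oh < 1 or ow < 1:
            raise ValueError("pooling target must be positive")
        self.out_hw = (oh, ow)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self.out_hw
        if h == 0 or w == 0:
            raise ValueError("cannot pool a zero-sized map")
        self._in_shape = x.shape
        if (oh, ow) == (h, w):
            self._identity = True
            return x
        self._identity = False
        hb, wb = _pool_bins(h, oh), _pool_bins(w, ow)
        self._bins = (hb, wb)
        y = np.empty((n, c, oh, ow))
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                y[:, :, i, j] = x[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._identity:
            return dy
        hb, wb = self._bins
        dx = np.zeros(self._in_shape)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += dy[:, :, i, j][:, :, None, None] / area
        return dx


def adaptive_avg_pool2d(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Functional adaptive average pooling (no gradient bookkeeping)."""
    return AdaptiveAvgPool2d(out_hw).forward(np.asarray(x, dtype=float))


class GlobalAvgPool(Layer):
    """Spatial mean, (N,C,H,W) -> (N,C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None], self._in_shape) / (h * w) + np.zeros(
            self._in_shape
        )


class Dense(Layer):
    """Fully connected layer on (N, in_features) inputs."""

    def __init__(
        self, in_features: int, out_features: int, *, rng: np.random.Generator | None = None
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called without a training-mode forward")
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Sequential(Layer):
    """An ordered chain of layers with optional taps.

    ``forward`` can record intermediate activations at given layer indices
    (the *taps* used for feature distillation); ``backward`` accepts extra
    gradients to inject at those same indices, so a loss attached to an
    intermediate feature map flows back correctly alongside the loss on the
    final output.
    """

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        tap_indices: Sequence[int] = (),
    ) -> np.ndarray | tuple[np.ndarray, dict[int, np.ndarray]]:
        taps: dict[int, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if i in tap_indices:
                taps[i] = x
        if tap_indices:
            return x, taps
        return x

    def backward(
        self, dy: np.ndarray, tap_grads: dict[int, np.ndarray] | None = None
    ) -> np.ndarray:
        tap_grads = tap_grads or {}
        for i in range(len(self.layers) - 1, -1, -1):
            if i in tap_grads:
                dy = dy + tap_grads[i]
            dy = self.layers[i].backward(dy)
        return dy

    def state(self) -> list[np.ndarray]:
        """Deep copies of all parameter values plus batch-norm statistics."""
        arrays = [p.value.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                arrays.append(layer.running_mean.copy())
                arrays.append(layer.running_var.copy())
        return arrays

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        arrays = list(arrays)
        params = self.parameters()
        for p, a in zip(params, arrays[: len(params)]):
            p.value[...] = a
        rest = arrays[len(params) :]
        k = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = rest[k]
                layer.running_var[...] = rest[k + 1]
                k += 2


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay.

    ``schedule="exponential"`` multiplies both the learning rate and the
    weight decay by ``rate`` every ``every_n_steps`` optimisation steps.
    """

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        schedule: str = "fixed",
        every_n_steps: int = 100,
        rate: float = 0.9,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if weight_decay < 0:
            raise ValueError("weight decay must be non-negative")
        if schedule not in ("fixed", "exponential"):
            raise ValueError(f"unknown schedule {schedule!r}")
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.schedule = schedule
        self.every_n_steps = every_n_steps
        self.rate = rate
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
        if self.schedule == "exponential" and self.t % self.every_n_steps == 0:
            self.lr *= self.rate
            self.weight_decay *= self.rate


def clone_layers(seq: Sequential) -> Sequential:
    """A deep, independent copy of a Sequential (weights and stats)."""
    return copy.deepcopy(seq)
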
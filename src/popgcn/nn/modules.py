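"""Layer modules built on the autodiff core.

Weight initialisation is fan-in-scaled Gaussian (He) driven by an explicit
``numpy.random.Generator``, so a model built twice from the same seed has
identical parameters.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv3d

__all__ = [
    "Parameter",
    "Module",
    "Dense",
    "Conv3d",
    "BatchNorm3d",
    "Dropout",
    "avg_pool3d_2x",
    "global_avg_pool3d",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter collection and state snapshots."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def get_state(self) -> list[np.ndarray]:
        """Copies of all trainable parameters plus non-trainable buffers."""
        return [p.data.copy() for p in self.parameters()] + [
            b.copy() for b in self.buffers()
        ]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p.data = s.copy()
        bufs = self.buffers()
        for b, s in zip(bufs, state[len(params) :]):
            b[...] = s

    def buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for value in vars(self).values():
            bufs.extend(_collect_buffers(value))
        return bufs


def _collect(value):
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_buffers(value):
    if isinstance(value, Module):
        return value.buffers()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_buffers(v))
        return out
    return []


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(he_init(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int = 0):
        fan_in = in_channels * kernel_size ** 3
        self.weight = Parameter(
            he_init(rng, (out_channels, in_channels) + (kernel_size,) * 3, fan_in)
        )
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, padding=self.padding)


class BatchNorm3d(Module):
    """Per-channel batch normalisation over (N, D, H, W).

    Training mode uses batch statistics (differentiable); evaluation mode
    uses the exponential running statistics, so inference is deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1, 1))
        self.momentum = momentum
        self.eps = eps

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3, 4), keepdims=True)
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mu.data
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * var.data
            inv = (var + self.eps) ** -0.5
            return (x - mu) * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * inv * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * mask


def avg_pool3d_2x(x: Tensor) -> Tensor:
    """Non-overlapping 2x2x2 average pooling, stride 2 (even dims required)."""
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x pooling, got {(d, h, w)}")
    return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))


def global_avg_pool3d(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3, 4))
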
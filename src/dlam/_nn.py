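"""Neural-network layers built on the autodiff core.

Conv1d / Linear / BatchNorm1d / Dropout with explicit train/eval semantics.
Initialization is He-uniform (suited to the Leaky ReLU used throughout) from
a caller-supplied ``numpy.random.Generator`` so that model construction is
fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Parameter, Tensor

__all__ = ["Module", "Conv1d", "Linear", "BatchNorm1d", "Dropout"]


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data[...] = s


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, *, rng: np.random.Generator):
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_he_uniform(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        self.weight = Parameter(_he_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Per-channel batch normalization of (B, C, L) maps.

    Training mode standardizes with batch statistics over (B, L) and updates
    exponential running statistics; eval mode uses the stored running values.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._seen_batch = False

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            if not self._seen_batch:
                # seed running statistics with the first batch: avoids the
                # cold-start bias of the (0, 1) init in early eval passes
                self.running_mean = mu.data.ravel().copy()
                self.running_var = var.data.ravel().copy()
                self._seen_batch = True
            else:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            xn = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
            xn = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xn * g + b


class Dropout(Module):
    def __init__(self, p: float):
        self.p = p

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        if not training or self.p <= 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
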
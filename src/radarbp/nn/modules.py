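"""Neural-network layers over the autodiff core.

Follows the familiar Module/parameter idiom: layers register parameters as
``Tensor`` attributes with ``requires_grad=True``; ``parameters()`` walks the
attribute tree.  Batch-norm layers keep running statistics and switch
behaviour with ``train()`` / ``eval()``.  Every layer takes an explicit
``numpy.random.Generator`` for weight initialization so model construction
is deterministic given a seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, conv1d, conv_transpose1d


def parameter(array: np.ndarray) -> Tensor:
    return Tensor(array, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # attribute-tree traversal ------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for obj in self._walk():
            for value in vars(obj).values():
                if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
        return params

    def _walk(self):
        stack = [self]
        seen = set()
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            yield obj
            for value in vars(obj).values():
                if isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))

    def train(self, mode: bool = True):
        for obj in self._walk():
            obj.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # serialization ------------------------------------------------------
    def _named_entries(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, np.ndarray):
                yield key, value
            elif isinstance(value, Module):
                yield from value._named_entries(key + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v._named_entries(f"{key}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for key, value in self._named_entries():
            out[key] = (value.data if isinstance(value, Tensor) else value).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        entries = dict(self._named_entries())
        missing = set(state) ^ set(entries)
        if missing:
            raise KeyError(f"state mismatch: {sorted(missing)}")
        for key, value in entries.items():
            src = np.asarray(state[key])
            if isinstance(value, Tensor):
                value.data = src.astype(np.float64).copy()
            else:  # running statistic stored as plain ndarray
                np.copyto(value, src)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = parameter(_kaiming(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 output_padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = parameter(_kaiming(rng, (in_channels, out_channels, kernel_size), fan_in))
        self.bias = parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding
        self.output_padding = output_padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose1d(x, self.weight, self.bias, stride=self.stride,
                                padding=self.padding, output_padding=self.output_padding)


class BatchNorm1d(Module):
    """Batch normalization over (B, C, L) or (B, C) inputs, per channel."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = parameter(np.ones(num_features))
        self.beta = parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) if x.ndim == 2 else (0, 2)
        shape = (1, -1) if x.ndim == 2 else (1, -1, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=axes, keepdims=True)
            xhat = centered * (var + self.eps) ** -0.5
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu.data.reshape(-1)
            self.running_var *= 1 - m
            self.running_var += m * var.data.reshape(-1)
        else:
            xhat = (x - self.running_mean.reshape(shape)) \
                * (self.running_var.reshape(shape) + self.eps) ** -0.5
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    """Normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


def global_avg_pool(x: Tensor) -> Tensor:
    """Temporal GAP: (B, C, L) -> (B, C)."""
    return x.mean(axis=2)


def global_max_pool(x: Tensor) -> Tensor:
    return x.max(axis=2)
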
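"""Layer abstractions over the autodiff tensors."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import (
    Parameter,
    Tensor,
    avg_pool2d,
    conv2d,
    max_pool2d,
    upsample_bilinear,
)

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid", "Sequential",
           "MaxPool2d", "AvgPool2d", "UpsampleBilinear"]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialisation."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self.children():
            yield from child.modules()

    def parameters(self) -> Iterator[Parameter]:
        for module in self.modules():
            for value in module.__dict__.values():
                if isinstance(value, Parameter):
                    yield value

    def named_buffers(self) -> Iterator[tuple["Module", str, np.ndarray]]:
        for module in self.modules():
            for name, value in module.__dict__.items():
                if isinstance(value, np.ndarray):
                    yield module, name, value

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for module in self.modules():
            module.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- flat state for checkpointing ---------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        arrays.extend(buf for _, _, buf in self.named_buffers())
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = list(self.parameters())
        buffers = list(self.named_buffers())
        if len(arrays) != len(params) + len(buffers):
            raise ValueError(
                f"state has {len(arrays)} arrays, model expects {len(params) + len(buffers)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype)
        for (module, name, buf), a in zip(buffers, arrays[len(params):]):
            setattr(module, name, a.astype(buf.dtype).reshape(buf.shape))


class Conv2d(Module):
    """Stride-1, same- or valid-padding 2-D convolution with He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel_size}")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, num_features, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, num_features, 1, 1), dtype=np.float32))
        self.running_mean = np.zeros((1, num_features, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, num_features, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.astype(np.float32)
            self.running_var = (1 - m) * self.running_var + m * var.data.astype(np.float32)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return self.gamma * xhat + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.factor)


class AvgPool2d(Module):
    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2d(x, self.factor)


class UpsampleBilinear(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        return upsample_bilinear(x, (h * self.factor, w * self.factor))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
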
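"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "InstanceNorm2d", "Sequential"]


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Tensor], seen: set[int]) -> None:
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
                seen.add(id(value))
                params.append(value)
            elif isinstance(value, Module):
                value._collect(params, seen)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._collect(params, seen)
                    elif isinstance(item, Tensor) and item.requires_grad and id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3x3/1x1/... convolution with He-normal init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, 1.0, (out_channels, in_channels, kernel, kernel)) * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, 1.0, (in_features, out_features)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class InstanceNorm2d(Module):
    """Per-sample per-channel normalization with learned affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
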
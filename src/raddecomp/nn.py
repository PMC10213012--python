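"""Convolutional building blocks and the Adam optimizer.

Layers follow the conventions of the resnet-generator / patch-discriminator
family used for unpaired image translation: reflection padding in
generators, instance normalization, leaky ReLU in discriminators.  All
computation runs through :mod:`raddecomp.autodiff`.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, avgpool2x, conv2d, pad2d, upsample2x

__all__ = [
    "Module",
    "Conv2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Upsample2x",
    "AvgPool2x",
    "Sequential",
    "ResidualBlock",
    "Adam",
]


class Module:
    """Base class: parameter registration, state dicts, call protocol."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}"
                )
            p.data[...] = arr

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """2-D convolution with 'same'-style padding (zero or reflect).

    Weights are He-initialized; ``zero_init=True`` gives an all-zero layer
    (used for the local enhancer's identity-at-init residual branch).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int | None = None,
        pad_mode: str = "zero",
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = (kernel - 1) // 2 if padding is None else padding
        self.pad_mode = pad_mode
        fan_in = in_channels * kernel * kernel
        scale = 0.0 if zero_init else math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, 1.0, (out_channels, in_channels, kernel, kernel))
            * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            pad2d(x, self.padding, self.pad_mode), self.weight, self.bias,
            stride=self.stride,
        )


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
            self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=(2, 3), keepdims=True)
        out = centered * ((var + self.eps) ** -0.5)
        if self.affine:
            out = out * self.gamma + self.beta
        return out


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


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample2x(x)


class AvgPool2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return avgpool2x(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ResidualBlock(Module):
    """conv-norm-relu-conv-norm with an identity skip (reflection padded)."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, pad_mode="reflect", rng=rng)
        self.norm1 = InstanceNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, pad_mode="reflect", rng=rng)
        self.norm2 = InstanceNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        return x + self.norm2(self.conv2(h))


class Adam:
    """Adam with the (0.5, 0.999) moment schedule customary for GANs."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "lr": self.lr,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        for m, src in zip(self.m, state["m"]):
            m[...] = src
        for v, src in zip(self.v, state["v"]):
            v[...] = src
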
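"""Parameterised layers built on the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .functional import conv_nd
from .tensor import Tensor

__all__ = ["Module", "Conv", "InstanceNorm", "Identity"]


class Module:
    """Base class: recursive parameter discovery and state (de)serialisation.

    Submodules and parameters are found by scanning ``__dict__``; lists of
    modules are supported (used for the decoder stage stacks).
    """

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise ValueError(f"state dict keys do not match module: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.array(state[name], dtype=np.float64, copy=True)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv(Module):
    """N-d convolution, stride 1, same padding, He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 nd: int, dilation: int = 1, rng: np.random.Generator | None = None):
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        rng = rng or np.random.default_rng(0)
        shape = (out_channels, in_channels) + (kernel,) * nd
        fan_in = in_channels * kernel ** nd
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.dilation = int(dilation)

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias, dilation=self.dilation)


class InstanceNorm(Module):
    """Per-sample, per-channel standardisation over spatial axes, affine.

    The default normaliser throughout the package: the reference training
    setting uses batch size 1, where batch statistics degenerate.
    """

    def __init__(self, channels: int, nd: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels) + (1,) * nd), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels) + (1,) * nd), requires_grad=True)
        self.eps = float(eps)
        self._nd = nd

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(2, 2 + self._nd))
        mu = x.mean(axis=axes, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=axes, keepdims=True)
        xhat = centred * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
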
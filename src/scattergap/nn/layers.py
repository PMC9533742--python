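"""Parameterized layers and the module container for the numpy engine."""

from __future__ import annotations

import copy
from typing import Iterator

import numpy as np

from . import tensor as F
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "PartialConv2d", "ConvTranspose2x2", "Linear"]


class Module:
    """Base class: parameter discovery, counting and state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            for p in _collect(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match the module's parameter list")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {arr.shape}")
            p.data = arr.copy()

    def copy(self) -> "Module":
        return copy.deepcopy(self)


def _collect(obj) -> Iterator[Tensor]:
    if isinstance(obj, Tensor):
        if obj.requires_grad:
            yield obj
    elif isinstance(obj, Module):
        yield from obj.parameters()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect(item)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """'Same' zero-padded convolution, kernel 1x1 or 3x3 with dilation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        dilation: int = 1,
    ):
        if kernel_size not in (1, 3):
            raise ValueError("kernel_size must be 1 or 3")
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            _he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.dilation)


class PartialConv2d(Module):
    """Mask-renormalized convolution; forward returns (features, new mask)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        dilation: int = 1,
    ):
        if kernel_size not in (1, 3):
            raise ValueError("kernel_size must be 1 or 3")
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            _he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
        self.dilation = dilation

    def __call__(self, x: Tensor, mask: np.ndarray) -> tuple[Tensor, np.ndarray]:
        return F.partial_conv2d(x, mask, self.weight, self.bias, self.dilation)


class ConvTranspose2x2(Module):
    """Stride-2 2x2 transposed convolution (the U-Net 'up-conv')."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.weight = Tensor(
            _he_init(rng, (in_channels, out_channels, 2, 2), in_channels * 4),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv_transpose2x2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Tensor(
            _he_init(rng, (out_features, in_features), in_features), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)
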
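"""Trainable layer primitives built on :mod:`dafdnet.autodiff`.

Parameter containers follow the familiar module pattern: assigning a
gradient-carrying :class:`~dafdnet.autodiff.Tensor` or a sub-``Module`` to an
attribute registers it, ``named_parameters`` walks the tree with dotted
names (used for checkpointing), and ``train``/``eval`` toggle batch-norm
behaviour.  Weight initialization draws from an explicit
``numpy.random.Generator`` so model construction is reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import DTYPE, Tensor


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value) -> None:
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._mods.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._mods.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- checkpoint plumbing ------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            for bname, buf in m._buffers().items():
                state[f"{name}{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=DTYPE)
        for name, m in self._named_modules():
            for bname in m._buffers():
                key = f"{name}{bname}"
                if key in state:
                    getattr(m, "_set_buffer")(bname, state[key])

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, m in self._mods.items():
            yield from m._named_modules(prefix + name + ".")

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()) -> None:
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module) -> None:
        self._mods[str(len(self._items))] = mod
        self._items.append(mod)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i: int) -> Module:
        return self._items[i]

    def __len__(self) -> int:
        return len(self._items)


class Conv2d(Module):
    """Same-size 2-D convolution layer (He-normal initialized)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same-size convolution")
        std = np.sqrt(2.0 / (in_channels * kernel_size * kernel_size))
        self.weight = parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = parameter(np.zeros(out_channels)) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)


class DepthwiseConv2d(Module):
    """Per-channel same-size convolution (the ghost module's cheap transform)."""

    def __init__(self, channels: int, kernel_size: int = 3, bias: bool = False,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same-size convolution")
        std = np.sqrt(2.0 / (kernel_size * kernel_size))
        self.weight = parameter(rng.normal(0.0, std, (channels, kernel_size, kernel_size)))
        self.bias = parameter(np.zeros(channels)) if bias else None
        self.channels = channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return ad.depthwise_conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = parameter(np.zeros(out_features))
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Training mode normalizes with batch statistics (differentiated through);
    eval mode uses exponential-moving-average running statistics, making
    inference deterministic for a fixed checkpoint.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.gamma = parameter(np.ones((1, channels, 1, 1)))
        self.beta = parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps
        self.momentum = momentum
        self.channels = channels
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, channels, 1, 1), dtype=DTYPE)

    def _buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        object.__setattr__(self, name, np.asarray(value, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = ad.mean(x, axis=(0, 2, 3), keepdims=True)
            xc = ad.sub(x, mu)
            var = ad.mean(ad.mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            inv = ad.pow_scalar(ad.add(var, self.eps), -0.5)
            xn = ad.mul(xc, inv)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xn = ad.mul(ad.sub(x, Tensor(self.running_mean)), Tensor(inv))
        return ad.add(ad.mul(xn, self.gamma), self.beta)
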
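"""Convolutional building blocks: ghost convolution, squeeze-and-excitation,
the SE-ghost module, and sequential spatial/channel attention.

Ghost convolution spends an ordinary convolution on only a fraction of the
output channels (the *primary* part) and derives the rest by inexpensive
per-channel transforms, cutting parameters roughly in half at ratio 1/2.
The SE-ghost module swaps the cheap depthwise transform for channel
reweighting: a squeeze-and-excitation gate computed from the primary result
scales it per channel, and the gated copy is concatenated with the primary
result.  The attention block applies a channel gate (SE) followed by a
single-channel spatial gate derived from pooled channel statistics; both
gates are sigmoids, so attention only ever attenuates.

Every block exposes a ``gate_override`` hook that, when set to a float,
replaces the corresponding sigmoid gate — a test harness for the identity
checks (override 1.0 makes attention a no-op).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import BatchNorm2d, Conv2d, DepthwiseConv2d, Linear, Module


@dataclass(frozen=True)
class GhostConfig:
    """Ghost split: ``m = ceil(out_channels * ratio)`` primary channels, the
    remaining ``out_channels - m`` produced by the cheap branch."""

    out_channels: int
    ratio: float = 0.5
    primary_kernel: int = 3
    cheap_kernel: int = 3

    def __post_init__(self) -> None:
        if self.out_channels < 2:
            raise ValueError(f"out_channels must be >= 2, got {self.out_channels}")
        if not 0.0 < self.ratio < 1.0:
            raise ValueError(f"ratio must lie in (0, 1), got {self.ratio}")
        if self.cheap_channels > self.primary_channels:
            raise ValueError("ratio < 1/2 would need more cheap channels than "
                             "primary channels; use ratio >= 1/2")

    @property
    def primary_channels(self) -> int:
        return math.ceil(self.out_channels * self.ratio)

    @property
    def cheap_channels(self) -> int:
        return self.out_channels - self.primary_channels


@dataclass(frozen=True)
class SEConfig:
    channels: int
    reduction: int = 4

    def __post_init__(self) -> None:
        if self.channels < 1 or self.reduction < 1:
            raise ValueError("channels and reduction must be positive")

    @property
    def bottleneck(self) -> int:
        return max(1, self.channels // self.reduction)


class SEBlock(Module):
    """Channel gate: global average pool, bottleneck MLP, sigmoid.

    ``forward`` returns the (N, C) gate itself — strictly inside (0, 1) —
    so callers decide how to apply it.
    """

    def __init__(self, cfg: SEConfig, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.fc1 = Linear(cfg.channels, cfg.bottleneck, rng=rng)
        self.fc2 = Linear(cfg.bottleneck, cfg.channels, rng=rng)
        self.gate_override: float | None = None

    def squeeze(self, x: Tensor) -> Tensor:
        return ad.mean(x, axis=(2, 3))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(f"SE block expects {self.cfg.channels} channels, got {x.shape[1]}")
        if self.gate_override is not None:
            return Tensor(np.full((x.shape[0], self.cfg.channels), self.gate_override,
                                  dtype=np.float32))
        z = self.squeeze(x)
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(z))))


class GhostConv(Module):
    """Plain ghost convolution (primary conv + depthwise cheap branch)."""

    def __init__(self, in_channels: int, cfg: GhostConfig,
                 rng: np.random.Generator | None = None, batch_norm: bool = True) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.primary = Conv2d(in_channels, cfg.primary_channels, cfg.primary_kernel, rng=rng)
        self.bn = BatchNorm2d(cfg.primary_channels) if batch_norm else None
        self.cheap = DepthwiseConv2d(cfg.primary_channels, cfg.cheap_kernel, rng=rng)
        self.out_channels = cfg.out_channels

    def _primary(self, x: Tensor) -> Tensor:
        p = self.primary(x)
        if self.bn is not None:
            p = self.bn(p)
        return ad.relu(p)

    def forward(self, x: Tensor) -> Tensor:
        p = self._primary(x)
        cheap = ad.slice_channels(self.cheap(p), 0, self.cfg.cheap_channels)
        return ad.concat([p, cheap], axis=1)


class SEGhostModule(GhostConv):
    """Ghost module whose cheap branch is SE channel reweighting of the
    primary convolution result, concatenated with that result."""

    def __init__(self, in_channels: int, cfg: GhostConfig,
                 se: SEConfig | None = None, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        super().__init__(in_channels, cfg, rng=rng)
        self.se = SEBlock(se or SEConfig(channels=cfg.primary_channels), rng=rng)
        if self.se.cfg.channels != cfg.primary_channels:
            raise ValueError("SE config must match the primary channel count")

    def forward(self, x: Tensor) -> Tensor:
        p = self._primary(x)
        w = self.se(p)
        gated = ad.mul(p, ad.reshape(w, (w.shape[0], w.shape[1], 1, 1)))
        return ad.concat([p, ad.slice_channels(gated, 0, self.cfg.cheap_channels)], axis=1)


class SCAAttention(Module):
    """Sequential channel-then-spatial gating with identical output shape.

    The channel gate is an SE block over the input; the spatial gate is a
    sigmoid of a 7x7 convolution of the channel-mean map.  Because both
    gates live in (0, 1), every output entry is no larger in magnitude than
    its input entry.
    """

    def __init__(self, channels: int, reduction: int = 4, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.se = SEBlock(SEConfig(channels=channels, reduction=reduction), rng=rng)
        self.spatial = Conv2d(1, 1, spatial_kernel, rng=rng)
        self.gate_override: float | None = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"attention expects {self.channels} channels, got {x.shape[1]}")
        if self.gate_override is not None:
            g = np.float32(self.gate_override)
            return ad.mul(ad.mul(x, g), g)
        w = self.se(x)
        xc = ad.mul(x, ad.reshape(w, (w.shape[0], w.shape[1], 1, 1)))
        pooled = ad.mean(xc, axis=1, keepdims=True)
        gate = ad.sigmoid(self.spatial(pooled))
        return ad.mul(xc, gate)


# ---------------------------------------------------------------------
# functional conveniences (fresh seeded weights per call)
# ---------------------------------------------------------------------

def ghost_conv(x: Tensor, cfg: GhostConfig, seed: int = 0) -> Tensor:
    return GhostConv(x.shape[1], cfg, rng=np.random.default_rng(seed))(x)


def se_block(x: Tensor, cfg: SEConfig, seed: int = 0) -> Tensor:
    return SEBlock(cfg, rng=np.random.default_rng(seed))(x)


def se_ghost_module(x: Tensor, cfg: GhostConfig, se: SEConfig | None = None,
                    seed: int = 0) -> Tensor:
    return SEGhostModule(x.shape[1], cfg, se=se, rng=np.random.default_rng(seed))(x)


def sca_attention(x: Tensor, seed: int = 0) -> Tensor:
    return SCAAttention(x.shape[1], rng=np.random.default_rng(seed))(x)


def plain_conv_parameters(in_channels: int, out_channels: int, kernel: int = 3) -> int:
    """Learnable parameter count of the ordinary convolution a ghost module
    replaces (weights + bias); the baseline for the parameter-saving check."""
    return out_channels * in_channels * kernel * kernel + out_channels
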
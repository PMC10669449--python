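"""The direction-aware fracture-segmentation network.

Encoder-decoder with two parallel encoder paths over a single-channel
image.  The *ghost path* stacks SE-ghost modules separated by 2x2 average
pooling (three stages at full, half and quarter resolution).  The *Gabor
path* convolves the image once with a fixed Gabor filter bank and pools the
responses to the same three resolutions.  Per stage the two paths are
concatenated (``GG_i``), refined by pool + 3x3 conv + batch norm (+ 2x
upsample back to the stage resolution, giving ``PF_i``), re-joined with the
ghost features and passed through spatial/channel attention (``A_i``).  The
decoder walks back up: each attention map is 2x-upsampled, concatenated
with the next-higher-resolution attention map and fused by a 3x3
convolution; a terminal 1x1 convolution and sigmoid emit a same-size
fracture-probability map in [0, 1].

Stage widths at the default configuration (input 1024):

======== ============= ==========
tensor    resolution    channels
======== ============= ==========
Gab1-3    1024/512/256  32
GhoM1-3   1024/512/256  32/64/128
GG1-3     1024/512/256  64/96/160
PF1-3     1024/512/256  32/64/128
A1-3      1024/512/256  64/128/256
Output    1024          1
======== ============= ==========

The training objective is plain mean-squared error between the probability
map and the binary ground-truth mask.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import DTYPE, Tensor
from .blocks import GhostConfig, SCAAttention, SEGhostModule
from .gabor import GaborBank, gabor_conv_batch, make_gabor_bank
from .layers import BatchNorm2d, Conv2d, Module, ModuleList


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``input_size`` is the square spatial side (1024 at clinical scale; 128
    is the customary desk-test size — channel counts never depend on it).
    ``stage_channels`` are the ghost-path widths per stage, ``pf_channels``
    the refinement widths; the Gabor path contributes
    ``gabor_orientations * len(gabor_scales)`` channels at every stage.
    """

    input_size: int = 1024
    stage_channels: tuple[int, ...] = (32, 64, 128)
    pf_channels: tuple[int, ...] = (32, 64, 128)
    gabor_orientations: int = 8
    gabor_scales: tuple[int, ...] = (1, 2, 3, 4)
    gabor_kernel_size: int = 15
    gabor_response_mode: str = "magnitude"
    ghost_ratio: float = 0.5
    se_reduction: int = 4
    upsample: str = "nearest"

    def __post_init__(self) -> None:
        if len(self.stage_channels) != len(self.pf_channels):
            raise ValueError("stage_channels and pf_channels must have equal length")
        if self.input_size % (2 ** self.n_stages) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by {2 ** self.n_stages} "
                "so pooling/upsampling round-trips exactly")
        if self.upsample not in ("nearest", "bilinear"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")

    @property
    def n_stages(self) -> int:
        return len(self.stage_channels)

    @property
    def gabor_channels(self) -> int:
        n = self.gabor_orientations * len(self.gabor_scales)
        return 2 * n if self.gabor_response_mode == "real+imag" else n

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        raw = json.loads(text)
        for key in ("stage_channels", "pf_channels", "gabor_scales"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


def _bilinear_weight(channels: int) -> Tensor:
    k = np.array([0.25, 0.5, 0.25], dtype=DTYPE)
    return Tensor(np.tile(np.outer(k, k), (channels, 1, 1)))


class DAFDNet(Module):
    """Direction-aware encoder-decoder; see the module docstring."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0) -> None:
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.bank: GaborBank = make_gabor_bank(
            U=cfg.gabor_orientations, scales=cfg.gabor_scales,
            kernel_size=cfg.gabor_kernel_size, response_mode=cfg.gabor_response_mode)
        gc = cfg.gabor_channels
        ghosts, pf_convs, pf_bns, atts = ModuleList(), ModuleList(), ModuleList(), ModuleList()
        in_ch = 1
        for i, (sc, pc) in enumerate(zip(cfg.stage_channels, cfg.pf_channels)):
            ghosts.append(SEGhostModule(in_ch, GhostConfig(sc, ratio=cfg.ghost_ratio), rng=rng))
            pf_convs.append(Conv2d(sc + gc, pc, 3, rng=rng))
            pf_bns.append(BatchNorm2d(pc))
            atts.append(SCAAttention(sc + pc, reduction=cfg.se_reduction, rng=rng))
            in_ch = sc
        self.ghosts, self.pf_convs, self.pf_bns, self.atts = ghosts, pf_convs, pf_bns, atts

        # decoder: fuse up(deeper) + A_i down to stage i's ghost width
        att_ch = [s + p for s, p in zip(cfg.stage_channels, cfg.pf_channels)]
        dec_convs, dec_bns = ModuleList(), ModuleList()
        carry = att_ch[-1]
        for i in range(cfg.n_stages - 2, -1, -1):
            dec_convs.append(Conv2d(carry + att_ch[i], cfg.stage_channels[i], 3, rng=rng))
            dec_bns.append(BatchNorm2d(cfg.stage_channels[i]))
            carry = cfg.stage_channels[i]
        self.dec_convs, self.dec_bns = dec_convs, dec_bns
        self.head = Conv2d(cfg.stage_channels[0], 1, 1, rng=rng)
        # Fracture pixels are a ~1% minority; starting the output sigmoid near
        # that prior (logit -3) spares the optimizer the long initial phase of
        # draining a 0.5-level map toward zero under MSE.
        self.head.bias.data[:] = -3.0

    # -- helpers -------------------------------------------------------
    def gabor_features(self, images: np.ndarray) -> np.ndarray:
        """Fixed full-resolution Gabor responses for an (N, 1, H, W) batch.

        These depend only on the input, so callers that sweep a dataset many
        times (training) compute them once and pass them to :meth:`forward`.
        """
        return gabor_conv_batch(images, self.bank)

    def _up(self, x: Tensor) -> Tensor:
        up = ad.upsample2(x)
        if self.cfg.upsample == "bilinear":
            up = ad.depthwise_conv2d(up, _bilinear_weight(x.shape[1]))
        return up

    # -- forward -------------------------------------------------------
    def forward(self, x, gab1: np.ndarray | None = None,
                probes: dict | None = None) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        n, c, h, w = x.shape
        if c != 1 or h != self.cfg.input_size or w != self.cfg.input_size:
            raise ValueError(f"expected (N, 1, {self.cfg.input_size}, {self.cfg.input_size}) "
                             f"input, got {x.shape}")
        if gab1 is None:
            gab1 = self.gabor_features(x.data)

        gab = [Tensor(gab1)]
        for _ in range(self.cfg.n_stages - 1):
            gab.append(ad.avg_pool2(gab[-1]))

        ghom, feats = [], x
        for i, ghost in enumerate(self.ghosts):
            if i > 0:
                feats = ad.avg_pool2(feats)
            feats = ghost(feats)
            ghom.append(feats)

        atts = []
        for i in range(self.cfg.n_stages):
            gg = ad.concat([gab[i], ghom[i]], axis=1)
            pf = ad.avg_pool2(gg)
            pf = ad.relu(self.pf_bns[i](self.pf_convs[i](pf)))
            pf = self._up(pf)
            a = self.atts[i](ad.concat([ghom[i], pf], axis=1))
            atts.append(a)
            if probes is not None:
                probes[f"Gab{i + 1}"] = gab[i].data
                probes[f"GhoM{i + 1}"] = ghom[i].data
                probes[f"GG{i + 1}"] = gg.data
                probes[f"PF{i + 1}"] = pf.data
                probes[f"A{i + 1}"] = a.data

        d = atts[-1]
        for j, i in enumerate(range(self.cfg.n_stages - 2, -1, -1)):
            d = ad.concat([self._up(d), atts[i]], axis=1)
            d = ad.relu(self.dec_bns[j](self.dec_convs[j](d)))
        out = ad.sigmoid(self.head(d))
        if probes is not None:
            probes["Output"] = out.data
        return out

    # -- inference on plain images --------------------------------------
    @property
    def input_size(self) -> int:
        return self.cfg.input_size

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one 2-D grayscale image in [0, 1].

        The image is resampled to the network's input size when needed and
        the map is resampled back, so output shape always equals input
        shape.  Runs in eval mode (running batch-norm statistics).
        """
        from skimage.transform import resize

        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 2:
            raise ValueError(f"predict expects a 2-D image, got shape {image.shape}")
        orig_shape = image.shape
        s = self.cfg.input_size
        if orig_shape != (s, s):
            image = resize(image, (s, s), order=1, preserve_range=True,
                           anti_aliasing=max(orig_shape) > s).astype(np.float32)
        was_training = self.training
        self.eval()
        try:
            prob = self.forward(image[None, None]).data[0, 0]
        finally:
            self.train(was_training)
        if orig_shape != (s, s):
            prob = resize(prob, orig_shape, order=1, preserve_range=True,
                          anti_aliasing=False).astype(np.float32)
        return np.clip(prob, 0.0, 1.0)


def build_dafdnet(cfg: NetworkConfig | None = None, seed: int = 0) -> DAFDNet:
    """Construct the network; ``seed`` fixes the weight initialization."""
    return DAFDNet(cfg or NetworkConfig(), seed=seed)


def mse_loss(pred, target):
    """Mean squared error.

    Accepts either the network's output :class:`Tensor` (returns a scalar
    ``Tensor`` on the autodiff graph) or two plain arrays (returns a float).
    Zero iff prediction equals target everywhere.
    """
    if isinstance(pred, Tensor):
        return ad.mse(pred, np.asarray(target, dtype=DTYPE))
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"mse shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


# ---------------------------------------------------------------------
# checkpoints: npz of parameters/buffers + embedded JSON config
# ---------------------------------------------------------------------

def save_checkpoint(model: DAFDNet, path: str | Path) -> None:
    state = model.state_dict()
    np.savez_compressed(str(path), __config__=np.array(model.cfg.to_json()), **state)


def load_checkpoint(path: str | Path) -> DAFDNet:
    with np.load(str(path)) as data:
        cfg = NetworkConfig.from_json(str(data["__config__"]))
        model = DAFDNet(cfg, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
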
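"""Training loop for the segmentation network.

The optimizer is Adam with a stepped warm-up: the learning rate starts at
``lr_init`` and grows by ``lr_step`` per epoch until it saturates at
``lr_max`` (defaults 1e-5 -> 4e-5 in 1e-5 steps).  Batches are drawn by
seeded shuffling; the loss is pixelwise mean-squared error between the
sigmoid probability map and the binary mask.  Because the Gabor path is a
fixed function of the input image, its responses are computed once per
dataset and reused every epoch.

Reproducibility: given the same (model seed, dataset, config) the loss
trace is identical run to run — all randomness flows through
``numpy.random.Generator(seed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .autodiff import DTYPE, Tensor
from .network import DAFDNet, mse_loss

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 12
    lr_init: float = 1e-5
    lr_max: float = 4e-5
    lr_step: float = 1e-5
    epochs: int = 100
    seed: int = 0
    shuffle: bool = True
    patience: int = 20
    prior_bias_init: bool = True

    def __post_init__(self) -> None:
        if self.lr_init > self.lr_max:
            raise ValueError("lr_init must not exceed lr_max")
        if self.lr_step < 0:
            raise ValueError("lr_step must be non-negative")
        if self.lr_step > 0:
            ratio = (self.lr_max - self.lr_init) / self.lr_step
            if abs(ratio - round(ratio)) > 1e-6:
                raise ValueError("(lr_max - lr_init) must be an integer multiple of lr_step")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Warm-up learning rate: ``lr_init + epoch*lr_step`` capped at ``lr_max``."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return min(cfg.lr_init + epoch * cfg.lr_step, cfg.lr_max)


class Adam:
    """Adam with bias-corrected first/second moments."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainHistory:
    """Per-epoch training records."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def append(self, epoch: int, train_loss: float, val_loss: float, lr: float) -> None:
        self.epoch.append(epoch)
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)
        self.lr.append(lr)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epoch, "train_loss": self.train_loss,
                             "val_loss": self.val_loss, "lr": self.lr})

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _stack(dataset) -> tuple[np.ndarray, np.ndarray]:
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    images, masks = [], []
    for image, mask in dataset:
        image = np.asarray(image, dtype=DTYPE)
        mask = np.asarray(mask, dtype=DTYPE)
        if image.shape != mask.shape:
            raise ValueError(f"mask shape {mask.shape} does not match image {image.shape}")
        images.append(image)
        masks.append(mask)
    return np.stack(images)[:, None], np.stack(masks)[:, None]


def _eval_loss(model: DAFDNet, images: np.ndarray, gab: np.ndarray,
               masks: np.ndarray, batch: int) -> float:
    model.eval()
    total = 0.0
    for s in range(0, len(images), batch):
        sl = slice(s, s + batch)
        pred = model.forward(images[sl], gab1=gab[sl])
        total += mse_loss(pred.data, masks[sl]) * (sl.indices(len(images))[1] - s)
    model.train()
    return total / len(images)


def train(model: DAFDNet, dataset, cfg: TrainConfig,
          val_dataset=None) -> tuple[DAFDNet, TrainHistory]:
    """Optimize ``model`` on (image, mask) pairs; returns it with a history.

    ``dataset`` and ``val_dataset`` are sequences of 2-D (image, mask)
    pairs whose side equals the model input size.  When a validation set is
    given, training stops early once validation loss has not improved for
    ``cfg.patience`` epochs (the best-epoch weights are NOT restored; the
    history records the full trace).
    """
    images, masks = _stack(dataset)
    if images.shape[-1] != model.cfg.input_size:
        raise ValueError(f"dataset images are {images.shape[-2:]}, "
                         f"model expects {model.cfg.input_size}")
    gab = model.gabor_features(images)
    val = None
    if val_dataset is not None:
        vimages, vmasks = _stack(val_dataset)
        val = (vimages, model.gabor_features(vimages), vmasks)

    if cfg.prior_bias_init:
        # Start the output sigmoid at the label prior: under MSE a head that
        # opens far from the target mean spends many steps crossing the
        # saturated region of the sigmoid before it can shape the map.
        p = float(np.clip(masks.mean(), 1e-3, 0.5))
        model.head.bias.data[:] = np.log(p / (1.0 - p))

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr_init)
    history = TrainHistory()
    model.train()
    best_val, stale = np.inf, 0
    n = len(images)
    batch = min(cfg.batch_size, n)
    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_loss = 0.0
        for s in range(0, n, batch):
            idx = order[s:s + batch]
            opt.zero_grad()
            pred = model.forward(images[idx], gab1=gab[idx])
            loss = mse_loss(pred, masks[idx])
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        epoch_loss /= n
        vloss = _eval_loss(model, *val, batch) if val is not None else float("nan")
        history.append(epoch, epoch_loss, vloss, opt.lr)
        log.info("epoch=%d lr=%.2e train_loss=%.5f val_loss=%.5f",
                 epoch, opt.lr, epoch_loss, vloss)
        if val is not None:
            if vloss < best_val - 1e-7:
                best_val, stale = vloss, 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    log.info("early stop at epoch %d (patience %d)", epoch, cfg.patience)
                    break
    return model, history
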
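"""Fixed 2-D Gabor wavelet filter bank.

The bank supplies the direction-aware path of the segmentation network: a
Gabor wavelet is a Gaussian-windowed complex plane wave, so each kernel is
an orientation- and frequency-selective band-pass filter.  Thin fracture
lines are locally oriented structures, and their energy concentrates in the
channels whose wave vector is perpendicular to the line — the property the
network exploits.

A kernel with orientation index ``u`` (of ``U``) and scale index ``v`` is
sampled at integer displacements ``z = (x, y)`` as::

    G(z) = (|k|^2 / sigma^2) * exp(-|k|^2 |z|^2 / (2 sigma^2))
           * (exp(i k.z) - exp(-sigma^2 / 2))

with envelope width ``sigma = 2*pi``, wave-vector magnitude
``k_v = (pi/2) / 2**(v-1)`` (an octave per scale step) and wave-vector angle
``phi_u = u*pi/U``.  The subtraction term removes the DC response of the
continuous filter; on a finite sampled grid an explicit discrete zero-mean
correction is applied on top (see :func:`make_gabor_kernel`), so every
kernel in a bank ignores constant image regions to numerical precision.

Kernel weights are fixed, never learned: the filter's optimal parameters
are set analytically, and the bank metadata (not the sampled grids) is what
serializes for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SIGMA = 2.0 * np.pi

_RESPONSE_MODES = ("magnitude", "real", "real+imag")


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a single Gabor kernel.

    ``U`` is the total orientation count, ``u`` the orientation index in
    ``[0, U)`` (``u = 0`` gives a horizontal wave vector), ``v >= 1`` the
    scale index, ``kernel_size`` the odd spatial support in pixels and
    ``sigma`` the envelope width (radians).
    """

    U: int = 8
    u: int = 0
    v: int = 1
    kernel_size: int = 15
    sigma: float = SIGMA

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError(f"kernel_size must be odd and positive, got {self.kernel_size}")
        if not 0 <= self.u < self.U:
            raise IndexError(f"orientation index u={self.u} outside [0, {self.U})")
        if self.v < 1:
            raise ValueError(f"scale index v must be >= 1, got {self.v}")

    @property
    def k_magnitude(self) -> float:
        """Wave-vector magnitude ``k_v = (pi/2)/2**(v-1)``; decreasing in v."""
        return (np.pi / 2.0) / 2.0 ** (self.v - 1)

    @property
    def angle(self) -> float:
        """Wave-vector angle ``phi_u = u*pi/U`` in ``[0, pi)``."""
        return self.u * np.pi / self.U


def make_gabor_kernel(params: GaborParams, dc_correct: bool = True) -> np.ndarray:
    """Sample one complex Gabor kernel on a ``kernel_size`` square grid.

    With ``dc_correct=False`` the analytic formula is returned verbatim;
    truncating and sampling it leaves a residual DC component (the
    continuous compensation term only cancels the infinite integral).  The
    default subtracts ``(sum Re G / sum env) * env`` from the real part,
    where ``env`` is the Gaussian envelope, which zeroes the kernel sum
    exactly while preserving the band-pass structure.  The imaginary part
    sums to zero already by odd symmetry of ``sin`` on the centred grid.
    """
    size, sigma = params.kernel_size, params.sigma
    half = size // 2
    rows, cols = np.mgrid[-half:half + 1, -half:half + 1]
    x = cols.astype(np.float64)   # displacement along +col
    y = rows.astype(np.float64)   # displacement along +row
    kmag = params.k_magnitude
    kx = kmag * np.cos(params.angle)
    ky = kmag * np.sin(params.angle)
    env = (kmag ** 2 / sigma ** 2) * np.exp(-(kmag ** 2) * (x ** 2 + y ** 2) / (2.0 * sigma ** 2))
    kernel = env * (np.exp(1j * (kx * x + ky * y)) - np.exp(-sigma ** 2 / 2.0))
    if dc_correct:
        kernel = kernel - (kernel.real.sum() / env.sum()) * env
    return kernel


@dataclass(frozen=True)
class GaborBank:
    """An ordered (scale-major, orientation-minor) collection of kernels."""

    kernels: tuple = field(repr=False)
    params: tuple = field(repr=False)
    U: int = 8
    scales: tuple = (1, 2, 3, 4)
    kernel_size: int = 15
    sigma: float = SIGMA
    response_mode: str = "magnitude"

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def n_channels(self) -> int:
        """Output channels of :func:`gabor_conv` under this bank's mode."""
        return 2 * len(self.kernels) if self.response_mode == "real+imag" else len(self.kernels)

    def orientation_of(self, index: int) -> int:
        """Orientation index u of the bank entry at ``index``."""
        return index % self.U

    def preferred_line_angle(self, u: int) -> float:
        """Image-plane angle (radians, mod pi) of the dark/bright line this
        orientation responds to most: perpendicular to the wave vector."""
        return (u * np.pi / self.U + np.pi / 2.0) % np.pi

    # -- metadata (de)serialization -----------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        meta = {"U": self.U, "scales": list(self.scales), "kernel_size": self.kernel_size,
                "sigma": self.sigma, "response_mode": self.response_mode}
        text = json.dumps(meta, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GaborBank":
        p = Path(str(source))
        meta = json.loads(p.read_text() if p.is_file() else str(source))
        return make_gabor_bank(U=meta["U"], scales=meta["scales"],
                               kernel_size=meta["kernel_size"],
                               response_mode=meta["response_mode"],
                               sigma=meta.get("sigma", SIGMA))


def make_gabor_bank(U: int = 8, scales=(1, 2, 3, 4), kernel_size: int = 15,
                    response_mode: str = "magnitude", sigma: float = SIGMA,
                    dc_correct: bool = True) -> GaborBank:
    """Build a bank of ``U x len(scales)`` kernels in (v-major, u-minor) order.

    The default 8 orientations x 4 scales gives the 32 direction/scale
    channels the network's Gabor path carries.
    """
    if U < 1:
        raise ValueError(f"orientation count U must be >= 1, got {U}")
    scales = tuple(int(v) for v in scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    if response_mode not in _RESPONSE_MODES:
        raise ValueError(f"response_mode must be one of {_RESPONSE_MODES}")
    params = tuple(GaborParams(U=U, u=u, v=v, kernel_size=kernel_size, sigma=sigma)
                   for v in scales for u in range(U))
    kernels = tuple(make_gabor_kernel(p, dc_correct=dc_correct) for p in params)
    return GaborBank(kernels=kernels, params=params, U=U, scales=scales,
                     kernel_size=kernel_size, sigma=sigma, response_mode=response_mode)


def _bank_weight_matrices(bank: GaborBank) -> tuple[np.ndarray, np.ndarray]:
    k = bank.kernel_size
    w = np.stack([kern for kern in bank.kernels]).reshape(len(bank), k * k)
    return w.real.astype(np.float32), w.imag.astype(np.float32)


def gabor_conv_batch(images: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Apply the bank to an (N, 1, H, W) float batch -> (N, C, H, W).

    Same-size cross-correlation via im2col with edge-replicate padding, so
    the zero-mean kernels keep their band-pass property (zero response to a
    constant image) up to the border.  The response per kernel is its
    complex magnitude under the default mode, its real part under ``real``,
    or both quadratures (doubling channels) under ``real+imag``.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or images.shape[1] != 1:
        raise ValueError(f"expected (N, 1, H, W) batch, got shape {images.shape}")
    n, _, h, w = images.shape
    half = bank.kernel_size // 2
    padded = np.pad(images, ((0, 0), (0, 0), (half, half), (half, half)), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(
        padded, (bank.kernel_size, bank.kernel_size), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, bank.kernel_size ** 2, h * w)
    w_re, w_im = _bank_weight_matrices(bank)
    re = np.matmul(w_re, cols).reshape(n, len(bank), h, w)
    if bank.response_mode == "real":
        return re
    im = np.matmul(w_im, cols).reshape(n, len(bank), h, w)
    if bank.response_mode == "real+imag":
        return np.concatenate([re, im], axis=1)
    return np.hypot(re, im)


def gabor_conv(image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Convolve a single 2-D image with every kernel -> (H, W, C) responses."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {image.shape}")
    out = gabor_conv_batch(image[None, None], bank)[0]
    return np.moveaxis(out, 0, -1)
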
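"""Synthetic radiograph phantoms with exact ground truth.

A phantom emulates the appearance that matters for thin-fracture detection
on a grayscale radiograph: a smooth bone-like background texture, one
brighter elliptical region standing in for the femoral neck, and a thin
(1-3 px) slightly curved dark line — the fracture — crossing that region at
a random orientation, plus additive sensor noise.  Each phantom carries the
exact ellipse mask and crack mask it was rendered from, so segmentation,
the two-stage pipeline and the overlap metrics are all testable without any
clinical data.

The augmentation procedure mirrors common radiograph augmentation: each
base image (with its masks, under the identical geometric transform) is
rotated by an angle drawn uniformly from +/-15 degrees and rescaled by the
fixed factor 0.95; eight variants per base image by default.  Dataset
construction splits at the *base-image* level so no augmented copy of a
training image can leak into the test side.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

DEG = np.pi / 180.0


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; ``None`` fields are drawn from ``seed``.

    ``crack_contrast`` is the peak fractional intensity drop along the
    crack (drawn from 0.03-0.10 by default); ``crack_width`` the nominal
    rendered width in pixels; ``background_scale`` the correlation length
    of the background texture; ``roi_brightness`` the intensity lift of the
    elliptical region over the background.
    """

    image_size: int = 256
    roi_center: tuple[float, float] | None = None
    roi_axes: tuple[float, float] | None = None
    roi_angle: float | None = None
    crack_orientation: float | None = None
    crack_width: int = 2
    crack_contrast: float | None = None
    background_scale: float | None = None
    noise_sd: float = 0.01
    roi_brightness: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 1 <= self.crack_width <= 3:
            raise ValueError(f"crack_width must be 1-3 px, got {self.crack_width}")
        if self.crack_contrast is not None and not 0.0 <= self.crack_contrast < 0.5:
            raise ValueError(f"crack_contrast must lie in [0, 0.5), got {self.crack_contrast}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def brightness_margin(self) -> float:
        """Guaranteed mean-intensity separation between ROI and background."""
        return 0.5 * self.roi_brightness


@dataclass
class PhantomRecord:
    """One rendered phantom: image in [0, 1], both masks, and metadata."""

    image: np.ndarray
    roi_mask: np.ndarray
    fracture_mask: np.ndarray
    meta: dict = field(default_factory=dict)


def _ellipse_mask(size: int, center, axes, angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _ellipse_radius(axes, psi: float) -> float:
    a, b = axes
    return a * b / np.hypot(b * np.cos(psi), a * np.sin(psi))


def _resolve(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    s = spec.image_size
    out = dataclasses.asdict(spec)
    if out["roi_center"] is None:
        out["roi_center"] = tuple(s / 2.0 + rng.uniform(-0.05, 0.05, 2) * s)
    if out["roi_axes"] is None:
        out["roi_axes"] = (s * rng.uniform(0.26, 0.32), s * rng.uniform(0.15, 0.20))
    if out["roi_angle"] is None:
        out["roi_angle"] = float(rng.uniform(-0.4, 0.4))
    if out["crack_orientation"] is None:
        out["crack_orientation"] = float(rng.uniform(0.0, np.pi))
    if out["crack_contrast"] is None:
        out["crack_contrast"] = float(rng.uniform(0.03, 0.10))
    if out["background_scale"] is None:
        out["background_scale"] = s / 8.0
    cr, cc = out["roi_center"]
    a = max(out["roi_axes"])
    if not (a <= cr <= s - a - 1 and a <= cc <= s - a - 1):
        # keep the whole ellipse inside the frame
        if a > s / 2 - 1:
            raise ValueError("roi_axes too large for image_size")
        out["roi_center"] = (float(np.clip(cr, a, s - a - 1)), float(np.clip(cc, a, s - a - 1)))
    return out


def _render_crack(size: int, geo: dict, rng: np.random.Generator) -> np.ndarray:
    """Rasterize a quadratic Bezier crack crossing the ellipse centre."""
    theta = geo["crack_orientation"]
    center = np.array(geo["roi_center"])
    psi = theta - geo["roi_angle"]
    reach = 0.75 * _ellipse_radius(geo["roi_axes"], psi)
    direction = np.array([np.sin(theta), np.cos(theta)])   # (row, col) step
    normal = np.array([np.cos(theta), -np.sin(theta)])
    p0, p1 = center - reach * direction, center + reach * direction
    bow = rng.uniform(-0.12, 0.12) * 2 * reach
    ctrl = center + bow * normal
    t = np.linspace(0.0, 1.0, max(64, int(8 * reach)))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t ** 2 * p1
    canvas = np.zeros((size, size), dtype=bool)
    ij = np.clip(np.round(pts).astype(int), 0, size - 1)
    canvas[ij[:, 0], ij[:, 1]] = True
    if geo["crack_width"] > 1:
        dist = ndimage.distance_transform_edt(~canvas)
        canvas = dist <= geo["crack_width"] / 2.0
    return canvas


def generate_phantom(spec: PhantomSpec) -> PhantomRecord:
    """Render one phantom; deterministic given ``spec`` (bit-identical)."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    geo = _resolve(spec, rng)

    texture = ndimage.gaussian_filter(rng.standard_normal((s, s)), geo["background_scale"] / 2.0)
    sd = texture.std()
    image = 0.35 + 0.06 * (texture / sd if sd > 0 else texture)

    roi_mask = _ellipse_mask(s, geo["roi_center"], geo["roi_axes"], geo["roi_angle"])
    image = image + spec.roi_brightness * ndimage.gaussian_filter(roi_mask.astype(np.float64), 1.5)

    fracture_mask = _render_crack(s, geo, rng) & roi_mask
    soft = ndimage.gaussian_filter(fracture_mask.astype(np.float64), 0.6)
    if soft.max() > 0:
        soft = soft / soft.max()
    image = image - geo["crack_contrast"] * soft

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, (s, s))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    meta = {k: geo[k] for k in ("roi_center", "roi_axes", "roi_angle", "crack_orientation",
                                "crack_width", "crack_contrast", "background_scale",
                                "noise_sd", "seed")}
    meta["image_size"] = s
    return PhantomRecord(image=image, roi_mask=roi_mask, fracture_mask=fracture_mask, meta=meta)


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentSpec:
    """Rotation range in degrees (sampled uniformly), fixed rescale factor,
    and the number of variants generated per base image."""

    rotation_range: tuple[float, float] = (-15.0, 15.0)
    scale_factor: float = 0.95
    n_variants: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.rotation_range[0] > self.rotation_range[1]:
            raise ValueError("rotation_range must be (low, high)")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    def sample_angles(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(self.seed)
        return rng.uniform(self.rotation_range[0], self.rotation_range[1], n)


def _affine_about_center(size: int, angle_deg: float, scale: float):
    """Inverse-mapping matrix/offset for rotate-then-scale about the centre."""
    th = angle_deg * DEG
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    matrix = rot.T / scale  # inverse of scale * rot
    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    offset = center - matrix @ center
    return matrix, offset


def transform_like(arr: np.ndarray, angle_deg: float, scale: float,
                   binary: bool = False) -> np.ndarray:
    """Apply the augmentation transform to an image or (binary) mask."""
    matrix, offset = _affine_about_center(arr.shape[0], angle_deg, scale)
    out = ndimage.affine_transform(arr.astype(np.float64), matrix, offset=offset,
                                   order=1, mode="nearest")
    if binary:
        return out > 0.5
    return out.astype(np.float32)


def augment(record: PhantomRecord, spec: AugmentSpec) -> list[PhantomRecord]:
    """Produce ``spec.n_variants`` rotated/rescaled copies of a phantom.

    The identical geometric transform is applied to the image and both
    masks; masks are re-binarized at 0.5 after interpolation.
    """
    rng = np.random.default_rng(spec.seed)
    angles = spec.sample_angles(spec.n_variants, rng)
    variants = []
    for i, angle in enumerate(angles):
        meta = dict(record.meta)
        meta.update(augment_angle=float(angle), augment_scale=spec.scale_factor, variant=i)
        variants.append(PhantomRecord(
            image=transform_like(record.image, angle, spec.scale_factor),
            roi_mask=transform_like(record.roi_mask, angle, spec.scale_factor, binary=True),
            fracture_mask=transform_like(record.fracture_mask, angle, spec.scale_factor,
                                         binary=True),
            meta=meta))
    return variants


# ---------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------

def make_dataset(n_base: int, split_fraction: float = 0.78125, *,
                 image_size: int = 256, n_variants: int = 8, seed: int = 0,
                 spec_overrides: dict | None = None,
                 ) -> tuple[list[PhantomRecord], list[PhantomRecord]]:
    """Generate ``n_base`` phantoms, augment each, split by base image.

    Returns ``(train, test)`` lists of augmented records.  ``split_fraction``
    is the train share of *base images* (default 375/480 = 0.78125, which at
    8 variants per base yields a 3000/840 split of 480 bases).  All variants
    of one base land on the same side, so the split is leakage-free by
    construction; ``meta['base_id']`` carries the provenance.
    """
    if n_base < 2:
        raise ValueError("n_base must be >= 2")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    n_train = int(round(split_fraction * n_base))
    if not 1 <= n_train <= n_base - 1:
        raise ValueError(f"degenerate split: {n_train} of {n_base} bases on the train side")

    rng = np.random.default_rng(seed)
    base_seeds = rng.integers(0, 2 ** 31 - 1, size=n_base)
    aug_seeds = rng.integers(0, 2 ** 31 - 1, size=n_base)
    order = rng.permutation(n_base)
    train_ids = set(int(i) for i in order[:n_train])

    train: list[PhantomRecord] = []
    test: list[PhantomRecord] = []
    overrides = spec_overrides or {}
    for i in range(n_base):
        spec = PhantomSpec(image_size=image_size, seed=int(base_seeds[i]), **overrides)
        base = generate_phantom(spec)
        base.meta["base_id"] = i
        side = train if i in train_ids else test
        for variant in augment(base, AugmentSpec(n_variants=n_variants, seed=int(aug_seeds[i]))):
            variant.meta["split"] = "train" if i in train_ids else "test"
            side.append(variant)
    return train, test


def as_pairs(records: Sequence[PhantomRecord], target: str = "fracture",
             ) -> list[tuple[np.ndarray, np.ndarray]]:
    """View records as (image, mask) training pairs for the chosen stage."""
    if target not in ("fracture", "roi"):
        raise ValueError("target must be 'fracture' or 'roi'")
    key = "fracture_mask" if target == "fracture" else "roi_mask"
    return [(r.image, getattr(r, key).astype(np.float32)) for r in records]
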
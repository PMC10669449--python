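"""Pixel-coordinate geometry shared by the pipeline and the metrics.

Boxes are axis-aligned, 0-based and half-open: ``BBox(r0, c0, r1, c1)``
covers rows ``r0..r1-1`` and columns ``c0..c1-1``; an empty box has
``r1 == r0`` or ``c1 == c0``.  ``CropTransform`` records how a sub-region
of a full image was resampled into a fixed-size square crop (uniform scale
plus centering pads) and maps boxes exactly in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class BBox:
    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 < self.row0 or self.col1 < self.col0:
            raise ValueError(f"malformed box {self}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def is_empty(self) -> bool:
        return self.area == 0

    def astuple(self) -> tuple[int, int, int, int]:
        return (self.row0, self.col0, self.row1, self.col1)

    def clip(self, height: int, width: int) -> "BBox":
        r0 = min(max(self.row0, 0), height)
        r1 = min(max(self.row1, 0), height)
        c0 = min(max(self.col0, 0), width)
        c1 = min(max(self.col1, 0), width)
        return BBox(r0, c0, max(r1, r0), max(c1, c0))

    def pad(self, margin: float) -> "BBox":
        """Grow by ``margin`` (fraction of each side; at least 1 px when a
        positive margin is requested)."""
        if margin == 0:
            return self
        mr = max(1, int(round(margin * self.height)))
        mc = max(1, int(round(margin * self.width)))
        return BBox(self.row0 - mr, self.col0 - mc, self.row1 + mr, self.col1 + mc)

    @classmethod
    def empty(cls) -> "BBox":
        return cls(0, 0, 0, 0)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "BBox":
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        if rows.size == 0:
            return cls.empty()
        return cls(int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


def as_bbox(box) -> BBox:
    return box if isinstance(box, BBox) else BBox(*box)


def largest_component(mask: np.ndarray) -> np.ndarray | None:
    """Largest 8-connected foreground component; ``None`` for an empty mask.

    Equal-size ties go to the component whose first pixel comes earliest in
    row-major order.
    """
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        flat = labels.ravel()
        best = sorted(best, key=lambda lab: np.flatnonzero(flat == lab)[0])
    return labels == best[0]


@dataclass(frozen=True)
class CropTransform:
    """Resampling of full-image region ``box`` into an ``out_size`` square.

    The region is scaled uniformly by ``scale`` (so aspect is preserved)
    and centred with ``pad_row``/``pad_col`` pixels of padding.
    """

    box: BBox
    scale: float
    pad_row: int
    pad_col: int
    out_size: int

    def full_to_crop(self, b: BBox) -> BBox:
        r0 = (b.row0 - self.box.row0) * self.scale + self.pad_row
        c0 = (b.col0 - self.box.col0) * self.scale + self.pad_col
        r1 = (b.row1 - self.box.row0) * self.scale + self.pad_row
        c1 = (b.col1 - self.box.col0) * self.scale + self.pad_col
        return BBox(*(int(round(v)) for v in (r0, c0, r1, c1))).clip(self.out_size, self.out_size)

    def crop_to_full(self, b: BBox) -> BBox:
        r0 = (b.row0 - self.pad_row) / self.scale + self.box.row0
        c0 = (b.col0 - self.pad_col) / self.scale + self.box.col0
        r1 = (b.row1 - self.pad_row) / self.scale + self.box.row0
        c1 = (b.col1 - self.pad_col) / self.scale + self.box.col0
        return BBox(*(int(round(v)) for v in (r0, c0, r1, c1)))


def resample_crop(image: np.ndarray, box: BBox, out_size: int,
                  ) -> tuple[np.ndarray, CropTransform]:
    """Cut ``box`` from ``image`` and fit it into an ``out_size`` square.

    The longer side is stretched to ``out_size``; the shorter side keeps
    the aspect ratio and is centred with constant padding at the region's
    mean intensity.
    """
    from skimage.transform import resize

    if box.is_empty:
        raise ValueError("cannot resample an empty box")
    region = image[box.row0:box.row1, box.col0:box.col1].astype(np.float32)
    scale = out_size / max(box.height, box.width)
    new_h = max(1, int(round(box.height * scale)))
    new_w = max(1, int(round(box.width * scale)))
    resized = resize(region, (new_h, new_w), order=1, preserve_range=True,
                     anti_aliasing=scale < 1).astype(np.float32)
    canvas = np.full((out_size, out_size), float(region.mean()), dtype=np.float32)
    pad_row = (out_size - new_h) // 2
    pad_col = (out_size - new_w) // 2
    canvas[pad_row:pad_row + new_h, pad_col:pad_col + new_w] = resized
    return canvas, CropTransform(box=box, scale=scale, pad_row=pad_row,
                                 pad_col=pad_col, out_size=out_size)
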
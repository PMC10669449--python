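"""Region-overlap evaluation: box IOU, mask Dice and Jaccard, and binned
summaries of detection quality.

Conventions: IOU is computed on axis-aligned bounding rectangles
(intersection area over union area, half-open pixel semantics) while Dice
``2|A∩B|/(|A|+|B|)`` and Jaccard ``|A∩B|/|A∪B|`` are computed on pixel
masks; the two are linked by the identity ``J = D/(2-D)``.  When both
masks are empty the mask metrics are defined as 1 (perfect agreement on
"nothing there"); when exactly one is empty they are 0.  Summaries bin the
IOU values at {0.2, 0.5} with lower-inclusive boundaries and report
percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import BBox, as_bbox


def box_iou(a, b) -> float:
    """Intersection-over-union of two half-open boxes; 0 when disjoint or
    either box is empty."""
    a, b = as_bbox(a), as_bbox(b)
    if a.is_empty or b.is_empty:
        return 0.0
    ih = min(a.row1, b.row1) - max(a.row0, b.row0)
    iw = min(a.col1, b.col1) - max(a.col0, b.col0)
    if ih <= 0 or iw <= 0:
        return 0.0
    inter = ih * iw
    return inter / (a.area + b.area - inter)


def _mask_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return int((a & b).sum()), int(a.sum()), int(b.sum())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient ``2|A∩B|/(|A|+|B|)`` of two binary masks."""
    inter, na, nb = _mask_counts(a, b)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index ``|A∩B|/|A∪B|`` of two binary masks."""
    inter, na, nb = _mask_counts(a, b)
    union = na + nb - inter
    if union == 0:
        return 1.0
    return inter / union


@dataclass(frozen=True)
class EvalRecord:
    image_id: str
    iou: float
    dice: float
    jaccard: float
    detected: bool

    def __post_init__(self) -> None:
        for name in ("iou", "dice", "jaccard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def evaluate_pair(image_id: str, pred_mask: np.ndarray, label_mask: np.ndarray,
                  pred_box: BBox | None = None, label_box: BBox | None = None,
                  ) -> EvalRecord:
    """Score one prediction: boxes (derived from the masks when not given)
    feed the IOU; the masks feed Dice/Jaccard."""
    pred_box = pred_box if pred_box is not None else BBox.from_mask(pred_mask)
    label_box = label_box if label_box is not None else BBox.from_mask(label_mask)
    return EvalRecord(image_id=image_id,
                      iou=box_iou(pred_box, label_box),
                      dice=dice(pred_mask, label_mask),
                      jaccard=jaccard(pred_mask, label_mask),
                      detected=bool(np.asarray(pred_mask, dtype=bool).any()))


@dataclass(frozen=True)
class EvalSummary:
    """Cohort summary on the percentage scale (0-100).

    ``pct_iou_high/mid/low`` are the shares of cases with IOU in
    [0.5, 1.0], [0.2, 0.5) and [0, 0.2); they sum to 100.
    """

    n: int
    pct_iou_high: float
    pct_iou_mid: float
    pct_iou_low: float
    mean_iou: float
    mean_dice: float
    mean_jaccard: float
    detection_rate: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def summarize(records: Sequence[EvalRecord]) -> EvalSummary:
    """Bin IOUs at {0.2, 0.5} (lower-inclusive: exactly 0.5 counts as high)
    and average the metrics; all values emitted as percentages."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record collection")
    ious = np.array([r.iou for r in records], dtype=np.float64)
    high = float((ious >= 0.5).mean())
    mid = float(((ious >= 0.2) & (ious < 0.5)).mean())
    low = float((ious < 0.2).mean())
    return EvalSummary(
        n=len(records),
        pct_iou_high=100.0 * high,
        pct_iou_mid=100.0 * mid,
        pct_iou_low=100.0 * low,
        mean_iou=100.0 * float(ious.mean()),
        mean_dice=100.0 * float(np.mean([r.dice for r in records])),
        mean_jaccard=100.0 * float(np.mean([r.jaccard for r in records])),
        detection_rate=100.0 * float(np.mean([r.detected for r in records])),
    )


def records_to_dataframe(records: Sequence[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
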
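"""Two-phase detection: locate the femoral-neck region, then find the
fracture inside it.

Phase 1 runs a segmentation model over the whole image, thresholds its
probability map at 0.5, keeps the largest 8-connected component and crops
its bounding box (padded by a 10% margin) out of the image, resampled to
the detection network's input size with aspect preserved.  Phase 2 runs
the fracture model on that crop and post-processes the same way.  The crop
transform is recorded exactly, so the detected box maps back to full-image
coordinates within a pixel per corner.

Restricting phase 2 to the localized region shrinks the problem the
detector sees and excludes look-alike structures elsewhere in the frame.

Models are duck-typed: anything with ``predict(image_2d) -> prob_2d``
(same shape, values in [0, 1]) and an ``input_size`` attribute works, which
keeps the pipeline testable with stub models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BBox, CropTransform, largest_component, resample_crop


@dataclass
class RoiResult:
    """Phase-1 output; ``found=False`` flags an empty thresholded map."""

    found: bool
    roi_mask: np.ndarray
    crop_box: BBox
    crop: np.ndarray | None = None
    transform: CropTransform | None = field(default=None, repr=False)


@dataclass
class DetectionResult:
    """Phase-2 output in crop coordinates, plus the full-image box once the
    pipeline has applied the inverse crop transform."""

    found_roi: bool
    found_fracture: bool
    fracture_mask_crop: np.ndarray | None
    fracture_box_crop: BBox
    fracture_box_full: BBox
    max_probability: float
    crop_box: BBox = BBox.empty()

    def to_dict(self) -> dict:
        return {
            "found_roi": self.found_roi,
            "found_fracture": self.found_fracture,
            "fracture_box_crop": list(self.fracture_box_crop.astuple()),
            "fracture_box_full": list(self.fracture_box_full.astuple()),
            "crop_box": list(self.crop_box.astuple()),
            "max_probability": float(self.max_probability),
        }


def localize_roi(image: np.ndarray, roi_model, threshold: float = 0.5,
                 margin: float = 0.10, out_size: int | None = None) -> RoiResult:
    """Find the region of interest and cut a square crop around it.

    The model's probability map is thresholded at ``threshold``; the
    largest connected component wins; its bounding box, padded by
    ``margin`` of each side, is resampled to ``out_size`` (default: the
    model's own input size).  An all-background map yields a "no ROI"
    result rather than an exception.
    """
    image = np.asarray(image, dtype=np.float32)
    out_size = out_size or roi_model.input_size
    prob = roi_model.predict(image)
    component = largest_component(prob >= threshold)
    if component is None:
        return RoiResult(found=False, roi_mask=np.zeros(image.shape, dtype=bool),
                         crop_box=BBox.empty())
    box = BBox.from_mask(component).pad(margin).clip(*image.shape)
    crop, transform = resample_crop(image, box, out_size)
    return RoiResult(found=True, roi_mask=component, crop_box=box,
                     crop=crop, transform=transform)


def detect_fracture(crop: np.ndarray, frac_model,
                    threshold: float = 0.5) -> DetectionResult:
    """Segment the fracture on a crop; empty threshold output yields a
    "no fracture" result (the map's maximum is still reported)."""
    crop = np.asarray(crop, dtype=np.float32)
    prob = frac_model.predict(crop)
    max_prob = float(prob.max())
    component = largest_component(prob >= threshold)
    if component is None:
        return DetectionResult(found_roi=True, found_fracture=False,
                               fracture_mask_crop=np.zeros(crop.shape, dtype=bool),
                               fracture_box_crop=BBox.empty(),
                               fracture_box_full=BBox.empty(),
                               max_probability=max_prob)
    return DetectionResult(found_roi=True, found_fracture=True,
                           fracture_mask_crop=component,
                           fracture_box_crop=BBox.from_mask(component),
                           fracture_box_full=BBox.empty(),
                           max_probability=max_prob)


def run_pipeline(image: np.ndarray, roi_model, frac_model,
                 roi_threshold: float = 0.5, frac_threshold: float = 0.5,
                 margin: float = 0.10) -> DetectionResult:
    """Compose localization and detection with exact coordinate back-mapping."""
    image = np.asarray(image, dtype=np.float32)
    roi = localize_roi(image, roi_model, threshold=roi_threshold, margin=margin,
                       out_size=frac_model.input_size)
    if not roi.found:
        return DetectionResult(found_roi=False, found_fracture=False,
                               fracture_mask_crop=None,
                               fracture_box_crop=BBox.empty(),
                               fracture_box_full=BBox.empty(),
                               max_probability=0.0)
    det = detect_fracture(roi.crop, frac_model, threshold=frac_threshold)
    det.crop_box = roi.crop_box
    if det.found_fracture:
        det.fracture_box_full = roi.transform.crop_to_full(
            det.fracture_box_crop).clip(*image.shape)
    return det
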
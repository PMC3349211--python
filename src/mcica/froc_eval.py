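"""Scoring generated ROIs against ground truth; FROC curves.

Per-image tagging follows the standard region-overlap convention: a generated
ROI is a true positive if its mask shares at least one pixel (configurable
minimum overlap fraction) with any malignant ground-truth region, otherwise a
false positive; a malignant region overlapped by no ROI is a false negative;
a healthy image on which no ROI is produced is one true negative.

Sensitivity is TP/(TP+FN) — the proportion of actual positives correctly
identified — and FPi is the mean number of false positives per image,
FP/#images.  A FROC curve traces (FPi, sensitivity) across analyzer rules of
increasing strictness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import (AnalyzerRule, MLPModel, DetectionMap,
                         detection_map_from_outputs, output_map)
from .errors import ValidationError
from .ica_features import ICABasis
from .io_calibration import GroundTruthRegion, ODImage
from .roi_builder import ROI, build_rois, density_map, filter_spurious, label_objects

__all__ = [
    "OutcomeCounts",
    "FROCPoint",
    "match_rois",
    "sensitivity",
    "fpi",
    "froc_curve",
    "evaluate_detections",
]


@dataclass(frozen=True)
class OutcomeCounts:
    """TP/FP/FN/TN tallies over one or more images."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    n_images: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn, self.n_images) < 0:
            raise ValidationError("all outcome counts must be ≥ 0")
        if self.tn > self.n_images:
            raise ValidationError("tn cannot exceed the number of images")

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        return OutcomeCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn,
            self.tn + other.tn, self.n_images + other.n_images)


@dataclass(frozen=True)
class FROCPoint:
    """One operating point: an analyzer rule's sensitivity and FPi."""

    analyzer: str
    sensitivity: float
    fpi: float
    counts: OutcomeCounts
    positive_pixels: int = 0


def match_rois(
    rois: Sequence[ROI],
    ground_truth_regions: Sequence[GroundTruthRegion],
    image_shape: tuple[int, int],
    min_overlap_frac: float = 0.0,
) -> OutcomeCounts:
    """Tag one image's ROIs against its (possibly empty) ground truth.

    With the default ``min_overlap_frac=0`` a single shared pixel suffices for
    an overlap.  A single ROI overlapping several truth regions counts as one
    TP; unmatched malignant regions each count as one FN.
    """
    malignant = [reg for reg in ground_truth_regions if reg.pathology == "malignant"]
    truth_masks = []
    for reg in malignant:
        m = reg.to_mask(image_shape)
        if m.shape != tuple(image_shape):
            raise ValidationError("truth mask shape does not match image shape")
        truth_masks.append(m)

    tp = fp = 0
    matched = np.zeros(len(malignant), dtype=bool)
    for roi in rois:
        if roi.mask.shape != tuple(image_shape):
            raise ValidationError("ROI mask shape does not match image shape")
        roi_area = int(roi.mask.sum())
        hit = False
        for j, tm in enumerate(truth_masks):
            overlap = int(np.count_nonzero(roi.mask & tm))
            if overlap > 0 and (min_overlap_frac <= 0.0
                                or overlap >= min_overlap_frac * roi_area):
                hit = True
                matched[j] = True
        if hit:
            tp += 1
        else:
            fp += 1
    fn = int(np.count_nonzero(~matched))
    healthy = len(malignant) == 0
    tn = 1 if healthy and len(rois) == 0 else 0
    return OutcomeCounts(tp=tp, fp=fp, fn=fn, tn=tn, n_images=1)


def sensitivity(counts: OutcomeCounts) -> float:
    """True-positive proportion TP/(TP+FN)."""
    if counts.tp + counts.fn == 0:
        raise ValidationError("sensitivity undefined: no actual positives")
    return counts.tp / (counts.tp + counts.fn)


def fpi(counts: OutcomeCounts) -> float:
    """Mean false positives per image, FP/#images."""
    if counts.n_images == 0:
        raise ValidationError("FPi undefined over zero images")
    return counts.fp / counts.n_images


def evaluate_detections(
    detections: DetectionMap,
    truth_regions: Sequence[GroundTruthRegion],
    pixel_size_um: float,
    min_object_px: int = 2,
    max_object_px: int | float = 100,
    threshold: int = 3,
    min_overlap_frac: float = 0.0,
) -> tuple[OutcomeCounts, list[ROI]]:
    """Run one detection map through the ROI builder and tag the outcome."""
    filtered = filter_spurious(detections, min_object_px, max_object_px)
    objects = label_objects(filtered)
    dmap = density_map(objects, filtered.mask.shape, pixel_size_um)
    rois = build_rois(dmap, objects, threshold)
    counts = match_rois(rois, truth_regions, filtered.mask.shape,
                        min_overlap_frac)
    return counts, rois


def froc_curve(
    model: MLPModel,
    basis: ICABasis,
    images: Sequence[ODImage],
    truths: Sequence[Sequence[GroundTruthRegion]],
    analyzer_set: Sequence[AnalyzerRule],
    positive_classes: Sequence[int] = (0, 1),
    min_object_px: int = 2,
    max_object_px: int | float = 100,
    threshold: int = 3,
) -> list[FROCPoint]:
    """One FROC operating point per analyzer rule, sorted by FPi.

    Network activation maps are computed once per image and reused across
    analyzers, so the sweep costs one diagnosis pass plus cheap thresholding.
    """
    if not analyzer_set:
        raise ValidationError("analyzer_set must be non-empty")
    if len(images) != len(truths):
        raise ValidationError("images and truths must align")
    cached = [output_map(model, basis, img) for img in images]

    points = []
    for rule in analyzer_set:
        total = OutcomeCounts()
        pos_pixels = 0
        for (acts, margin), img, truth in zip(cached, images, truths):
            det = detection_map_from_outputs(
                acts, margin, rule, positive_classes, img.pixels.shape,
                meta=img.meta)
            pos_pixels += int(det.mask.sum())
            pixel_size = img.meta.pixel_size_um if img.meta else 43.5
            counts, _ = evaluate_detections(
                det, truth, pixel_size, min_object_px, max_object_px, threshold)
            total = total + counts
        points.append(FROCPoint(
            analyzer=rule.describe(),
            sensitivity=sensitivity(total) if total.tp + total.fn else float("nan"),
            fpi=fpi(total),
            counts=total,
            positive_pixels=pos_pixels,
        ))
    return sorted(points, key=lambda p: p.fpi)
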
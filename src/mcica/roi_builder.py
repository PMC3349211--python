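"""From pixel detections to disjoint regions of interest.

A clinically suspicious configuration is ≥3 microcalcifications within about
1 cm².  The builder therefore (1) discards spurious detections — connected
components below a minimum pixel size (isolated pixels) or above an artifact
guard; (2) labels the surviving 8-connected components as microcalcification
objects with sizes and centroids; (3) computes, for every pixel, the number of
object centroids inside the 1 cm² neighbourhood centred on it (a density map);
and (4) thresholds the density map (counts ≥ 3 by default) and takes connected
components of the surviving support as disjoint ROIs, attaching the objects
whose centroids fall inside each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .classifier import DetectionMap
from .errors import GeometryError, ValidationError

__all__ = [
    "MicrocalcObject",
    "DensityMap",
    "ROI",
    "filter_spurious",
    "label_objects",
    "density_map",
    "build_rois",
    "neighbourhood_side_px",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass
class MicrocalcObject:
    """One detected microcalcification: a connected detection component."""

    object_id: int
    pixel_count: int
    centroid: tuple[float, float]  # (row, col)
    bounding_box: tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax) inclusive

    @property
    def binned_centroid(self) -> tuple[int, int]:
        return int(round(self.centroid[0])), int(round(self.centroid[1]))


@dataclass
class DensityMap:
    """Per-pixel count of microcalcification objects in the 1 cm² neighbourhood."""

    counts: np.ndarray
    neighbourhood_px: int
    neighbourhood_area_cm2: float = 1.0


@dataclass
class ROI:
    """One disjoint suspicious region."""

    roi_id: int
    mask: np.ndarray
    member_objects: list[int]
    peak_density: int


def filter_spurious(
    detections: DetectionMap,
    min_object_px: int = 2,
    max_object_px: int | float = 100,
) -> DetectionMap:
    """Remove isolated-pixel detections and oversized artifacts.

    8-connected components with fewer than ``min_object_px`` pixels or more
    than ``max_object_px`` pixels are dropped.
    """
    if min_object_px < 1:
        raise ValidationError("min_object_px must be ≥ 1")
    labels, n = ndimage.label(detections.mask, structure=_EIGHT)
    if n == 0:
        return DetectionMap(detections.mask.copy(), detections.meta,
                            detections.margin_px)
    sizes = np.bincount(labels.ravel())[1:]
    keep = (sizes >= min_object_px) & (sizes <= max_object_px)
    mask = keep[labels - 1] & (labels > 0)
    return DetectionMap(mask=mask, meta=detections.meta,
                        margin_px=detections.margin_px)


def label_objects(detections: DetectionMap) -> list[MicrocalcObject]:
    """8-connected components of a (filtered) detection map, with geometry."""
    labels, n = ndimage.label(detections.mask, structure=_EIGHT)
    if n == 0:
        return []
    objects = []
    centroids = ndimage.center_of_mass(detections.mask, labels, range(1, n + 1))
    slices = ndimage.find_objects(labels)
    sizes = np.bincount(labels.ravel())[1:]
    for i in range(n):
        sr, sc = slices[i]
        objects.append(MicrocalcObject(
            object_id=i,
            pixel_count=int(sizes[i]),
            centroid=(float(centroids[i][0]), float(centroids[i][1])),
            bounding_box=(sr.start, sc.start, sr.stop - 1, sc.stop - 1),
        ))
    return objects


def neighbourhood_side_px(pixel_size_um: float) -> int:
    """Pixel side of the 1 cm neighbourhood window, forced odd."""
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be positive")
    side = int(round(10000.0 / pixel_size_um))
    if side < 1:
        raise GeometryError("1 cm neighbourhood is below one pixel")
    return side + 1 if side % 2 == 0 else side


def density_map(
    objects: Sequence[MicrocalcObject],
    image_shape: tuple[int, int],
    pixel_size_um: float,
    shape: str = "square",
) -> DensityMap:
    """Count object centroids in the 1 cm² neighbourhood of every pixel.

    The default neighbourhood is the square of physical side 1 cm (area exactly
    1 cm²) centred on the pixel; ``shape='disc'`` uses a disc of area 1 cm²
    instead.  Object centroids are binned to their nearest pixel.  Windows are
    clipped at image borders (counts only include in-image centroids).
    """
    side = neighbourhood_side_px(pixel_size_um)
    if side > min(image_shape):
        raise GeometryError(
            f"1 cm neighbourhood ({side}px) exceeds the image {image_shape}")
    points = np.zeros(image_shape, dtype=np.int64)
    for obj in objects:
        r, c = obj.binned_centroid
        r = min(max(r, 0), image_shape[0] - 1)
        c = min(max(c, 0), image_shape[1] - 1)
        points[r, c] += 1
    if shape == "square":
        counts = _box_sum(points, side)
    elif shape == "disc":
        radius_px = np.sqrt(1e8 / np.pi) / pixel_size_um  # disc of area 1 cm²
        ext = int(np.ceil(radius_px))
        rr, cc = np.mgrid[-ext:ext + 1, -ext:ext + 1]
        kernel = (rr ** 2 + cc ** 2 <= radius_px ** 2).astype(float)
        conv = fftconvolve(points.astype(float), kernel, mode="same")
        counts = np.rint(conv).astype(np.int64)
    else:
        raise ValidationError(f"unknown neighbourhood shape {shape!r}")
    return DensityMap(counts=counts, neighbourhood_px=side)


def _box_sum(points: np.ndarray, side: int) -> np.ndarray:
    """Sliding square-window sum via an integral image, zero-padded at borders."""
    half = side // 2
    integral = np.zeros((points.shape[0] + 1, points.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(points, axis=0), axis=1, out=integral[1:, 1:])
    rows, cols = points.shape
    r = np.arange(rows)
    c = np.arange(cols)
    r0 = np.clip(r - half, 0, rows)
    r1 = np.clip(r + half + 1, 0, rows)
    c0 = np.clip(c - half, 0, cols)
    c1 = np.clip(c + half + 1, 0, cols)
    return (integral[np.ix_(r1, c1)] - integral[np.ix_(r0, c1)]
            - integral[np.ix_(r1, c0)] + integral[np.ix_(r0, c0)])


def build_rois(
    dmap: DensityMap,
    objects: Sequence[MicrocalcObject],
    threshold: int = 3,
) -> list[ROI]:
    """Threshold the density map and group the support into disjoint ROIs.

    Support pixels with ``counts ≥ threshold`` are grouped 8-connected; each
    component becomes one ROI and is assigned the objects whose (binned)
    centroids lie inside it.
    """
    if threshold < 1:
        raise ValidationError("threshold must be ≥ 1")
    support = dmap.counts >= threshold
    labels, n = ndimage.label(support, structure=_EIGHT)
    rois = []
    for i in range(1, n + 1):
        mask = labels == i
        members = [obj.object_id for obj in objects
                   if mask[obj.binned_centroid[0], obj.binned_centroid[1]]]
        rois.append(ROI(
            roi_id=i - 1,
            mask=mask,
            member_objects=members,
            peak_density=int(dmap.counts[mask].max()),
        ))
    return rois
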
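"""Image input and optical-density calibration.

Digitized film mammograms come off different scanners with different grey-level
mappings, so every downstream stage of the pipeline works in optical density
(OD) rather than raw grey levels.  This module reads single-channel raster
images (PNG/TIFF/``.npy``) together with a JSON metadata sidecar, converts grey
levels to OD through an affine calibration (linear in grey, or linear in
log10(grey)), and loads radiologist-style ground-truth regions given either as
closed polygons or as binary masks.

Conventions: pixel coordinates are 0-based, row-major ``(row, col)``; polygons
use the same convention and are rasterized inclusively of boundary pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import CalibrationError, ValidationError

__all__ = [
    "CalibrationSpec",
    "ImageMeta",
    "ODImage",
    "GroundTruthRegion",
    "read_image",
    "to_optical_density",
    "read_ground_truth",
    "write_image",
]

#: default clamp range for optical density, covering the physical range of film
DEFAULT_OD_CLIP = (0.0, 4.0)
#: grey-level floor applied before log10 in log-mode calibration
DEFAULT_LOG_FLOOR = 1.0


@dataclass(frozen=True)
class CalibrationSpec:
    """Affine grey-level → optical-density calibration.

    ``linear`` mode: ``od = slope * grey + intercept``.
    ``log`` mode:    ``od = slope * log10(max(grey, log_floor)) + intercept``.
    The result is clamped to ``od_clip``.
    """

    mode: Literal["linear", "log"]
    slope: float
    intercept: float
    od_clip: tuple[float, float] = DEFAULT_OD_CLIP
    log_floor: float = DEFAULT_LOG_FLOOR

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "log"):
            raise ValidationError(f"unknown calibration mode {self.mode!r}")
        if not (math.isfinite(self.slope) and self.slope != 0.0):
            raise ValidationError("calibration slope must be finite and nonzero")
        if not math.isfinite(self.intercept):
            raise ValidationError("calibration intercept must be finite")
        lo, hi = self.od_clip
        if not lo < hi:
            raise ValidationError("od_clip minimum must be below maximum")
        if self.mode == "log" and self.log_floor <= 0:
            raise ValidationError("log_floor must be positive")


@dataclass(frozen=True)
class ImageMeta:
    """Per-image physical and acquisition metadata."""

    pixel_size_um: float
    bit_depth: int
    calibration: CalibrationSpec
    patient_age: int | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")
        if not 1 <= int(self.bit_depth) <= 16:
            raise ValidationError("bit_depth must be in [1, 16]")
        if self.patient_age is not None and not self.patient_age > 0:
            raise ValidationError("patient_age must be a positive integer")


@dataclass
class ODImage:
    """A 2-D optical-density image plus its metadata."""

    pixels: np.ndarray
    meta: ImageMeta | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class GroundTruthRegion:
    """One annotated region: a closed polygon or a binary mask.

    Polygons are stored as ``(row, col)`` vertex lists with the closing vertex
    (equal to the first) removed; ``to_mask`` rasterizes them inclusively of
    boundary pixels.
    """

    region_id: str
    pathology: Literal["malignant", "benign", "normal-structure"]
    polygon: np.ndarray | None = None  # (n_vertices, 2) as (row, col)
    mask: np.ndarray | None = None
    _mask_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask is None):
            raise ValidationError("exactly one of polygon or mask must be given")
        if self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise ValidationError("polygon needs at least 3 (row, col) vertices")
            shp = _ShapelyPolygon([(r, c) for r, c in poly])
            if not shp.is_valid:
                raise ValidationError(f"region {self.region_id}: self-intersecting polygon")
            object.__setattr__(self, "polygon", poly)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of the region on an image of the given shape."""
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise ValidationError("mask shape does not match image shape")
            return self.mask
        key = tuple(shape)
        if key not in self._mask_cache:
            self._mask_cache[key] = rasterize_polygon(self.polygon, shape)
        return self._mask_cache[key]


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon inclusively of boundary pixels.

    A pixel belongs to the region iff its centre ``(row, col)`` lies inside the
    polygon or exactly on its boundary (a point-in-polygon ``covers`` test),
    which makes the rasterization exact rather than a scanline approximation.
    """
    v = np.asarray(vertices, dtype=float)
    poly = _ShapelyPolygon([(r, c) for r, c in v])
    mask = np.zeros(shape, dtype=bool)
    r0 = max(0, int(np.floor(v[:, 0].min())))
    r1 = min(shape[0] - 1, int(np.ceil(v[:, 0].max())))
    c0 = max(0, int(np.floor(v[:, 1].min())))
    c1 = min(shape[1] - 1, int(np.ceil(v[:, 1].max())))
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    pts = shapely.points(np.column_stack([rr.ravel(), cc.ravel()]))
    inside = shapely.covers(poly, pts).reshape(rr.shape)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    return mask


def _parse_calibration(d: dict) -> CalibrationSpec:
    return CalibrationSpec(
        mode=d["mode"],
        slope=float(d["slope"]),
        intercept=float(d["intercept"]),
        od_clip=tuple(d.get("od_clip", DEFAULT_OD_CLIP)),  # type: ignore[arg-type]
        log_floor=float(d.get("log_floor", DEFAULT_LOG_FLOOR)),
    )


def read_meta(meta_path: str | Path) -> ImageMeta:
    """Parse and validate a JSON metadata sidecar."""
    with open(meta_path) as fh:
        raw = json.load(fh)
    age = raw.get("patient_age")
    return ImageMeta(
        pixel_size_um=float(raw["pixel_size_um"]),
        bit_depth=int(raw["bit_depth"]),
        calibration=_parse_calibration(raw["calibration"]),
        patient_age=int(age) if age is not None else None,
        image_id=str(raw.get("image_id", Path(meta_path).stem)),
    )


def read_image(path: str | Path, meta_path: str | Path) -> tuple[np.ndarray, ImageMeta]:
    """Read a raw grey image and its metadata sidecar.

    Pixel values are returned unmodified; values above ``2**bit_depth - 1``
    raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if path.suffix == ".npy":
        raw = np.load(path)
    else:
        raw = np.asarray(iio.imread(path))
    if raw.ndim != 2:
        raise ValidationError(f"expected single-channel 2-D image, got shape {raw.shape}")
    meta = read_meta(meta_path)
    if np.issubdtype(raw.dtype, np.integer):
        limit = 2 ** meta.bit_depth - 1
        if raw.max(initial=0) > limit:
            raise ValidationError(
                f"grey values exceed 2^{meta.bit_depth}-1 = {limit} (max {raw.max()})"
            )
    return raw, meta


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a 2-D array as .npy or 16-bit PNG (integer input required for PNG)."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, pixels)
    else:
        iio.imwrite(path, np.asarray(pixels, dtype=np.uint16))


def to_optical_density(
    raw_image: np.ndarray,
    calibration: CalibrationSpec,
    meta: ImageMeta | None = None,
) -> ODImage:
    """Convert raw grey levels to clamped optical density."""
    grey = np.asarray(raw_image, dtype=float)
    if calibration.mode == "linear":
        od = calibration.slope * grey + calibration.intercept
    else:
        od = calibration.slope * np.log10(np.maximum(grey, calibration.log_floor))
        od += calibration.intercept
    if not np.all(np.isfinite(od)):
        raise CalibrationError("non-finite optical density before clamping")
    lo, hi = calibration.od_clip
    return ODImage(pixels=np.clip(od, lo, hi), meta=meta)


def read_ground_truth(
    path: str | Path, image_shape: tuple[int, int]
) -> list[GroundTruthRegion]:
    """Load ground-truth regions from a JSON annotation (or sidecar) file.

    Accepts either a bare list of region dicts or a sidecar with a ``regions``
    key; an absent or empty list means a healthy image.  Polygon regions must
    be explicitly closed (first vertex repeated last).  Masks may be inline
    nested lists or a ``mask_path`` to a ``.npy`` file next to the annotation.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    entries: Sequence[dict] = raw if isinstance(raw, list) else raw.get("regions", [])
    regions: list[GroundTruthRegion] = []
    for entry in entries:
        rid = str(entry.get("id", f"region{len(regions)}"))
        pathology = entry.get("pathology", "malignant")
        if "polygon" in entry:
            poly = np.asarray(entry["polygon"], dtype=float)
            if len(poly) < 4 or not np.allclose(poly[0], poly[-1]):
                raise ValidationError(f"region {rid}: polygon is not closed")
            poly = poly[:-1]
            if poly.min() < 0 or np.any(poly.max(axis=0) >= np.asarray(image_shape)):
                raise ValidationError(f"region {rid}: vertices outside image bounds")
            regions.append(GroundTruthRegion(rid, pathology, polygon=poly))
        elif "mask" in entry or "mask_path" in entry:
            if "mask" in entry:
                mask = np.asarray(entry["mask"], dtype=bool)
            else:
                mask = np.load(path.parent / entry["mask_path"]).astype(bool)
            if mask.shape != tuple(image_shape):
                raise ValidationError(f"region {rid}: mask shape mismatch")
            regions.append(GroundTruthRegion(rid, pathology, mask=mask))
        else:
            raise ValidationError(f"region {rid}: neither polygon nor mask given")
    return regions
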
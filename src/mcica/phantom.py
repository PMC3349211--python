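"""Synthetic mammogram-like phantoms with known microcalcification truth.

A phantom is an optical-density image containing:

* **clustered microcalcifications** — small bright discs grouped inside a
  compact region (the clinically suspicious configuration of ≥3 deposits in
  roughly 1 cm²), each cluster annotated by a ground-truth polygon;
* **isolated microcalcifications** — single, typically somewhat larger bright
  deposits that are not part of any cluster;
* **distractors** — line-like structures mimicking calcified vessels and large
  smooth blobs mimicking film artifacts;
* **structured background** — a mean OD level plus a low-pass-filtered
  Gaussian field (texture) plus i.i.d. Gaussian noise.

All randomness flows from the single seed in :class:`PhantomSpec`; two calls
with equal specs are bit-identical.  The module also provides a labelled
pixel-prototype sampler and a controlled linear source-mixture generator used
to validate ICA source recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Point
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import GenerationError, SamplingError, ValidationError
from .io_calibration import CalibrationSpec, GroundTruthRegion, ImageMeta, ODImage

__all__ = [
    "BackgroundSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_patch_dataset",
    "generate_source_mixture",
    "assign_splits",
    "CLASSES",
    "LABEL_BACKGROUND",
    "LABEL_CLUSTERED",
    "LABEL_ISOLATED",
    "LABEL_DISTRACTOR",
]

# pixel-level label codes in PhantomTruth.label_mask
LABEL_BACKGROUND = 0
LABEL_CLUSTERED = 1
LABEL_ISOLATED = 2
LABEL_DISTRACTOR = 3

#: prototype classes fed to the classifier, in canonical output order
CLASSES = ("malignant-mc", "isolated-mc", "normal")


@dataclass(frozen=True)
class BackgroundSpec:
    """Structured background: mean OD + smooth correlated field + white noise."""

    mean_od: float = 1.5
    field_amplitude: float = 0.15
    correlation_px: float = 8.0
    noise_sd: float = 0.03


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom image.

    Defaults emulate a ~1.4 cm square tile of a 12-bit film mammogram digitized
    at 43.5 μm/pixel: one malignant cluster of 5–8 deposits spread over a
    0.25 cm radius, two isolated deposits, two vessel-mimic lines and one
    large-blob artifact.  ``object_size_px`` ranges are disc *diameters*.
    """

    shape: tuple[int, int] = (320, 320)
    pixel_size_um: float = 43.5
    n_clusters: int = 1
    objects_per_cluster: tuple[int, int] = (5, 8)
    cluster_radius_um: float = 2500.0
    object_size_px: tuple[int, int] = (3, 6)
    object_contrast: tuple[float, float] = (0.4, 0.8)
    n_isolated: int = 2
    isolated_size_px: tuple[int, int] = (5, 9)
    n_line_distractors: int = 2
    n_blob_distractors: int = 1
    distractor_contrast: float = 0.3
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    age_range: tuple[int, int] = (27, 91)
    seed: int = 0
    od_clip: tuple[float, float] = (0.0, 4.0)
    region_dilation_radii: float = 2.0  # hull dilation, in units of object radius

    def __post_init__(self) -> None:
        if self.n_clusters > 0 and self.objects_per_cluster[0] < 4:
            raise ValidationError(
                "objects_per_cluster.min must be ≥ 4 so clusters stay detectable "
                "under the ≥3-in-1-cm² rule"
            )
        if self.object_size_px[0] < 1:
            raise ValidationError("object_size_px must be ≥ 1")
        if min(self.n_clusters, self.n_isolated, self.n_line_distractors,
               self.n_blob_distractors) < 0:
            raise ValidationError("all counts must be ≥ 0")


@dataclass
class PhantomTruth:
    """Ground truth for one phantom.

    ``object_centroids`` rows are ``(row, col, label)`` with label in
    {"clustered", "isolated", "distractor"}.  ``label_mask`` assigns each pixel
    its rendered structure class (see ``LABEL_*`` codes); it is the
    "perfect-detector" oracle used in end-to-end validation.
    """

    cluster_regions: list[GroundTruthRegion]
    object_centroids: list[tuple[float, float, str]]
    age: int
    label_mask: np.ndarray


def _render_disc(img: np.ndarray, core: np.ndarray, r: float, c: float,
                 radius: float, contrast: float, edge: float = 0.7) -> None:
    """Add a Gaussian-edge-tapered bright disc; mark core pixels (≥ half contrast)."""
    ext = int(np.ceil(radius + 4 * edge)) + 1
    r0, r1 = max(0, int(r) - ext), min(img.shape[0], int(r) + ext + 1)
    c0, c1 = max(0, int(c) - ext), min(img.shape[1], int(c) + ext + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - r, cc - c)
    profile = contrast * np.exp(-np.maximum(d - (radius - edge), 0.0) ** 2
                                / (2.0 * edge ** 2))
    img[r0:r1, c0:c1] += profile
    core[r0:r1, c0:c1] |= profile >= 0.5 * contrast


def _place_cluster_centers(rng: np.random.Generator, shape: tuple[int, int],
                           n: int, margin: float, min_sep: float) -> list[tuple[float, float]]:
    centers: list[tuple[float, float]] = []
    for _ in range(500):
        if len(centers) == n:
            break
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all(np.hypot(r - rr, c - cc) >= min_sep for rr, cc in centers):
            centers.append((r, c))
    if len(centers) < n:
        raise GenerationError(
            f"could not place {n} clusters with separation {min_sep:.0f}px "
            f"in a {shape} image"
        )
    return centers


def generate_phantom(spec: PhantomSpec) -> tuple[ODImage, PhantomTruth]:
    """Render one phantom image and its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    bg = spec.background

    image = np.full(spec.shape, bg.mean_od, dtype=float)
    if bg.field_amplitude > 0:
        fld = gaussian_filter(rng.standard_normal(spec.shape), bg.correlation_px)
        sd = fld.std()
        if sd > 0:
            image += bg.field_amplitude * fld / sd
    if bg.noise_sd > 0:
        image += rng.normal(0.0, bg.noise_sd, spec.shape)

    label_mask = np.zeros(spec.shape, dtype=np.uint8)
    centroids: list[tuple[float, float, str]] = []
    cluster_regions: list[GroundTruthRegion] = []

    radius_px = spec.cluster_radius_um / spec.pixel_size_um
    max_obj_r = spec.object_size_px[1] / 2.0
    hull_margin = spec.region_dilation_radii * max_obj_r
    margin = radius_px + hull_margin + max_obj_r + 3
    if spec.n_clusters > 0 and 2 * margin >= min(spec.shape):
        raise GenerationError("image too small for the configured cluster geometry")
    cluster_centers = _place_cluster_centers(
        rng, spec.shape, spec.n_clusters, margin,
        min_sep=2 * (radius_px + hull_margin) + 4,
    )

    for k, (cr, cc) in enumerate(cluster_centers):
        n_obj = int(rng.integers(spec.objects_per_cluster[0],
                                 spec.objects_per_cluster[1] + 1))
        core = np.zeros(spec.shape, dtype=bool)
        members: list[tuple[float, float]] = []
        radii: list[float] = []
        for _ in range(n_obj):
            ang = rng.uniform(0, 2 * np.pi)
            rad = radius_px * np.sqrt(rng.uniform())
            orow, ocol = cr + rad * np.sin(ang), cc + rad * np.cos(ang)
            diam = rng.uniform(spec.object_size_px[0], spec.object_size_px[1])
            contrast = rng.uniform(*spec.object_contrast)
            _render_disc(image, core, orow, ocol, diam / 2.0, contrast)
            members.append((orow, ocol))
            radii.append(diam / 2.0)
            centroids.append((orow, ocol, "clustered"))
        label_mask[core] = LABEL_CLUSTERED
        hull = MultiPoint([(r, c) for r, c in members]).convex_hull
        poly = hull.buffer(spec.region_dilation_radii * float(np.mean(radii)))
        verts = np.asarray(poly.exterior.coords[:-1], dtype=float)
        verts[:, 0] = np.clip(verts[:, 0], 0, rows - 1)
        verts[:, 1] = np.clip(verts[:, 1], 0, cols - 1)
        cluster_regions.append(
            GroundTruthRegion(f"cluster{k}", "malignant", polygon=verts)
        )

    # isolated microcalcifications: keep clear of cluster regions and borders
    iso_margin = spec.isolated_size_px[1] / 2.0 + 3
    placed = 0
    for _ in range(500):
        if placed == spec.n_isolated:
            break
        r = rng.uniform(iso_margin, rows - iso_margin)
        c = rng.uniform(iso_margin, cols - iso_margin)
        if any(np.hypot(r - cr, c - cc) < margin + iso_margin
               for cr, cc in cluster_centers):
            continue
        core = np.zeros(spec.shape, dtype=bool)
        diam = rng.uniform(spec.isolated_size_px[0], spec.isolated_size_px[1])
        _render_disc(image, core, r, c, diam / 2.0, rng.uniform(*spec.object_contrast))
        label_mask[core & (label_mask == 0)] = LABEL_ISOLATED
        centroids.append((r, c, "isolated"))
        placed += 1
    if placed < spec.n_isolated:
        raise GenerationError("could not place isolated microcalcifications")

    # distractors: vessel-mimic line segments and large smooth blobs
    for _ in range(spec.n_line_distractors):
        r0 = rng.uniform(5, rows - 5)
        c0 = rng.uniform(5, cols - 5)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(30, 60)
        r1 = np.clip(r0 + length * np.sin(ang), 1, rows - 2)
        c1 = np.clip(c0 + length * np.cos(ang), 1, cols - 2)
        n_steps = int(np.hypot(r1 - r0, c1 - c0) * 2) + 1
        rr = np.linspace(r0, r1, n_steps)
        cc = np.linspace(c0, c1, n_steps)
        line = np.zeros(spec.shape, dtype=float)
        line[np.round(rr).astype(int), np.round(cc).astype(int)] = 1.0
        line = gaussian_filter(line, 0.8)
        mx = line.max()
        if mx > 0:
            line *= spec.distractor_contrast / mx
        image += line
        label_mask[(line >= 0.5 * spec.distractor_contrast) & (label_mask == 0)] = \
            LABEL_DISTRACTOR
        centroids.append(((r0 + r1) / 2.0, (c0 + c1) / 2.0, "distractor"))

    for _ in range(spec.n_blob_distractors):
        r = rng.uniform(20, rows - 20)
        c = rng.uniform(20, cols - 20)
        sigma = rng.uniform(8, 15)
        rr, cc = np.mgrid[0:rows, 0:cols]
        blob = spec.distractor_contrast * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma ** 2))
        image += blob
        label_mask[(blob >= 0.5 * spec.distractor_contrast) & (label_mask == 0)] = \
            LABEL_DISTRACTOR
        centroids.append((r, c, "distractor"))

    np.clip(image, spec.od_clip[0], spec.od_clip[1], out=image)

    # invariant: every clustered centroid lies inside exactly one region
    region_polys = [_ShapelyPolygon([(vr, vc) for vr, vc in reg.polygon])
                    for reg in cluster_regions]
    for r, c, lab in centroids:
        if lab != "clustered":
            continue
        hits = sum(1 for poly in region_polys if poly.covers(Point(r, c)))
        if hits != 1:
            raise GenerationError(
                f"clustered centroid ({r:.1f},{c:.1f}) lies in {hits} regions")

    age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
    meta = ImageMeta(
        pixel_size_um=spec.pixel_size_um,
        bit_depth=12,
        calibration=CalibrationSpec("linear", 1.0, 0.0, od_clip=spec.od_clip),
        patient_age=age,
        image_id=f"phantom-{spec.seed}",
    )
    truth = PhantomTruth(cluster_regions, centroids, age, label_mask)
    return ODImage(pixels=image, meta=meta), truth


def generate_patch_dataset(
    phantoms: Sequence[tuple[ODImage, PhantomTruth]],
    counts: dict[str, int],
    margin_px: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample labelled pixel locations from phantom truth.

    ``counts`` maps class name (see :data:`CLASSES`) to the number of pixel
    rows requested, pooled across all phantoms.  Malignant prototypes are drawn
    from clustered-object discs, isolated ones from isolated discs, and normal
    prototypes as single pixels from background and distractor areas.
    Locations closer than ``margin_px`` to any border are excluded so that a
    sampling window of side ``2*margin_px + 1`` always fits.
    """
    if not phantoms:
        raise ValidationError("need at least one phantom")
    rng = np.random.default_rng(seed)
    label_for_class = {
        "malignant-mc": (LABEL_CLUSTERED,),
        "isolated-mc": (LABEL_ISOLATED,),
        "normal": (LABEL_BACKGROUND, LABEL_DISTRACTOR),
    }
    frames = []
    for cls, n_req in counts.items():
        if cls not in label_for_class:
            raise ValidationError(f"unknown class {cls!r}")
        pool = []
        for od, truth in phantoms:
            interior = np.zeros(od.shape, dtype=bool)
            m = margin_px
            interior[m:od.shape[0] - m or None, m:od.shape[1] - m or None] = True
            sel = np.isin(truth.label_mask, label_for_class[cls]) & interior
            rr, cc = np.nonzero(sel)
            img_id = od.meta.image_id if od.meta else ""
            pool.append(pd.DataFrame(
                {"image_id": img_id, "row": rr, "col": cc, "label": cls}))
        pool_df = pd.concat(pool, ignore_index=True)
        if n_req > len(pool_df):
            raise SamplingError(
                f"requested {n_req} {cls!r} pixels but only {len(pool_df)} available")
        idx = rng.choice(len(pool_df), size=n_req, replace=False)
        frames.append(pool_df.iloc[np.sort(idx)])
    return pd.concat(frames, ignore_index=True)


def assign_splits(
    image_ids: Sequence[str],
    n_learn: int,
    n_val: int,
    n_test: int,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Partition image ids into disjoint learning/validation/test splits."""
    ids = list(dict.fromkeys(image_ids))
    if n_learn + n_val + n_test > len(ids):
        raise ValidationError("split sizes exceed number of images")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    picked = [ids[i] for i in order]
    return {
        "learn": sorted(picked[:n_learn]),
        "val": sorted(picked[n_learn:n_learn + n_val]),
        "test": sorted(picked[n_learn + n_val:n_learn + n_val + n_test]),
    }


def generate_source_mixture(
    n_sources: int,
    n_samples: int,
    source_dists: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a controlled linear mixture ``X = S Aᵀ`` of non-Gaussian sources.

    Sources are i.i.d. unit-variance Laplace or uniform columns (alternating by
    default); the mixing matrix ``A`` is a random Gaussian matrix redrawn until
    well conditioned.  Returns ``(X, A, S)``.
    """
    if n_sources < 2:
        raise ValidationError("need at least 2 sources")
    if source_dists is None:
        source_dists = ["laplace" if i % 2 == 0 else "uniform" for i in range(n_sources)]
    if len(source_dists) != n_sources:
        raise ValidationError("source_dists length must equal n_sources")
    rng = np.random.default_rng(seed)
    cols = []
    for dist in source_dists:
        if dist == "laplace":
            cols.append(rng.laplace(0.0, 1.0 / np.sqrt(2.0), n_samples))
        elif dist == "uniform":
            cols.append(rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), n_samples))
        else:
            raise ValidationError(f"unsupported source distribution {dist!r}")
    S = np.column_stack(cols)
    for _ in range(20):
        A = rng.normal(size=(n_sources, n_sources))
        if np.linalg.cond(A) < 1e3:
            break
    else:
        raise GenerationError("could not draw a well-conditioned mixing matrix")
    return S @ A.T, A, S
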
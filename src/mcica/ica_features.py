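"""ICA patch-feature extraction.

A pixel and its square neighbourhood are characterized by the coefficients of
an ICA basis estimated from training patches: the patch matrix ``X`` is
column-centred, prewhitened by projecting onto its leading principal
directions with unit output variance (matrix ``K``), and a fixed-point
negentropy-maximizing iteration (FastICA, log-cosh contrast, symmetric
decorrelation) estimates an orthonormal rotation ``W`` such that the training
sources ``S = X_c K W`` are maximally non-Gaussian and mutually decorrelated.
A window centred on a pixel then maps to the feature vector
``F = ((R − column_means) K) W``, optionally augmented with the patient's age
scaled linearly from [27, 91] years onto [−1, +1].
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import BorderError, ConvergenceError, RankError, ValidationError
from .io_calibration import ODImage

__all__ = [
    "PatchMatrix",
    "ICABasis",
    "sample_patches",
    "fit_ica_basis",
    "extract_features",
    "scale_age",
    "window_physical_size",
    "amari_index",
    "save_basis",
    "load_basis",
]

AGE_RANGE = (27.0, 91.0)  # years mapped onto [-1, +1]
WINDOW_RANGE = (3, 81)
COMPONENT_RANGE = (2, 80)


@dataclass
class PatchMatrix:
    """Vectorized square windows, one per row, in row-major pixel order.

    Rows are raw window contents; the per-column (per-pixel-position) mean is
    subtracted later, at basis-estimation time, and stored with the basis.
    """

    X: np.ndarray  # (n_samples, window_px**2)
    window_px: int
    source_locations: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if self.X.shape[1] != self.window_px ** 2:
            raise ValidationError("n_pixels must equal window_px**2")


@dataclass
class ICABasis:
    """Estimated prewhitening/unmixing pair plus the centering vector.

    ``K`` has shape ``(n_pixels, n_comp)`` and maps a centred window to a
    whitened vector with identity covariance on the training set; ``W`` is the
    ``(n_comp, n_comp)`` orthonormal rotation such that features are
    ``((R − column_means) K) W``.
    """

    K: np.ndarray
    W: np.ndarray
    column_means: np.ndarray
    window_px: int
    n_components: int
    seed: int
    use_age: bool = False

    @property
    def n_features(self) -> int:
        return self.n_components + (1 if self.use_age else 0)

    def transform(self, windows: np.ndarray) -> np.ndarray:
        """Map raw vectorized windows (rows) to ICA feature rows."""
        return (np.asarray(windows, float) - self.column_means) @ self.K @ self.W


def window_physical_size(window_px: int, pixel_size_um: float) -> float:
    """Physical side length of a sampling window, in μm."""
    if window_px < 1:
        raise ValidationError("window_px must be ≥ 1")
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be positive")
    return window_px * pixel_size_um


def scale_age(age_years: float) -> float:
    """Scale an age in years linearly from [27, 91] onto [−1, +1], clamped."""
    if not age_years > 0:
        raise ValidationError("age must be positive")
    lo, hi = AGE_RANGE
    return float(np.clip(2.0 * (age_years - lo) / (hi - lo) - 1.0, -1.0, 1.0))


def _check_window(window_px: int) -> None:
    if window_px % 2 == 0:
        raise ValidationError("window_px must be odd")
    if not WINDOW_RANGE[0] <= window_px <= WINDOW_RANGE[1]:
        raise ValidationError(f"window_px must be within {WINDOW_RANGE}")


def sample_patches(
    od_images: Sequence[ODImage] | dict[str, ODImage],
    locations: Sequence[tuple[str, int, int]],
    window_px: int,
) -> PatchMatrix:
    """Collect vectorized windows centred on the given (image_id, row, col).

    Locations whose window would overhang the image border raise
    :class:`BorderError` (the default border policy rejects them).
    """
    _check_window(window_px)
    if isinstance(od_images, dict):
        by_id = od_images
    else:
        by_id = {img.meta.image_id if img.meta else str(i): img
                 for i, img in enumerate(od_images)}
    half = window_px // 2
    rows = []
    kept: list[tuple[str, int, int]] = []
    for image_id, r, c in locations:
        img = by_id[image_id].pixels
        if not (half <= r < img.shape[0] - half and half <= c < img.shape[1] - half):
            raise BorderError(
                f"window of side {window_px} at ({r},{c}) overhangs image "
                f"{image_id!r} of shape {img.shape}")
        rows.append(img[r - half:r + half + 1, c - half:c + half + 1].ravel())
        kept.append((image_id, int(r), int(c)))
    X = np.asarray(rows, dtype=float).reshape(len(rows), window_px ** 2)
    return PatchMatrix(X=X, window_px=window_px, source_locations=kept)


def fit_ica_basis(
    patches: PatchMatrix | np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    window_px: int | None = None,
    strict_convergence: bool = True,
) -> ICABasis:
    """Estimate an ICA basis (K, W, column means) from training patches.

    Whitening uses the top ``n_components`` principal directions scaled to unit
    sample variance (ddof=1).  The rotation ``W`` comes from FastICA with
    log-cosh contrast and symmetric decorrelation.  With
    ``strict_convergence``, failure to converge within ``max_iter`` raises
    :class:`ConvergenceError` carrying the iteration count.
    """
    if isinstance(patches, PatchMatrix):
        X = patches.X
        window_px = patches.window_px
    else:
        X = np.asarray(patches, dtype=float)
        if window_px is None:
            side = int(round(np.sqrt(X.shape[1])))
            window_px = side if side * side == X.shape[1] else 0
    if not COMPONENT_RANGE[0] <= n_components <= COMPONENT_RANGE[1]:
        raise ValidationError(f"n_components must be within {COMPONENT_RANGE}")
    if n_components > X.shape[1]:
        raise RankError("n_components exceeds window dimensionality")
    n_samples = X.shape[0]
    if n_samples <= n_components:
        raise RankError("need n_samples well above n_components")

    column_means = X.mean(axis=0)
    Xc = X - column_means
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(svals > svals[0] * 1e-12))
    if n_components > rank:
        raise RankError(f"n_components={n_components} exceeds data rank {rank}")
    # unit-variance whitening with the ddof=1 sample-covariance convention
    K = Vt[:n_components].T * (np.sqrt(n_samples - 1) / svals[:n_components])
    Z = Xc @ K

    rng = np.random.RandomState(seed)
    ica = FastICA(
        n_components=None,  # Z already has exactly n_components whitened columns
        whiten=False,
        fun="logcosh",
        tol=tol,
        max_iter=max_iter,
        random_state=rng,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(Z)
    if strict_convergence and any(
            issubclass(w.category, ConvergenceWarning) for w in caught):
        raise ConvergenceError(
            f"FastICA did not converge within {max_iter} iterations "
            f"(ran {ica.n_iter_})", n_iter=int(ica.n_iter_))
    W = np.asarray(ica.components_).T  # sources = Z @ W
    return ICABasis(K=K, W=W, column_means=column_means,
                    window_px=int(window_px), n_components=n_components, seed=seed)


def extract_features(
    basis: ICABasis,
    od_image: ODImage,
    location: tuple[int, int],
    age: float | None = None,
) -> np.ndarray:
    """Feature vector for the window centred at ``location`` (row, col)."""
    if basis.use_age and age is None:
        raise ValidationError("basis is configured with age; age is required")
    if not basis.use_age and age is not None:
        raise ValidationError("basis is not configured with age")
    half = basis.window_px // 2
    r, c = location
    img = od_image.pixels
    if not (half <= r < img.shape[0] - half and half <= c < img.shape[1] - half):
        raise BorderError(f"window at ({r},{c}) overhangs the image")
    window = img[r - half:r + half + 1, c - half:c + half + 1].ravel()
    feats = basis.transform(window[None, :])[0]
    if basis.use_age:
        feats = np.append(feats, scale_age(age))
    return feats


def amari_index(M_est: np.ndarray, A_true: np.ndarray) -> float:
    """Permutation- and scale-invariant distance between unmixings, in [0, 1].

    ``M_est`` maps observations to estimated sources; a perfect recovery gives
    ``M_est @ A_true`` equal to a scaled permutation and an index of 0.
    """
    G = np.abs(np.asarray(M_est) @ np.asarray(A_true))
    n = G.shape[0]
    rows = (G.sum(axis=1) / G.max(axis=1) - 1.0).sum()
    cols = (G.sum(axis=0) / G.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * n * (n - 1)))


def _basis_hash(basis: ICABasis) -> str:
    h = hashlib.sha256()
    for arr in (basis.K, basis.W, basis.column_means):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(json.dumps([basis.window_px, basis.n_components, basis.seed,
                         basis.use_age]).encode())
    return h.hexdigest()


def save_basis(basis: ICABasis, path: str | Path) -> None:
    """Persist a basis as a single .npz archive with a content hash."""
    np.savez(
        path,
        K=basis.K, W=basis.W, column_means=basis.column_means,
        window_px=basis.window_px, n_components=basis.n_components,
        seed=basis.seed, use_age=basis.use_age,
        content_hash=np.bytes_(_basis_hash(basis).encode()),
    )


def load_basis(path: str | Path) -> ICABasis:
    """Load a persisted basis, verifying its content hash."""
    with np.load(path) as arc:
        basis = ICABasis(
            K=arc["K"], W=arc["W"], column_means=arc["column_means"],
            window_px=int(arc["window_px"]), n_components=int(arc["n_components"]),
            seed=int(arc["seed"]), use_age=bool(arc["use_age"]),
        )
        stored = bytes(arc["content_hash"]).decode()
    if stored != _basis_hash(basis):
        raise ValidationError(f"basis archive {path} failed its content-hash check")
    return basis
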
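"""Pixel classification: single-hidden-layer MLP trained with RPROP.

The network maps an ICA feature vector to one activation per prototype class
(logistic sigmoid on hidden and output layers) and is trained full-batch on a
sum-of-squares error with the resilient-backpropagation (RPROP) update: each
weight keeps its own step size, grown when the gradient sign repeats and shrunk
when it flips.  Model selection keeps the epoch snapshot with the best
validation success rate; a sweep over hidden-layer sizes with several random
restarts keeps the single best network.

Output decisions use SNNS-style analyzer rules:

* ``402040`` — accept class c iff its activation ≥ h while every other
  activation ≤ l (classic parameters l=0.45, h=0.55);
* ``wta`` — winner takes all: accept the argmax iff it is unique and its
  activation exceeds h (presets WTA0–WTA3 with h = 0, 0.5, 0.55, 0.6).

Patterns accepted by no rule are UNCLASSIFIED and count as errors in the
success rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.util import view_as_windows

from .errors import ConfigError, TrainingError, ValidationError
from .ica_features import ICABasis, scale_age
from .io_calibration import ODImage

__all__ = [
    "UNCLASSIFIED",
    "AnalyzerRule",
    "ANALYZER_PRESETS",
    "ClassDecision",
    "RpropConfig",
    "MLPModel",
    "train_mlp",
    "sweep_train",
    "analyze",
    "analyze_batch",
    "classify_image",
    "output_map",
    "DetectionMap",
]

UNCLASSIFIED = -1


@dataclass(frozen=True)
class AnalyzerRule:
    """SNNS-style output analyzer ('rule402040' or 'wta')."""

    kind: str
    h: float
    l: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind == "rule402040":
            if self.l is None or not (0.0 <= self.l < self.h <= 1.0):
                raise ConfigError("rule402040 requires 0 ≤ l < h ≤ 1")
        elif self.kind == "wta":
            if not 0.0 <= self.h <= 1.0:
                raise ConfigError("wta requires h in [0, 1]")
        else:
            raise ConfigError(f"unknown analyzer kind {self.kind!r}")

    def describe(self) -> str:
        return self.name or (f"{self.kind}(h={self.h}"
                             + (f", l={self.l})" if self.l is not None else ")"))


#: the five named analyzer presets
ANALYZER_PRESETS: Mapping[str, AnalyzerRule] = {
    "402040": AnalyzerRule("rule402040", h=0.55, l=0.45, name="402040"),
    "wta0": AnalyzerRule("wta", h=0.0, name="WTA0"),
    "wta1": AnalyzerRule("wta", h=0.5, name="WTA1"),
    "wta2": AnalyzerRule("wta", h=0.55, name="WTA2"),
    "wta3": AnalyzerRule("wta", h=0.6, name="WTA3"),
}


@dataclass(frozen=True)
class ClassDecision:
    label: int  # class index or UNCLASSIFIED
    winning_output: float


@dataclass(frozen=True)
class RpropConfig:
    """RPROP hyperparameters (standard published constants) and stopping rule."""

    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_max: float = 50.0
    delta_min: float = 1e-6
    max_epochs: int = 1000
    patience: int = 50

    def __post_init__(self) -> None:
        if not self.eta_minus < 1.0 < self.eta_plus:
            raise ConfigError("need eta_minus < 1 < eta_plus")
        if not 0.0 < self.delta_min <= self.delta0 <= self.delta_max:
            raise ConfigError("need 0 < delta_min ≤ delta0 ≤ delta_max")


@dataclass
class MLPModel:
    """Single-hidden-layer perceptron with logistic sigmoid activations."""

    W1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray
    W2: np.ndarray  # (n_hidden, n_out)
    b2: np.ndarray
    seed: int = 0
    epochs_run: int = 0
    validation_score: float = float("nan")
    score_history: list[float] = field(default_factory=list)  # best-so-far per epoch

    @property
    def n_in(self) -> int:
        return self.W1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]

    @property
    def n_out(self) -> int:
        return self.W2.shape[1]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Output activations in (0, 1), shape (n_samples, n_out)."""
        H = _sigmoid(np.asarray(X, float) @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def analyze(outputs: Sequence[float], rule: AnalyzerRule) -> ClassDecision:
    """Apply an analyzer rule to one output vector."""
    out = np.asarray(outputs, dtype=float)
    if out.ndim != 1 or out.size < 2:
        raise ValidationError("outputs must be a vector of length ≥ 2")
    if out.min() < 0.0 or out.max() > 1.0:
        raise ValidationError("outputs must lie in [0, 1]")
    label = int(analyze_batch(out[None, :], rule)[0])
    winner = int(np.argmax(out))
    return ClassDecision(label=label, winning_output=float(out[winner]))


def analyze_batch(outputs: np.ndarray, rule: AnalyzerRule) -> np.ndarray:
    """Vectorized analyzer: one label (or UNCLASSIFIED) per row."""
    out = np.asarray(outputs, dtype=float)
    n = out.shape[1]
    winners = np.argmax(out, axis=1)
    wvals = out[np.arange(len(out)), winners]
    if rule.kind == "wta":
        unique = (out == wvals[:, None]).sum(axis=1) == 1
        ok = unique & (wvals > rule.h)
    else:  # rule402040
        above = out >= rule.h
        sorted_out = np.sort(out, axis=1)
        runner_up = sorted_out[:, -2] if n >= 2 else np.zeros(len(out))
        ok = above[np.arange(len(out)), winners] & (runner_up <= rule.l) \
            & (above.sum(axis=1) == 1)
    labels = np.where(ok, winners, UNCLASSIFIED)
    return labels.astype(int)


def _one_hot(labels: np.ndarray, n_out: int) -> np.ndarray:
    T = np.zeros((len(labels), n_out))
    T[np.arange(len(labels)), labels] = 1.0
    return T


def _success_rate(model: MLPModel, X: np.ndarray, y: np.ndarray,
                  rule: AnalyzerRule) -> float:
    """Fraction of analyzer-correct patterns; UNCLASSIFIED counts as an error."""
    decisions = analyze_batch(model.forward(X), rule)
    return float(np.mean(decisions == y))


def _init_model(n_in: int, n_hidden: int, n_out: int, seed: int) -> MLPModel:
    rng = np.random.default_rng(seed)
    return MLPModel(
        W1=rng.uniform(-0.3, 0.3, (n_in, n_hidden)),
        b1=rng.uniform(-0.3, 0.3, n_hidden),
        W2=rng.uniform(-0.3, 0.3, (n_hidden, n_out)),
        b2=rng.uniform(-0.3, 0.3, n_out),
        seed=seed,
    )


def train_mlp(
    features: np.ndarray,
    labels: np.ndarray,
    split: Mapping[str, Sequence[int]],
    n_hidden: int,
    config: RpropConfig | None = None,
    seed: int = 0,
    n_out: int | None = None,
    selection_analyzer: AnalyzerRule = ANALYZER_PRESETS["wta0"],
) -> MLPModel:
    """Train one MLP with full-batch RPROP and best-validation-snapshot return.

    ``split`` maps 'learn' and 'val' to disjoint row-index sets.  Weights are
    updated by the sign-based RPROP rule (iRPROP−: the update is skipped on a
    gradient sign flip while the step size shrinks) on the sum-of-squares error
    over the learning set; the returned model is the epoch snapshot with the
    highest validation success rate under ``selection_analyzer``.
    """
    config = config or RpropConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_out = n_out or int(y.max()) + 1
    learn_idx = np.asarray(split["learn"], dtype=int)
    val_idx = np.asarray(split["val"], dtype=int)
    if len(learn_idx) == 0 or len(val_idx) == 0:
        raise ValidationError("learning and validation splits must be non-empty")
    if set(learn_idx) & set(val_idx):
        raise ValidationError("learning and validation splits must be disjoint")

    Xl, Tl = X[learn_idx], _one_hot(y[learn_idx], n_out)
    Xv, yv = X[val_idx], y[val_idx]

    model = _init_model(X.shape[1], n_hidden, n_out, seed)
    params = [model.W1, model.b1, model.W2, model.b2]
    deltas = [np.full_like(p, config.delta0) for p in params]
    prev_grad = [np.zeros_like(p) for p in params]

    best_score = _success_rate(model, Xv, yv, selection_analyzer)
    best = [p.copy() for p in params]
    best_epoch = 0
    history = [best_score]
    since_improve = 0

    for epoch in range(1, config.max_epochs + 1):
        H = _sigmoid(Xl @ params[0] + params[1])
        O = _sigmoid(H @ params[2] + params[3])
        err = O - Tl
        if not np.all(np.isfinite(err)):
            raise TrainingError(f"training diverged at epoch {epoch}")
        dO = err * O * (1.0 - O)
        gW2 = H.T @ dO
        gb2 = dO.sum(axis=0)
        dH = (dO @ params[2].T) * H * (1.0 - H)
        gW1 = Xl.T @ dH
        gb1 = dH.sum(axis=0)
        grads = [gW1, gb1, gW2, gb2]

        for p, g, d, gp in zip(params, grads, deltas, prev_grad):
            sign = g * gp
            inc, dec = sign > 0, sign < 0
            d[inc] = np.minimum(d[inc] * config.eta_plus, config.delta_max)
            d[dec] = np.maximum(d[dec] * config.eta_minus, config.delta_min)
            g[dec] = 0.0  # iRPROP−: no step right after a sign flip
            p -= np.sign(g) * d
            gp[...] = g

        score = _success_rate(model, Xv, yv, selection_analyzer)
        if score > best_score:
            best_score = score
            best = [p.copy() for p in params]
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
        history.append(best_score)
        if since_improve >= config.patience:
            break

    model.W1, model.b1, model.W2, model.b2 = best
    model.epochs_run = best_epoch
    model.validation_score = best_score
    model.score_history = history
    return model


def sweep_train(
    features: np.ndarray,
    labels: np.ndarray,
    split: Mapping[str, Sequence[int]],
    hidden_sizes: Sequence[int] = (50, 100, 150, 200),
    n_restarts: int = 4,
    base_seed: int = 0,
    config: RpropConfig | None = None,
    n_out: int | None = None,
    selection_analyzer: AnalyzerRule = ANALYZER_PRESETS["wta0"],
) -> tuple[MLPModel, pd.DataFrame]:
    """Sweep hidden sizes × random restarts; keep the best-validation model.

    Ties are broken toward fewer hidden units, then the lower restart index.
    The report has one row per trained configuration.
    """
    rows = []
    best_model: MLPModel | None = None
    best_key: tuple = ()
    for hi, n_hidden in enumerate(hidden_sizes):
        for restart in range(n_restarts):
            # base_seed itself for the first configuration, so a degenerate
            # sweep (one size, one restart) reproduces a single train_mlp call
            seed = (base_seed + 7919 * hi + restart) % (2 ** 31)
            model = train_mlp(features, labels, split, n_hidden, config,
                              seed=seed, n_out=n_out,
                              selection_analyzer=selection_analyzer)
            rows.append({
                "n_hidden": n_hidden, "restart": restart, "seed": seed,
                "val_score": model.validation_score,
                "epochs": model.epochs_run,
            })
            key = (-model.validation_score, n_hidden, restart)
            if best_model is None or key < best_key:
                best_model, best_key = model, key
    report = pd.DataFrame(rows)
    assert best_model is not None
    return best_model, report


@dataclass
class DetectionMap:
    """Per-pixel binary microcalcification decisions for one image."""

    mask: np.ndarray
    meta: object = None  # ImageMeta of the source image
    margin_px: int = 0


def output_map(
    model: MLPModel,
    basis: ICABasis,
    od_image: ODImage,
    chunk_rows: int = 16,
) -> tuple[np.ndarray, int]:
    """Network output activations for every interior pixel of an image.

    Returns ``(activations, margin)`` where activations has shape
    ``(rows − 2·margin, cols − 2·margin, n_out)``.  Processing is chunked by
    image row blocks to bound memory.
    """
    if model.n_in != basis.n_features:
        raise ConfigError(
            f"model expects {model.n_in} inputs but basis yields {basis.n_features}")
    w = basis.window_px
    margin = w // 2
    img = od_image.pixels
    if img.shape[0] < w or img.shape[1] < w:
        raise ValidationError("image smaller than the sampling window")
    age_col = None
    if basis.use_age:
        if od_image.meta is None or od_image.meta.patient_age is None:
            raise ValidationError("basis uses age but image metadata has no age")
        age_col = scale_age(od_image.meta.patient_age)
    out_rows = img.shape[0] - 2 * margin
    out_cols = img.shape[1] - 2 * margin
    acts = np.empty((out_rows, out_cols, model.n_out))
    for r0 in range(0, out_rows, chunk_rows):
        r1 = min(r0 + chunk_rows, out_rows)
        block = img[r0:r1 + 2 * margin, :]
        wins = view_as_windows(block, (w, w)).reshape(-1, w * w)
        feats = basis.transform(wins)
        if age_col is not None:
            feats = np.column_stack([feats, np.full(len(feats), age_col)])
        acts[r0:r1] = model.forward(feats).reshape(r1 - r0, out_cols, model.n_out)
    return acts, margin


def detection_map_from_outputs(
    acts: np.ndarray,
    margin: int,
    rule: AnalyzerRule,
    positive_classes: Sequence[int],
    image_shape: tuple[int, int],
    meta: object = None,
) -> DetectionMap:
    """Apply an analyzer rule to precomputed activations."""
    labels = analyze_batch(acts.reshape(-1, acts.shape[-1]), rule)
    pos = np.isin(labels, np.asarray(positive_classes, int))
    mask = np.zeros(image_shape, dtype=bool)
    mask[margin:image_shape[0] - margin or None,
         margin:image_shape[1] - margin or None] = pos.reshape(acts.shape[:2])
    return DetectionMap(mask=mask, meta=meta, margin_px=margin)


def classify_image(
    model: MLPModel,
    basis: ICABasis,
    od_image: ODImage,
    rule: AnalyzerRule,
    positive_classes: Sequence[int] = (0, 1),
) -> DetectionMap:
    """Pixel-level diagnosis of one image.

    Every interior pixel (border margin = half window) is featurized, run
    through the network and the analyzer; the map is true where the decision
    falls in ``positive_classes`` (default: the two microcalcification
    classes).
    """
    acts, margin = output_map(model, basis, od_image)
    return detection_map_from_outputs(
        acts, margin, rule, positive_classes, od_image.pixels.shape,
        meta=od_image.meta)
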
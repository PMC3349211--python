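"""End-to-end phantom experiments: generate → fit basis → train → diagnose → score.

This is thin orchestration over the stage modules, used by the CLI, the test
suite and the reproduction script.  Default problem sizes (20 phantoms split
10/5/5, a 9-pixel window, 20 ICA components, hidden sizes 50 and 100 with two
restarts) keep a full run in the minutes range on one CPU while exercising
every stage at realistic parameter settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (ANALYZER_PRESETS, AnalyzerRule, MLPModel, RpropConfig,
                         classify_image, sweep_train)
from .froc_eval import OutcomeCounts, evaluate_detections, fpi, sensitivity
from .ica_features import ICABasis, fit_ica_basis, sample_patches
from .io_calibration import GroundTruthRegion, ODImage
from .phantom import CLASSES, PhantomSpec, PhantomTruth, generate_patch_dataset, generate_phantom

__all__ = ["ExperimentConfig", "ExperimentResult", "run_phantom_experiment",
           "make_phantom_set"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs for one end-to-end phantom experiment."""

    n_phantoms: int = 20
    split: tuple[int, int, int] = (10, 5, 5)  # learn / validation / test images
    window_px: int = 9
    n_components: int = 20
    hidden_sizes: tuple[int, ...] = (50, 100)
    n_restarts: int = 2
    analyzer: AnalyzerRule = ANALYZER_PRESETS["wta1"]
    counts_learn: dict = field(default_factory=lambda: {
        "malignant-mc": 200, "isolated-mc": 200, "normal": 800})
    counts_val: dict = field(default_factory=lambda: {
        "malignant-mc": 100, "isolated-mc": 100, "normal": 400})
    rprop: RpropConfig = field(default_factory=lambda: RpropConfig(
        max_epochs=400, patience=40))
    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    min_object_px: int = 2
    max_object_px: int = 100
    density_threshold: int = 3
    positive_classes: tuple[int, ...] = (0, 1)


@dataclass
class ExperimentResult:
    """Everything a caller may want back from one experiment run."""

    sensitivity: float
    fpi: float
    counts: OutcomeCounts
    model: MLPModel
    basis: ICABasis
    sweep_report: pd.DataFrame
    test_images: list[ODImage]
    test_truths: list[list[GroundTruthRegion]]
    per_image: pd.DataFrame
    rois_per_image: list[list]


def make_phantom_set(
    n: int, seed: int, spec: PhantomSpec | None = None
) -> list[tuple[ODImage, PhantomTruth]]:
    """Generate ``n`` phantoms with per-image seeds derived from ``seed``."""
    spec = spec or PhantomSpec()
    child = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    return [generate_phantom(replace(spec, seed=int(s))) for s in child]


def run_phantom_experiment(cfg: ExperimentConfig | None = None,
                           seed: int = 0) -> ExperimentResult:
    """Run the full pipeline on a synthetic phantom set.

    Phantoms are split by image into disjoint learning/validation/test sets;
    the ICA basis is estimated from learning-split patches only; the network is
    selected on validation-split patches; sensitivity and FPi are measured on
    whole test-split images.
    """
    cfg = cfg or ExperimentConfig()
    n_learn, n_val, n_test = cfg.split
    if n_learn + n_val + n_test > cfg.n_phantoms:
        raise ValueError("split sizes exceed n_phantoms")
    phantoms = make_phantom_set(cfg.n_phantoms, seed, cfg.phantom_spec)
    learn_set = phantoms[:n_learn]
    val_set = phantoms[n_learn:n_learn + n_val]
    test_set = phantoms[n_learn + n_val:n_learn + n_val + n_test]

    margin = cfg.window_px // 2
    table_l = generate_patch_dataset(learn_set, cfg.counts_learn,
                                     margin_px=margin, seed=seed + 1)
    table_v = generate_patch_dataset(val_set, cfg.counts_val,
                                     margin_px=margin, seed=seed + 2)
    by_id = {od.meta.image_id: od for od, _ in phantoms}

    locs_l = list(table_l[["image_id", "row", "col"]].itertuples(index=False))
    locs_v = list(table_v[["image_id", "row", "col"]].itertuples(index=False))
    patches_l = sample_patches(by_id, locs_l, cfg.window_px)
    patches_v = sample_patches(by_id, locs_v, cfg.window_px)

    basis = fit_ica_basis(patches_l, cfg.n_components, seed=seed,
                          strict_convergence=False)

    class_idx = {c: i for i, c in enumerate(CLASSES)}
    X = np.vstack([basis.transform(patches_l.X), basis.transform(patches_v.X)])
    y = np.concatenate([
        table_l["label"].map(class_idx).to_numpy(),
        table_v["label"].map(class_idx).to_numpy(),
    ])
    split = {"learn": np.arange(len(table_l)),
             "val": np.arange(len(table_l), len(table_l) + len(table_v))}

    model, report = sweep_train(
        X, y, split, hidden_sizes=cfg.hidden_sizes, n_restarts=cfg.n_restarts,
        base_seed=seed, config=cfg.rprop, n_out=len(CLASSES))

    total = OutcomeCounts()
    per_image_rows = []
    rois_all = []
    test_images = [od for od, _ in test_set]
    test_truths = [truth.cluster_regions for _, truth in test_set]
    for od, truth in test_set:
        det = classify_image(model, basis, od, cfg.analyzer,
                             positive_classes=cfg.positive_classes)
        counts, rois = evaluate_detections(
            det, truth.cluster_regions, od.meta.pixel_size_um,
            cfg.min_object_px, cfg.max_object_px, cfg.density_threshold)
        total = total + counts
        rois_all.append(rois)
        per_image_rows.append({
            "image_id": od.meta.image_id, "tp": counts.tp, "fp": counts.fp,
            "fn": counts.fn, "tn": counts.tn, "n_rois": len(rois)})

    return ExperimentResult(
        sensitivity=sensitivity(total),
        fpi=fpi(total),
        counts=total,
        model=model,
        basis=basis,
        sweep_report=report,
        test_images=test_images,
        test_truths=test_truths,
        per_image=pd.DataFrame(per_image_rows),
        rois_per_image=rois_all,
    )
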
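"""Persistence for trained MLP models: .npz archive with a content hash."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .classifier import MLPModel
from .errors import ValidationError

__all__ = ["save_model", "load_model"]


def _model_hash(model: MLPModel) -> str:
    h = hashlib.sha256()
    for arr in (model.W1, model.b1, model.W2, model.b2):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(json.dumps([model.seed, model.epochs_run]).encode())
    return h.hexdigest()


def save_model(model: MLPModel, path: str | Path) -> None:
    np.savez(
        path,
        W1=model.W1, b1=model.b1, W2=model.W2, b2=model.b2,
        seed=model.seed, epochs_run=model.epochs_run,
        validation_score=model.validation_score,
        content_hash=np.bytes_(_model_hash(model).encode()),
    )


def load_model(path: str | Path) -> MLPModel:
    with np.load(path) as arc:
        model = MLPModel(
            W1=arc["W1"], b1=arc["b1"], W2=arc["W2"], b2=arc["b2"],
            seed=int(arc["seed"]), epochs_run=int(arc["epochs_run"]),
            validation_score=float(arc["validation_score"]),
        )
        stored = bytes(arc["content_hash"]).decode()
    if stored != _model_hash(model):
        raise ValidationError(f"model archive {path} failed its content-hash check")
    return model
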
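"""Flat JSON-text persistence for fitted models and feature tensors.

Every model in the package serializes to a single JSON document: scalar
hyperparameters as keys, matrices as nested lists.  Human-inspectable and
dependency-free; not meant for very large models.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .decomposition import LoadingsModel, LowRankSparse, TwoDProjection
from .exceptions import ArchiveFormatError
from .preprocessing import FeatureTensor
from .smm import SMMModel

__all__ = ["save_model", "load_model", "save_features", "load_features"]

_KINDS = {
    "LoadingsModel": LoadingsModel,
    "TwoDProjection": TwoDProjection,
    "LowRankSparse": LowRankSparse,
    "SMMModel": SMMModel,
}


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_encode(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj.get("dtype", "float64"))
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(o) for o in obj]
    return obj


def save_model(model, path) -> None:
    """Serialize a fitted model to a JSON text file."""
    kind = type(model).__name__
    if kind not in _KINDS:
        raise ArchiveFormatError(f"cannot persist objects of type {kind}")
    doc = {"kind": kind}
    for name, value in vars(model).items():
        doc[name] = _encode(value)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_model(path):
    """Load a model saved with :func:`save_model`."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    kind = doc.pop("kind", None)
    if kind not in _KINDS:
        raise ArchiveFormatError(f"unknown model kind {kind!r} in {path}")
    fields = {k: _decode(v) for k, v in doc.items()}
    return _KINDS[kind](**fields)


def save_features(ft: FeatureTensor, path) -> None:
    """Serialize a :class:`FeatureTensor` to a JSON text file."""
    doc = {
        "kind": "FeatureTensor",
        "features": _encode(ft.features),
        "labels": _encode(np.asarray(ft.labels)),
        "feature_names": list(ft.feature_names),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_features(path) -> FeatureTensor:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("kind") != "FeatureTensor":
        raise ArchiveFormatError(f"{path} does not hold a FeatureTensor")
    labels = _decode(doc["labels"])
    return FeatureTensor(_decode(doc["features"]), labels,
                         doc.get("feature_names"))
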
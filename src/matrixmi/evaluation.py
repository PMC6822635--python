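"""Metrics, stratified cross-validation and pipeline orchestration.

Cohen's kappa is used in its balanced-class form: the chance level is
``p_o = 1/k`` for a k-class problem, so ``kappa = (acc - 1/k)/(1 - 1/k)``.
This differs from the general marginal-product definition and is the
appropriate form when every class has the same number of trials.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, InvalidParameterError
from .preprocessing import (
    FeatureTensor,
    TrialSet,
    csp_fit,
    csp_transform,
    tdp_features,
)

__all__ = [
    "EvalReport",
    "cohen_kappa",
    "precision_recall_f",
    "stratified_kfold",
    "pairwise_tasks",
    "cross_validate",
]


@dataclass
class EvalReport:
    """Aggregated cross-validation result."""

    accuracy: float
    p_o: float
    kappa: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    classes: np.ndarray
    fold_results: list
    seed: int
    zero_division_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "p_o": self.p_o,
            "kappa": self.kappa,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "classes": [c.item() if hasattr(c, "item") else c
                        for c in self.classes],
            "fold_accuracies": [f["accuracy"] for f in self.fold_results],
            "seed": self.seed,
        }

    def summary(self) -> str:
        """Fixed-width text table of the headline metrics."""
        lines = [
            f"{'metric':<16}{'value':>10}",
            f"{'accuracy':<16}{self.accuracy:>10.4f}",
            f"{'kappa':<16}{self.kappa:>10.4f}",
            f"{'macro precision':<16}{self.macro_precision:>10.4f}",
            f"{'macro recall':<16}{self.macro_recall:>10.4f}",
            f"{'macro F1':<16}{self.macro_f1:>10.4f}",
        ]
        return "\n".join(lines)


def cohen_kappa(accuracy: float, n_classes: int) -> float:
    """Chance-corrected accuracy with balanced chance ``p_o = 1/k``."""
    if n_classes < 2:
        raise InvalidParameterError(f"n_classes must be >= 2, got {n_classes}")
    if not 0 <= accuracy <= 1:
        raise InvalidParameterError(f"accuracy must be in [0, 1], got {accuracy}")
    p_o = 1.0 / n_classes
    return (accuracy - p_o) / (1.0 - p_o)


def precision_recall_f(confusion) -> dict:
    """Per-class precision/recall/F1 and macro averages from a confusion
    matrix (rows = true class, cols = predicted class).

    Zero denominators yield 0 and are flagged in ``zero_division_flags``.
    """
    conf = np.asarray(confusion)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise InvalidParameterError("confusion must be a square matrix")
    if np.any(conf < 0):
        raise InvalidParameterError("confusion counts must be nonnegative")
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    flags = []
    k = conf.shape[0]
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    for i in range(k):
        if tp[i] + fp[i] > 0:
            precision[i] = tp[i] / (tp[i] + fp[i])
        else:
            flags.append(("precision", i))
        if tp[i] + fn[i] > 0:
            recall[i] = tp[i] / (tp[i] + fn[i])
        else:
            flags.append(("recall", i))
        if precision[i] + recall[i] > 0:
            f1[i] = 2 * precision[i] * recall[i] / (precision[i] + recall[i])
        else:
            flags.append(("f1", i))
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "zero_division_flags": flags,
    }


def stratified_kfold(labels, k: int, seed: int) -> list:
    """k disjoint validation index sets with per-fold class balance.

    Deterministic given ``seed``; warns (best effort) when a class has
    fewer than ``k`` members.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise InvalidParameterError(f"k must be >= 2, got {k}")
    if k > n:
        raise InvalidParameterError(f"k={k} exceeds {n} samples")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} member(s) < k={k}; "
            "folds will be best-effort", stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        folds = [val for _, val in skf.split(np.zeros((n, 1)), labels)]
    return folds


def pairwise_tasks(classes) -> list:
    """All C(k, 2) unordered class pairs in lexicographic order."""
    cs = sorted(set(classes))
    if len(cs) < 2:
        raise InvalidParameterError("need >= 2 classes for pairwise tasks")
    return list(itertools.combinations(cs, 2))


# ---------------------------------------------------------------------------
# pipeline cross-validation
# ---------------------------------------------------------------------------

_FEATURE_METHODS = ("none", "csp", "tdp")
_CLASSIFIERS = ("svm", "rsmm")


def _extract_features(train_ts: TrialSet, test_ts: TrialSet, config: dict):
    method = config.get("feature", "tdp")
    if method == "tdp":
        K = int(config.get("tdp_K", 2))
        return tdp_features(train_ts, K), tdp_features(test_ts, K)
    if method == "csp":
        m = int(config.get("csp_m", 2))
        classes = np.unique(train_ts.labels)
        if len(classes) != 2:
            raise ConfigurationError("csp feature method needs exactly 2 classes")
        model = csp_fit(train_ts, (classes[0], classes[1]))
        return csp_transform(model, train_ts, m), csp_transform(model, test_ts, m)
    raise ConfigurationError(f"unknown feature method {method!r}")


def _fit_classifier(ft: FeatureTensor, config: dict):
    from . import smm

    clf = config.get("classifier", "rsmm")
    C = float(config.get("C", 1.0))
    if clf == "svm":
        return smm.svm_baseline_fit(ft, C=C)
    if clf == "rsmm":
        return smm.rsmm_fit_multiclass(
            ft,
            gamma=float(config.get("gamma", 0.1)),
            tau=float(config.get("tau", 0.1)),
            C=C,
            max_iter=int(config.get("max_iter", 200)),
        )
    raise ConfigurationError(f"unknown classifier {clf!r}")


def cross_validate(data, pipeline_config: dict, k: int = 5,
                   seed: int = 0) -> EvalReport:
    """Stratified k-fold evaluation of a feature + classifier pipeline.

    ``data`` is a :class:`TrialSet` (a feature method then applies per fold,
    fitted on the training split only — no leakage) or a
    :class:`FeatureTensor` (used as-is, ``feature: none``).  Deterministic
    given ``seed``.
    """
    from . import smm

    feature = pipeline_config.get("feature", "tdp")
    classifier = pipeline_config.get("classifier", "rsmm")
    if feature not in _FEATURE_METHODS:
        raise ConfigurationError(f"unknown feature method {feature!r}")
    if classifier not in _CLASSIFIERS:
        raise ConfigurationError(f"unknown classifier {classifier!r}")
    labels = data.labels
    classes = np.unique(labels)
    folds = stratified_kfold(labels, k, seed)
    all_idx = np.arange(len(labels))
    kc = len(classes)
    class_pos = {c.item() if hasattr(c, "item") else c: i
                 for i, c in enumerate(classes)}
    confusion = np.zeros((kc, kc), dtype=int)
    fold_results = []
    for fold_id, val in enumerate(folds):
        train = np.setdiff1d(all_idx, val)
        if isinstance(data, TrialSet):
            ft_train, ft_val = _extract_features(
                data.subset(train), data.subset(val), pipeline_config
            )
        else:
            ft_train, ft_val = data.subset(train), data.subset(val)
        model = _fit_classifier(ft_train, pipeline_config)
        pred = smm.smm_predict(model, ft_val)
        fold_conf = np.zeros((kc, kc), dtype=int)
        for t, p in zip(labels[val], pred):
            fold_conf[class_pos[t.item() if hasattr(t, "item") else t],
                      class_pos[p.item() if hasattr(p, "item") else p]] += 1
        confusion += fold_conf
        fold_results.append({
            "fold": fold_id,
            "n": int(len(val)),
            "accuracy": float(np.trace(fold_conf) / len(val)),
            "confusion": fold_conf,
        })
    accuracy = float(np.trace(confusion) / confusion.sum())
    prf = precision_recall_f(confusion)
    return EvalReport(
        accuracy=accuracy,
        p_o=1.0 / kc,
        kappa=cohen_kappa(accuracy, kc),
        precision=prf["precision"],
        recall=prf["recall"],
        f1=prf["f1"],
        macro_precision=prf["macro_precision"],
        macro_recall=prf["macro_recall"],
        macro_f1=prf["macro_f1"],
        confusion=confusion,
        classes=classes,
        fold_results=fold_results,
        seed=seed,
        zero_division_flags=prf["zero_division_flags"],
    )
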
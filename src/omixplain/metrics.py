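"""Evaluation metric registry with orientation metadata.

Each metric knows whether it is score-type (larger is better, ideal 1) or
error-type (smaller is better, ideal 0); the best-model rule and the
automated-k window rule both depend on that orientation.  F1 and precision
are binary for two classes and support-weighted for multiclass.
MAPE is reported in percent: 100 · mean(|y − ŷ| / |y|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm


@dataclass(frozen=True)
class MetricInfo:
    name: str
    kind: str  # "score" | "error"
    problem: str  # "class" | "numeric"
    needs_proba: bool = False


_REGISTRY: dict[str, MetricInfo] = {
    "accuracy": MetricInfo("accuracy", "score", "class"),
    "f1": MetricInfo("f1", "score", "class"),
    "precision": MetricInfo("precision", "score", "class"),
    "recall": MetricInfo("recall", "score", "class"),
    "roc_auc": MetricInfo("roc_auc", "score", "class", needs_proba=True),
    "mse": MetricInfo("mse", "error", "numeric"),
    "mae": MetricInfo("mae", "error", "numeric"),
    "mape": MetricInfo("mape", "error", "numeric"),
    "r2": MetricInfo("r2", "score", "numeric"),
}

CLASSIFICATION_PANEL = ["accuracy", "f1", "precision", "recall", "roc_auc"]
REGRESSION_PANEL = ["mse", "mae", "mape", "r2"]


def metric_info(name: str) -> MetricInfo:
    if name not in _REGISTRY:
        raise ValueError(
            f"unknown metric {name!r}; available: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def metric_panel(problem_type: str) -> list[str]:
    return CLASSIFICATION_PANEL if problem_type == "classification" else REGRESSION_PANEL


def _average(y_true) -> str:
    return "binary" if np.unique(y_true).size == 2 else "weighted"


def compute_metric(
    name: str,
    y_true: np.ndarray,
    y_pred: np.ndarray | None = None,
    y_proba: np.ndarray | None = None,
    classes: list | None = None,
    positive_label=None,
) -> float:
    """Compute one metric from predictions (or class probabilities for AUC)."""
    info = metric_info(name)
    y_true = np.asarray(y_true)
    if info.needs_proba:
        if y_proba is None:
            raise ValueError(f"{name} needs class probability scores")
        if np.unique(y_true).size < 2:
            raise ValueError(f"{name} undefined with a single class present")
        proba = np.asarray(y_proba)
        if proba.ndim == 1:
            return float(skm.roc_auc_score(y_true, proba))
        if proba.shape[1] == 2:
            return float(skm.roc_auc_score(y_true, proba[:, 1]))
        return float(
            skm.roc_auc_score(
                y_true, proba, multi_class="ovr", average="weighted", labels=classes
            )
        )
    y_pred = np.asarray(y_pred)
    if name == "accuracy":
        return float(skm.accuracy_score(y_true, y_pred))
    if name in ("f1", "precision", "recall"):
        avg = _average(y_true)
        kwargs = {"average": avg, "zero_division": 0}
        if avg == "binary":
            pos = positive_label if positive_label is not None else sorted(
                np.unique(y_true).tolist()
            )[-1]
            kwargs["pos_label"] = pos
        fn = {"f1": skm.f1_score, "precision": skm.precision_score, "recall": skm.recall_score}[name]
        return float(fn(y_true, y_pred, **kwargs))
    if name == "mse":
        return float(skm.mean_squared_error(y_true, y_pred))
    if name == "mae":
        return float(skm.mean_absolute_error(y_true, y_pred))
    if name == "mape":
        y_true = y_true.astype(float)
        if np.any(y_true == 0):
            raise ValueError("MAPE undefined when any true value is 0")
        return float(100.0 * np.mean(np.abs(y_true - y_pred) / np.abs(y_true)))
    if name == "r2":
        return float(skm.r2_score(y_true, y_pred))
    raise AssertionError(name)


def sklearn_scorer(name: str, target=None):
    """A cross-validation scorer built on :func:`compute_metric`.

    Error metrics come back negated (sklearn convention: larger is always
    better inside a search); callers flip the sign when reporting on the
    natural scale.
    """
    info = metric_info(name)
    classes = None
    if target is not None and getattr(target, "kind", None) == "class":
        classes = sorted(set(np.asarray(target.values).tolist()))

    if info.needs_proba:
        def proba_fn(y_true, y_proba):
            return compute_metric(name, y_true, y_proba=y_proba, classes=classes)

        return skm.make_scorer(proba_fn, response_method="predict_proba")

    def pred_fn(y_true, y_pred):
        return compute_metric(name, y_true, y_pred=y_pred, classes=classes)

    return skm.make_scorer(pred_fn, greater_is_better=(info.kind == "score"))
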
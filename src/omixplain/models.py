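"""Model registry, hyperparameter search, and cross-validated evaluation.

Registry entries cover the classical learners used throughout the tool:
random forest, gradient-boosted trees (XGBoost backend), AdaBoost,
k-nearest neighbours, and a LightGBM-style booster.  Each entry resolves to
a classifier or regressor to match the problem type and carries a fixed,
documented search space for grid search plus a sampling space for random
search (default budget 20 draws).  The winner of a search is refit on the
full training partition; per-fold cross-validation scores of the winner are
retained for box plots and the results table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    RandomizedSearchCV,
    StratifiedKFold,
    cross_validate,
)
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor

from .io_tabular import TableError
from .metrics import compute_metric, metric_info, metric_panel, sklearn_scorer
from .split_transform import SplitDataset

logger = logging.getLogger(__name__)

try:  # optional boosting backends: skip with a warning when absent
    from xgboost import XGBClassifier, XGBRegressor

    _HAVE_XGB = True
except ImportError:  # pragma: no cover - backend present in supported envs
    _HAVE_XGB = False

try:
    from lightgbm import LGBMClassifier, LGBMRegressor

    _HAVE_LGBM = True
except ImportError:  # pragma: no cover
    _HAVE_LGBM = False


@dataclass
class ModelSpec:
    name: str
    make: Any  # callable(problem_type, seed) -> estimator
    grid: dict[str, list]
    random_space: dict[str, list]


def _make_rf(problem_type: str, seed: int):
    cls = RandomForestClassifier if problem_type == "classification" else RandomForestRegressor
    return cls(n_estimators=100, random_state=seed)


def _make_xgb(problem_type: str, seed: int):
    if problem_type == "classification":
        return XGBClassifier(
            n_estimators=100, random_state=seed, eval_metric="logloss", verbosity=0
        )
    return XGBRegressor(n_estimators=100, random_state=seed, verbosity=0)


def _make_adaboost(problem_type: str, seed: int):
    cls = AdaBoostClassifier if problem_type == "classification" else AdaBoostRegressor
    return cls(random_state=seed)


def _make_knn(problem_type: str, seed: int):
    cls = KNeighborsClassifier if problem_type == "classification" else KNeighborsRegressor
    return cls()


def _make_lgbm(problem_type: str, seed: int):
    cls = LGBMClassifier if problem_type == "classification" else LGBMRegressor
    return cls(n_estimators=100, random_state=seed, verbose=-1)


_TREE_GRID = {"n_estimators": [100, 300], "max_depth": [3, 6, None]}
_BOOST_GRID = {"n_estimators": [100, 300], "learning_rate": [0.3, 0.1, 0.03]}
_TREE_RANDOM = {"n_estimators": [100, 200, 300, 500], "max_depth": [3, 6, 12, None]}
_BOOST_RANDOM = {
    "n_estimators": [100, 200, 300, 500],
    "learning_rate": [0.3, 0.1, 0.03],
    "max_depth": [3, 6, 12],
}

REGISTRY: dict[str, ModelSpec] = {
    "rf": ModelSpec("rf", _make_rf, _TREE_GRID, _TREE_RANDOM),
    "adaboost": ModelSpec(
        "adaboost",
        _make_adaboost,
        {"n_estimators": [50, 100], "learning_rate": [1.0, 0.5]},
        {"n_estimators": [50, 100, 200], "learning_rate": [1.0, 0.5, 0.1]},
    ),
    "knn": ModelSpec(
        "knn",
        _make_knn,
        {"n_neighbors": [3, 5, 11], "weights": ["uniform", "distance"]},
        {"n_neighbors": [3, 5, 11, 21], "weights": ["uniform", "distance"]},
    ),
}
if _HAVE_XGB:
    REGISTRY["gradient_boosted_trees"] = ModelSpec(
        "gradient_boosted_trees", _make_xgb, _BOOST_GRID, _BOOST_RANDOM
    )
else:  # pragma: no cover
    logger.warning("xgboost backend missing; gradient_boosted_trees skipped")
if _HAVE_LGBM:
    REGISTRY["lightgbm_style"] = ModelSpec(
        "lightgbm_style", _make_lgbm, _BOOST_GRID, _BOOST_RANDOM
    )
else:  # pragma: no cover
    logger.warning("lightgbm backend missing; lightgbm_style skipped")

#: registry order used for deterministic tie-breaking
REGISTRY_ORDER = ["rf", "gradient_boosted_trees", "adaboost", "knn", "lightgbm_style"]


@dataclass
class ModelResult:
    """One tuned model: identity, hyperparameters, CV scores, metric sets."""

    name: str
    best_params: dict
    cv_scores: list[float]
    model: Any
    scoring: str
    train_metrics: dict[str, float] = field(default_factory=dict)
    test_metrics: dict[str, float] = field(default_factory=dict)
    cv_metrics: dict[str, tuple[float, float]] = field(default_factory=dict)
    predictions: dict[str, Any] = field(default_factory=dict)


class _LabelEncodedModel:
    """Wraps an estimator needing integer labels (xgboost) behind string labels."""

    def __init__(self, estimator, classes: list[str]):
        self.estimator = estimator
        self.classes_list = list(classes)

    def fit(self, X, y):
        idx = {c: i for i, c in enumerate(self.classes_list)}
        self.estimator.fit(X, np.array([idx[v] for v in y]))
        return self

    def predict(self, X):
        codes = np.asarray(self.estimator.predict(X)).astype(int)
        return np.array(self.classes_list, dtype=object)[codes]

    def predict_proba(self, X):
        return self.estimator.predict_proba(X)

    def get_params(self, deep=True):  # sklearn clone support
        return {"estimator": self.estimator, "classes": self.classes_list}

    def set_params(self, **params):  # pragma: no cover - not tuned directly
        return self


def _needs_label_encoding(estimator) -> bool:
    return _HAVE_XGB and isinstance(estimator, XGBClassifier)


def make_cv(problem_type: str, n_folds: int, seed: int):
    if problem_type == "classification":
        return StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return KFold(n_splits=n_folds, shuffle=True, random_state=seed)


def tune_and_fit(
    spec_name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    problem_type: str,
    search: str = "random",
    scoring: str | None = None,
    n_folds: int = 5,
    seed: int = 42,
    n_random_draws: int = 20,
    target=None,
) -> ModelResult:
    """Hyper-tune one registry model and refit the winner on all of X_train.

    ``search``: "grid" is exhaustive over the spec's grid, "random" draws a
    fixed budget (default 20) from the spec's sampling space, "none" keeps
    the defaults.  Deterministic given the seed.
    """
    if spec_name not in REGISTRY:
        raise TableError(
            f"unknown model {spec_name!r}; available: {sorted(REGISTRY)}"
        )
    info = metric_info(scoring)
    if (info.problem == "class") != (problem_type == "classification"):
        raise TableError(
            f"scoring {scoring!r} incompatible with {problem_type}"
        )
    spec = REGISTRY[spec_name]
    estimator = spec.make(problem_type, seed)

    classes = None
    if problem_type == "classification":
        classes = sorted(set(np.asarray(y_train).tolist()))
        if _needs_label_encoding(estimator):
            y_fit = np.array([classes.index(v) for v in y_train])
        else:
            y_fit = np.asarray(y_train)
    else:
        y_fit = np.asarray(y_train, dtype=float)

    # xgboost sees integer-encoded labels; score against them consistently
    if classes is not None and _needs_label_encoding(estimator):
        class _IntTarget:
            kind = "class"
            values = np.arange(len(classes))

        scorer = sklearn_scorer(scoring, _IntTarget())
    else:
        scorer = sklearn_scorer(scoring, target)
    cv = make_cv(problem_type, n_folds, seed)

    if search == "grid":
        searcher = GridSearchCV(estimator, spec.grid, scoring=scorer, cv=cv, refit=True)
        searcher.fit(X_train, y_fit)
        best, params = searcher.best_estimator_, searcher.best_params_
    elif search == "random":
        searcher = RandomizedSearchCV(
            estimator,
            spec.random_space,
            n_iter=n_random_draws,
            scoring=scorer,
            cv=cv,
            random_state=seed,
            refit=True,
        )
        searcher.fit(X_train, y_fit)
        best, params = searcher.best_estimator_, searcher.best_params_
    elif search == "none":
        best, params = estimator, {}
        best.fit(X_train, y_fit)
    else:
        raise TableError(f"unknown search mode {search!r}")

    # per-fold CV of the winner, on the configured metric's natural scale
    cvres = cross_validate(best, X_train, y_fit, cv=cv, scoring=scorer)
    raw = cvres["test_score"]
    fold_scores = (-raw if info.kind == "error" else raw).tolist()

    best.fit(X_train, y_fit)
    if classes is not None and _needs_label_encoding(best):
        best = _LabelEncodedModel(best, classes)
        best.fit(X_train, y_train)

    return ModelResult(
        name=spec_name,
        best_params=params,
        cv_scores=fold_scores,
        model=best,
        scoring=scoring,
    )


def evaluate_on_split(
    result: ModelResult,
    split: SplitDataset,
    panel: list[str],
    problem_type: str,
) -> ModelResult:
    """Fill train/test metric sets and cache predictions for plots/explanations."""
    classes = split.y_train.classes() if problem_type == "classification" else None
    for part, X, y in (
        ("train", split.X_train.values, split.y_train.values),
        ("test", split.X_test.values, split.y_test.values),
    ):
        pred = result.model.predict(X)
        proba = None
        if problem_type == "classification" and hasattr(result.model, "predict_proba"):
            proba = result.model.predict_proba(X)
        result.predictions[part] = {"y_true": y, "y_pred": pred, "y_proba": proba}
        metrics = {}
        for name in panel:
            try:
                metrics[name] = compute_metric(
                    name, y, y_pred=pred, y_proba=proba, classes=classes
                )
            except ValueError as exc:
                logger.warning("%s on %s partition skipped: %s", name, part, exc)
                metrics[name] = float("nan")
        if part == "train":
            result.train_metrics = metrics
        else:
            result.test_metrics = metrics
    if result.scoring not in (result.test_metrics or {}):
        raise TableError(
            f"panel must include the configured scoring metric {result.scoring!r}"
        )
    return result
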
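"""Univariate feature selection with an automated best-k search.

Variance thresholding removes constant or near-constant columns; features
are then scored univariately (one-way ANOVA F for classification, the
univariate-regression F for regression) and the k best are kept.  When
k = "auto", candidate values of k are log-spaced between a minimum and a
maximum, each candidate is scored by cross-validating a fixed random-forest
evaluation model on the k best features, and the chosen k is the largest
member of the best-performing, most-stable window of three consecutive
candidates.  A lone spike of good performance flanked by poor neighbours is
deliberately never chosen: instability under adding or removing a handful
of features is treated as evidence of a fragile feature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold, KFold, cross_val_score

from .io_tabular import FeatureTable, TableError, TargetVector
from .metrics import metric_info, sklearn_scorer

logger = logging.getLogger(__name__)


def variance_filter(
    table: FeatureTable, threshold: float = 0.0
) -> tuple[FeatureTable, list[str]]:
    """Keep features with population variance strictly above ``threshold``."""
    if threshold < 0:
        raise TableError("variance threshold must be nonnegative")
    var = table.values.var(axis=0)
    keep = [f for f, v in zip(table.feature_ids, var) if v > threshold]
    removed = [f for f, v in zip(table.feature_ids, var) if v <= threshold]
    if not keep:
        raise TableError("no features remain after variance filtering")
    logger.info("variance_filter: removed %d features", len(removed))
    return table.subset_features(keep), removed


def f_classif_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic of each column against the class labels.

    F = between-class mean square / within-class mean square.  Zero within-
    class variance with nonzero between-class variance gives +inf (perfect
    separation, ranked above every finite score); the fully degenerate
    0/0 case scores 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise TableError("f_classif needs at least 2 classes")
    n, g = X.shape[0], classes.size
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for c in classes:
        block = X[y == c]
        mean_c = block.mean(axis=0)
        ss_between += block.shape[0] * (mean_c - grand) ** 2
        ss_within += ((block - mean_c) ** 2).sum(axis=0)
    ms_between = ss_between / (g - 1)
    ms_within = ss_within / (n - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    f[(ms_within == 0) & (ms_between > 0)] = np.inf
    degenerate = (ms_within == 0) & (ms_between == 0)
    if degenerate.any():
        logger.warning(
            "f_classif: %d constant features scored 0", int(degenerate.sum())
        )
        f[degenerate] = 0.0
    return f


def f_regression_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Univariate linear-regression F statistic: F = r²/(1−r²)·(n−2)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    r = np.nan_to_num(r, nan=0.0)
    r2 = np.clip(r ** 2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        f = r2 / (1.0 - r2) * (n - 2)
    f[r2 >= 1.0] = np.inf
    return f


def scorer_for(kind: str):
    return f_classif_scores if kind == "class" else f_regression_scores


def select_k_best(
    table: FeatureTable, target: TargetVector, k: int, scorer=None
) -> list[str]:
    """IDs of the k highest-scoring features; ties broken by input order."""
    if not 1 <= k <= table.shape[1]:
        raise TableError(
            f"k={k} out of range for {table.shape[1]} features"
        )
    scorer = scorer or scorer_for(target.kind)
    scores = scorer(table.values, target.values)
    # stable sort on negated scores → highest first, input order on ties;
    # +inf sorts above every finite score
    order = np.argsort(-scores, kind="stable")
    chosen = np.sort(order[:k])
    return [table.feature_ids[i] for i in chosen]


@dataclass
class SelectionCurve:
    """The automated-k accuracy curve and its chosen window."""

    candidate_ks: list[int]
    scores: list[float]
    chosen_k: int
    window: tuple[int, int, int]
    window_mean: float
    window_std: float
    scoring: str = "accuracy"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"k": self.candidate_ks, "score": self.scores})


def log_spaced_candidates(
    auto_min: int, auto_max: int, n_candidates: int = 10
) -> list[int]:
    """Unique integer candidates log-spaced in [auto_min, auto_max]."""
    if auto_min < 1 or auto_min >= auto_max:
        raise TableError("need 1 <= auto_min < auto_max")
    raw = np.exp(np.linspace(np.log(auto_min), np.log(auto_max), n_candidates))
    ks = sorted(set(int(round(v)) for v in raw) | {auto_min, auto_max})
    return ks


def choose_window(
    scores: np.ndarray, ks: list[int], higher_is_better: bool = True
) -> tuple[int, float, float]:
    """Pick the best stable window of three consecutive candidate scores.

    Returns (start index, window mean, window std).  Score-type metrics
    maximize mean − std; error-type metrics minimize mean + std.  Ties go
    to the window with better mean, then to the one containing larger k.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise TableError("need at least 3 candidates for the window rule")
    best = None
    for i in range(scores.size - 2):
        w = scores[i : i + 3]
        m, s = w.mean(), w.std()
        crit = (m - s) if higher_is_better else -(m + s)
        mean_crit = m if higher_is_better else -m
        key = (crit, mean_crit, ks[i + 2])
        if best is None or key > best[0]:
            best = (key, i, m, s)
    _, i, m, s = best
    return i, m, s


def auto_select_k(
    table: FeatureTable,
    target: TargetVector,
    auto_min: int,
    auto_max: int,
    scoring: str,
    seed: int,
    n_candidates: int = 10,
    n_folds: int = 5,
) -> tuple[int, SelectionCurve]:
    """Automated best-k search over log-spaced candidates.

    Each candidate k is scored by ``n_folds``-fold cross-validation of a
    100-tree random forest (classifier or regressor to match the target)
    restricted to the k best univariate features, using the configured
    scoring metric.
    """
    if auto_max > table.shape[1]:
        raise TableError(
            f"auto_max={auto_max} exceeds the {table.shape[1]} features"
        )
    ks = log_spaced_candidates(auto_min, auto_max, n_candidates)
    if len(ks) < 3:
        raise TableError("fewer than 3 unique candidate values of k")

    info = metric_info(scoring)
    y = target.values
    if target.kind == "class":
        model = RandomForestClassifier(n_estimators=100, random_state=seed)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        model = RandomForestRegressor(n_estimators=100, random_state=seed)
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scorer = sklearn_scorer(scoring, target)

    scores = []
    for k in ks:
        feats = select_k_best(table, target, k)
        Xk = table.subset_features(feats).values
        cv_scores = cross_val_score(model, Xk, y, cv=cv, scoring=scorer)
        mean = cv_scores.mean()
        # sklearn scorers negate error metrics; report on the natural scale
        scores.append(-mean if info.kind == "error" else mean)
        logger.info("auto_select_k: k=%d mean %s=%.4f", k, scoring, scores[-1])

    i, m, s = choose_window(
        np.array(scores), ks, higher_is_better=(info.kind == "score")
    )
    window = (ks[i], ks[i + 1], ks[i + 2])
    chosen_k = window[2]
    curve = SelectionCurve(
        candidate_ks=ks,
        scores=scores,
        chosen_k=chosen_k,
        window=window,
        window_mean=float(m),
        window_std=float(s),
        scoring=scoring,
    )
    return chosen_k, curve
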
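"""Shapley-value and permutation-importance explanations with CSV export.

A Shapley value is the signed contribution of one feature to one sample's
prediction; for every explained sample the base value plus the sum of the
per-feature attributions equals the model's output for that sample (the
additivity axiom).  Tree ensembles are explained exactly:

* sklearn forests/trees — an in-package implementation of the
  path-dependent polynomial-time tree attribution algorithm, which walks
  every root→leaf path maintaining the subset-size weight polynomial of the
  features split on so far (EXTEND), and at each leaf unwinds each feature
  out of the polynomial (UNWIND) to read off its Shapley weight.  The
  conditional expectation used when a feature is "absent" follows the
  tree's own cover (training sample counts) at each split.
* XGBoost / LightGBM — the boosters' built-in exact tree attributions
  (``pred_contribs`` / ``pred_contrib``), reported on the margin scale.

Models with no tree structure (k-NN, AdaBoost) get a seeded
permutation-sampling estimate whose attributions still sum exactly to
``f(x) − base`` by construction (the per-permutation chain telescopes).

Classification attributions are per class on the probability scale for
sklearn forests and on the per-class margin for boosters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Exact attribution for a single sklearn decision tree
# ---------------------------------------------------------------------------

class _Path:
    __slots__ = ("feature", "zero", "one", "weight")

    def __init__(self, depth: int):
        self.feature = np.empty(depth, dtype=np.int64)
        self.zero = np.empty(depth, dtype=np.float64)
        self.one = np.empty(depth, dtype=np.float64)
        self.weight = np.empty(depth, dtype=np.float64)


def _extend(p: _Path, depth: int, zero: float, one: float, feature: int) -> None:
    p.feature[depth] = feature
    p.zero[depth] = zero
    p.one[depth] = one
    p.weight[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        p.weight[i + 1] += one * p.weight[i] * (i + 1.0) / (depth + 1.0)
        p.weight[i] = zero * p.weight[i] * (depth - i) / (depth + 1.0)


def _unwind(p: _Path, depth: int, idx: int) -> None:
    one = p.one[idx]
    zero = p.zero[idx]
    nxt = p.weight[depth]
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = p.weight[i]
            p.weight[i] = nxt * (depth + 1.0) / ((i + 1.0) * one)
            nxt = tmp - p.weight[i] * zero * (depth - i) / (depth + 1.0)
        else:
            p.weight[i] = p.weight[i] * (depth + 1.0) / (zero * (depth - i))
    for i in range(idx, depth):
        p.feature[i] = p.feature[i + 1]
        p.zero[i] = p.zero[i + 1]
        p.one[i] = p.one[i + 1]


def _unwound_sum(p: _Path, depth: int, idx: int) -> float:
    one = p.one[idx]
    zero = p.zero[idx]
    nxt = p.weight[depth]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (depth + 1.0) / ((i + 1.0) * one)
            total += tmp
            nxt = p.weight[i] - tmp * zero * (depth - i) / (depth + 1.0)
        elif zero != 0.0:
            total += p.weight[i] / zero * (depth + 1.0) / (depth - i)
    return total


@dataclass
class _TreeArrays:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    cover: np.ndarray
    values: np.ndarray  # (n_nodes, n_outputs)

    @classmethod
    def from_sklearn(cls, tree, normalize: bool) -> "_TreeArrays":
        t = tree.tree_
        values = t.value.reshape(t.node_count, -1).astype(float)
        if normalize:
            sums = values.sum(axis=1, keepdims=True)
            sums[sums == 0] = 1.0
            values = values / sums
        return cls(
            children_left=t.children_left,
            children_right=t.children_right,
            feature=t.feature,
            threshold=t.threshold,
            cover=t.weighted_n_node_samples.astype(float),
            values=values,
        )

    def expected_value(self) -> np.ndarray:
        """Cover-weighted mean over leaves — the model output with no features known."""
        out = np.zeros(self.values.shape[1])
        root_cover = self.cover[0]

        def rec(node):
            nonlocal out
            if self.children_left[node] == -1:
                out += self.cover[node] / root_cover * self.values[node]
            else:
                rec(self.children_left[node])
                rec(self.children_right[node])

        rec(0)
        return out


def _tree_shap_single(tree: _TreeArrays, x: np.ndarray, phi: np.ndarray) -> None:
    """Accumulate attributions of one tree for one sample into phi (p, outputs)."""
    max_depth = phi.shape[0] + 2

    def recurse(node, parent: _Path, depth, pzero, pone, pfeature):
        p = _Path(depth + 2)
        p.feature[:depth] = parent.feature[:depth]
        p.zero[:depth] = parent.zero[:depth]
        p.one[:depth] = parent.one[:depth]
        p.weight[:depth] = parent.weight[:depth]
        _extend(p, depth, pzero, pone, pfeature)

        left = tree.children_left[node]
        if left == -1:
            for i in range(1, depth + 1):
                w = _unwound_sum(p, depth, i)
                phi[p.feature[i]] += (
                    w * (p.one[i] - p.zero[i]) * tree.values[node]
                )
            return

        right = tree.children_right[node]
        split = tree.feature[node]
        if x[split] <= tree.threshold[node]:
            hot, cold = left, right
        else:
            hot, cold = right, left
        hot_zero = tree.cover[hot] / tree.cover[node]
        cold_zero = tree.cover[cold] / tree.cover[node]

        inc_zero, inc_one = 1.0, 1.0
        k = -1
        for i in range(1, depth + 1):
            if p.feature[i] == split:
                k = i
                break
        if k >= 0:
            inc_zero, inc_one = p.zero[k], p.one[k]
            _unwind(p, depth, k)
            depth -= 1

        recurse(hot, p, depth + 1, hot_zero * inc_zero, inc_one, split)
        recurse(cold, p, depth + 1, cold_zero * inc_zero, 0.0, split)

    recurse(0, _Path(1), 0, 1.0, 1.0, -1)


def _kernel():
    global _FAST_KERNEL
    if _FAST_KERNEL is None:
        try:
            from ._treeshap_fast import tree_shap_kernel

            _FAST_KERNEL = tree_shap_kernel
        except ImportError:  # pragma: no cover - numba present in supported envs
            _FAST_KERNEL = False
    return _FAST_KERNEL


_FAST_KERNEL = None


def shap_values_sklearn_tree(
    tree, X: np.ndarray, normalize: bool = False, use_fast: bool | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact attributions for one fitted sklearn decision tree.

    Returns (phi of shape (n, p, n_outputs), base of shape (n_outputs,)).
    The compiled kernel is used when available; ``use_fast=False`` forces
    the pure-Python reference implementation.
    """
    arrays = _TreeArrays.from_sklearn(tree, normalize)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    phi = np.zeros((n, p, arrays.values.shape[1]))
    kernel = _kernel() if use_fast is not False else False
    if use_fast and not kernel:  # pragma: no cover
        raise RuntimeError("compiled tree-attribution kernel unavailable")
    if kernel:
        for s in range(n):
            kernel(
                arrays.children_left,
                arrays.children_right,
                arrays.feature,
                arrays.threshold,
                arrays.cover,
                arrays.values,
                X[s],
                phi[s],
            )
    else:
        for s in range(n):
            _tree_shap_single(arrays, X[s], phi[s])
    return phi, arrays.expected_value()


def shap_values_forest(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attributions for a sklearn forest: the mean over its trees.

    Classification forests are explained on the probability scale, matching
    ``predict_proba`` (the forest probability is the mean of per-tree leaf
    class fractions).
    """
    from sklearn.ensemble import RandomForestClassifier

    normalize = isinstance(model, RandomForestClassifier) or hasattr(model, "classes_")
    trees = model.estimators_
    phi = None
    base = None
    for t in trees:
        p, b = shap_values_sklearn_tree(t, X, normalize=normalize)
        phi = p if phi is None else phi + p
        base = b if base is None else base + b
    return phi / len(trees), base / len(trees)


# ---------------------------------------------------------------------------
# Booster built-ins and the sampling fallback
# ---------------------------------------------------------------------------

def _shap_values_xgboost(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    import xgboost as xgb

    booster = model.get_booster()
    contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
    if contribs.ndim == 2:  # binary / regression: (n, p+1)
        phi = contribs[:, :-1][:, :, None]
        base = contribs[0, -1:][None, :].ravel()
    else:  # multiclass: (n, n_class, p+1)
        phi = np.moveaxis(contribs[:, :, :-1], 1, 2)
        base = contribs[0, :, -1]
    return phi, np.atleast_1d(base)


def _shap_values_lightgbm(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    contribs = model.predict(X, pred_contrib=True)
    n, p = X.shape
    n_out = contribs.shape[1] // (p + 1)
    contribs = contribs.reshape(n, n_out, p + 1)
    phi = np.moveaxis(contribs[:, :, :-1], 1, 2)
    base = contribs[0, :, -1]
    return phi, np.atleast_1d(base)


def sampling_shapley(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    X_explain: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded permutation-sampling Shapley estimate for arbitrary models.

    For each permutation a background row is drawn; features are revealed
    in permutation order and each feature is credited with the change in
    model output it causes.  The per-permutation chain telescopes, so
    attributions sum exactly to f(x) − base with base the mean output over
    the drawn background rows.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X_explain, dtype=float)
    n, p = X.shape
    first = np.atleast_2d(predict_fn(X[:1]))
    n_out = first.shape[1]
    phi = np.zeros((n, p, n_out))
    base = np.zeros(n_out)
    for _ in range(n_permutations):
        order = rng.permutation(p)
        b = background[rng.integers(len(background))]
        current = np.tile(b, (n, 1))
        prev = np.atleast_2d(predict_fn(current))
        base += prev[0]
        for j in order:
            current[:, j] = X[:, j]
            out = np.atleast_2d(predict_fn(current))
            phi[:, j, :] += out - prev
            prev = out
    return phi / n_permutations, base / n_permutations


# ---------------------------------------------------------------------------
# Dispatch, bundles, permutation importance, export
# ---------------------------------------------------------------------------

@dataclass
class ExplanationBundle:
    """Per-sample, per-feature attributions plus global summaries."""

    feature_ids: list[str]
    sample_ids: list[str]
    attributions: dict[str, pd.DataFrame]  # output name → samples × features
    base_values: dict[str, float]
    output_scale: str  # "probability" | "margin" | "response"
    permutation_importance: pd.DataFrame | None = None
    top_n: int = 15

    def global_ranking(self) -> pd.DataFrame:
        """Features ordered by mean |attribution| pooled over outputs/samples."""
        stacked = np.stack([df.to_numpy() for df in self.attributions.values()])
        mean_abs = np.abs(stacked).mean(axis=(0, 1))
        order = np.argsort(-mean_abs, kind="stable")
        ranked = pd.DataFrame(
            {
                "feature": [self.feature_ids[i] for i in order],
                "mean_abs_attribution": mean_abs[order],
            }
        )
        return ranked.head(min(self.top_n, len(self.feature_ids)))


def model_output_fn(model, problem_type: str):
    """The output the attributions decompose, and its scale name."""
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    try:
        from omixplain.models import _LabelEncodedModel

        if isinstance(model, _LabelEncodedModel):
            model = model.estimator
    except ImportError:  # pragma: no cover
        pass
    name = type(model).__name__
    if name.startswith("XGB"):
        import xgboost as xgb

        booster = model.get_booster()

        def margin(X):
            out = booster.predict(xgb.DMatrix(np.asarray(X, dtype=float)), output_margin=True)
            return np.atleast_2d(out.T).T if out.ndim == 1 else out

        return margin, "margin"
    if name.startswith("LGBM"):
        def raw(X):
            out = model.predict(np.asarray(X, dtype=float), raw_score=True)
            return out[:, None] if out.ndim == 1 else out

        return raw, "margin"
    if problem_type == "classification" and hasattr(model, "predict_proba"):
        return (lambda X: model.predict_proba(np.asarray(X, dtype=float))), "probability"
    return (
        lambda X: np.asarray(model.predict(np.asarray(X, dtype=float)), dtype=float)[:, None],
        "response",
    )


def _unwrap(model):
    try:
        from omixplain.models import _LabelEncodedModel

        if isinstance(model, _LabelEncodedModel):
            return model.estimator
    except ImportError:  # pragma: no cover
        pass
    return model


def shapley_explanations(
    model,
    X_explain: pd.DataFrame,
    problem_type: str,
    class_names: list[str] | None = None,
    background: np.ndarray | None = None,
    top_n: int = 15,
    seed: int = 0,
) -> ExplanationBundle:
    """Per-sample additive attributions for a fitted model.

    Tree ensembles get exact attributions; other models a seeded sampling
    approximation (requires ``background`` rows, typically the training
    partition).
    """
    inner = _unwrap(model)
    name = type(inner).__name__
    X = X_explain.to_numpy(dtype=float)

    if name in ("RandomForestClassifier", "RandomForestRegressor", "DecisionTreeClassifier", "DecisionTreeRegressor"):
        if name.startswith("DecisionTree"):
            phi, base = shap_values_sklearn_tree(
                inner, X, normalize=name.endswith("Classifier")
            )
        else:
            phi, base = shap_values_forest(inner, X)
        scale = "probability" if name.endswith("Classifier") else "response"
    elif name.startswith("XGB"):
        phi, base = _shap_values_xgboost(inner, X)
        scale = "margin"
    elif name.startswith("LGBM"):
        phi, base = _shap_values_lightgbm(inner, X)
        scale = "margin"
    else:
        if background is None:
            raise ValueError(
                f"{name} has no exact tree explainer; sampling needs background rows"
            )
        fn, scale = model_output_fn(model, problem_type)
        phi, base = sampling_shapley(fn, X, background, seed=seed)

    n_out = phi.shape[2]
    if problem_type == "classification":
        if class_names is None or len(class_names) != n_out:
            if n_out == 1 and class_names and len(class_names) == 2:
                # single-margin binary booster: one output for the second class
                outputs = [class_names[1]]
            else:
                outputs = [f"class{i}" for i in range(n_out)]
        else:
            outputs = list(class_names)
    else:
        outputs = ["value"]

    attributions = {
        out: pd.DataFrame(
            phi[:, :, i], index=X_explain.index, columns=X_explain.columns
        )
        for i, out in enumerate(outputs)
    }
    base_values = {out: float(base[i]) for i, out in enumerate(outputs)}
    return ExplanationBundle(
        feature_ids=list(X_explain.columns),
        sample_ids=list(X_explain.index.astype(str)),
        attributions=attributions,
        base_values=base_values,
        output_scale=scale,
        top_n=top_n,
    )


def permutation_importance_table(
    model,
    X_eval: pd.DataFrame,
    y_eval: np.ndarray,
    scoring: str,
    target=None,
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ± sd drop in the evaluation score over seeded column shuffles."""
    from sklearn.inspection import permutation_importance as _perm

    from .metrics import sklearn_scorer

    scorer = sklearn_scorer(scoring, target)
    res = _perm(
        model,
        X_eval.to_numpy(dtype=float),
        y_eval,
        scoring=scorer,
        n_repeats=repeats,
        random_state=seed,
    )
    table = pd.DataFrame(
        {
            "feature": list(X_eval.columns),
            "importance_mean": res.importances_mean,
            "importance_sd": res.importances_std,
        }
    ).sort_values("importance_mean", ascending=False, kind="stable")
    return table.reset_index(drop=True)


def _safe(name: str) -> str:
    return "".join(c if (c.isalnum() or c in "-_.") else "_" for c in str(name))


def export_explanations(
    bundle: ExplanationBundle,
    model_name: str,
    out_dir: str | Path,
    problem_type: str,
) -> list[Path]:
    """Write the fixed-name CSV exports.

    ``shapley_values_all_[NameOfModelAndClassIfApplicable].csv`` — one
    samples × features table per class for classification, a single table
    for regression — and ``permutimp_TopFeatures_info_[NameOfModel].csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for out, df in bundle.attributions.items():
        if problem_type == "classification":
            path = out_dir / f"shapley_values_all_{_safe(model_name)}_{_safe(out)}.csv"
        else:
            path = out_dir / f"shapley_values_all_{_safe(model_name)}.csv"
        df.to_csv(path)
        written.append(path)
    if bundle.permutation_importance is not None:
        path = out_dir / f"permutimp_TopFeatures_info_{_safe(model_name)}.csv"
        bundle.permutation_importance.to_csv(path, index=False)
        written.append(path)
    ranking = bundle.global_ranking()
    path = out_dir / f"shapley_global_ranking_{_safe(model_name)}.csv"
    ranking.to_csv(path, index=False)
    written.append(path)
    return written
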
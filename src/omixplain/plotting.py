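"""The configurable plot suite, rendered from a completed run.

Every plot writes one image (PNG) and a companion CSV holding the exact
numbers drawn, so tests and downstream analyses assert data rather than
pixels.  An empty plot list is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from sklearn.metrics import confusion_matrix, roc_curve, auc
from sklearn.preprocessing import label_binarize

from .io_tabular import TableError

CLASSIFICATION_ONLY = {"confusion", "roc"}
REGRESSION_ONLY = {"correlation", "joint"}

PLOT_NAMES = (
    "cv_box",
    "test_bar",
    "confusion",
    "roc",
    "feature_selection_curve",
    "correlation",
    "joint",
    "shap_bar",
    "shap_dot",
    "permutation_bar",
)


@dataclass
class PlotContext:
    """Everything the plot suite may need from a run."""

    problem_type: str
    scoring: str
    results: pd.DataFrame  # long results table
    cv_scores: dict[str, list[float]]  # model → per-fold scores
    best_model_name: str
    predictions: dict[str, dict] | None = None  # partition → y_true/y_pred/y_proba
    classes: list[str] | None = None
    selection_curve: pd.DataFrame | None = None  # k, score
    shap_ranking: pd.DataFrame | None = None
    shap_dot_data: pd.DataFrame | None = None  # feature, value, attribution, output
    permutation_importance: pd.DataFrame | None = None


def _finish(fig, data: pd.DataFrame, out_dir: Path, stem: str) -> list[Path]:
    png = out_dir / f"{stem}.png"
    csv = out_dir / f"{stem}.csv"
    fig.savefig(png, dpi=110, bbox_inches="tight")
    plt.close(fig)
    data.to_csv(csv, index=False)
    return [png, csv]


def _plot_cv_box(ctx: PlotContext, out_dir: Path) -> list[Path]:
    rows = [
        {"model": m, "fold": i, "score": s}
        for m, scores in ctx.cv_scores.items()
        for i, s in enumerate(scores)
    ]
    data = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=(6, 4))
    sns.boxplot(data=data, x="model", y="score", ax=ax)
    ax.set_ylabel(f"CV {ctx.scoring}")
    return _finish(fig, data, out_dir, "cv_box")


def _plot_test_bar(ctx: PlotContext, out_dir: Path) -> list[Path]:
    data = ctx.results.query("metric == @ctx.scoring")[["model", "test"]]
    fig, ax = plt.subplots(figsize=(6, 4))
    sns.barplot(data=data, x="model", y="test", ax=ax)
    ax.set_ylabel(f"test {ctx.scoring}")
    return _finish(fig, data, out_dir, "test_bar")


def _best_test_predictions(ctx: PlotContext) -> dict:
    if not ctx.predictions or "test" not in ctx.predictions:
        raise TableError("plot needs cached test predictions of the best model")
    return ctx.predictions["test"]


def _plot_confusion(ctx: PlotContext, out_dir: Path) -> list[Path]:
    pred = _best_test_predictions(ctx)
    cm = confusion_matrix(pred["y_true"], pred["y_pred"], labels=ctx.classes)
    data = pd.DataFrame(cm, index=ctx.classes, columns=ctx.classes)
    fig, ax = plt.subplots(figsize=(5, 4))
    sns.heatmap(data, annot=True, fmt="d", cmap="Blues", ax=ax)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"confusion matrix — {ctx.best_model_name}")
    long = data.reset_index(names="true").melt(
        id_vars="true", var_name="predicted", value_name="count"
    )
    return _finish(fig, long, out_dir, "confusion")


def _plot_roc(ctx: PlotContext, out_dir: Path) -> list[Path]:
    pred = _best_test_predictions(ctx)
    proba = pred.get("y_proba")
    if proba is None:
        raise TableError("ROC needs class probability scores")
    y_bin = label_binarize(pred["y_true"], classes=ctx.classes)
    if y_bin.shape[1] == 1:  # binary: binarize yields one column
        y_bin = np.hstack([1 - y_bin, y_bin])
    rows = []
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, cls in enumerate(ctx.classes):
        fpr, tpr, _ = roc_curve(y_bin[:, i], proba[:, i])
        ax.plot(fpr, tpr, label=f"{cls} (AUC {auc(fpr, tpr):.2f})")
        rows.extend(
            {"class": cls, "fpr": f, "tpr": t} for f, t in zip(fpr, tpr)
        )
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return _finish(fig, pd.DataFrame(rows), out_dir, "roc")


def _plot_selection_curve(ctx: PlotContext, out_dir: Path) -> list[Path]:
    if ctx.selection_curve is None:
        raise TableError("no feature-selection curve in this run")
    data = ctx.selection_curve
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(data["k"], data["score"], marker="o")
    ax.set_xscale("log")
    ax.set_xlabel("number of selected features (k)")
    ax.set_ylabel("CV score")
    return _finish(fig, data, out_dir, "feature_selection_curve")


def _plot_regression_scatter(
    ctx: PlotContext, out_dir: Path, stem: str, joint: bool
) -> list[Path]:
    pred = _best_test_predictions(ctx)
    data = pd.DataFrame(
        {"true": np.asarray(pred["y_true"], dtype=float),
         "predicted": np.asarray(pred["y_pred"], dtype=float)}
    )
    if joint:
        grid = sns.jointplot(data=data, x="true", y="predicted", height=4.5)
        lims = [data.min().min(), data.max().max()]
        grid.ax_joint.plot(lims, lims, "k:", lw=0.8)
        fig = grid.figure
    else:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(data["true"], data["predicted"], s=12)
        lims = [data.min().min(), data.max().max()]
        ax.plot(lims, lims, "k:", lw=0.8)
        ax.set_xlabel("true")
        ax.set_ylabel("predicted")
    return _finish(fig, data, out_dir, stem)


def _plot_shap_bar(ctx: PlotContext, out_dir: Path) -> list[Path]:
    if ctx.shap_ranking is None:
        raise TableError("no Shapley ranking in this run")
    data = ctx.shap_ranking
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(data) + 1.5))
    ax.barh(data["feature"][::-1], data["mean_abs_attribution"][::-1])
    ax.set_xlabel("mean |attribution|")
    return _finish(fig, data, out_dir, "shap_bar")


def _plot_shap_dot(ctx: PlotContext, out_dir: Path) -> list[Path]:
    if ctx.shap_dot_data is None:
        raise TableError("no Shapley dot data in this run")
    data = ctx.shap_dot_data
    fig, ax = plt.subplots(figsize=(6, 4))
    top = data["feature"].unique()[:15]
    sub = data[data["feature"].isin(top)]
    sns.stripplot(
        data=sub, x="attribution", y="feature", hue="value",
        size=3, ax=ax, legend=False, palette="coolwarm",
    )
    ax.axvline(0, color="k", lw=0.6)
    return _finish(fig, data, out_dir, "shap_dot")


def _plot_permutation_bar(ctx: PlotContext, out_dir: Path) -> list[Path]:
    if ctx.permutation_importance is None:
        raise TableError("no permutation importances in this run")
    data = ctx.permutation_importance.head(15)
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(data) + 1.5))
    ax.barh(
        data["feature"][::-1],
        data["importance_mean"][::-1],
        xerr=data["importance_sd"][::-1],
    )
    ax.set_xlabel("permutation importance (score drop)")
    return _finish(fig, data, out_dir, "permutation_bar")


_RENDERERS = {
    "cv_box": _plot_cv_box,
    "test_bar": _plot_test_bar,
    "confusion": _plot_confusion,
    "roc": _plot_roc,
    "feature_selection_curve": _plot_selection_curve,
    "correlation": lambda c, d: _plot_regression_scatter(c, d, "correlation", False),
    "joint": lambda c, d: _plot_regression_scatter(c, d, "joint", True),
    "shap_bar": _plot_shap_bar,
    "shap_dot": _plot_shap_dot,
    "permutation_bar": _plot_permutation_bar,
}


def validate_plot_names(plot_names: list[str], problem_type: str) -> None:
    for name in plot_names:
        if name not in _RENDERERS:
            raise TableError(
                f"unknown plot {name!r}; available: {sorted(_RENDERERS)}"
            )
        if problem_type == "regression" and name in CLASSIFICATION_ONLY:
            raise TableError(f"plot {name!r} needs a classification run")
        if problem_type == "classification" and name in REGRESSION_ONLY:
            raise TableError(f"plot {name!r} needs a regression run")


def render(plot_names: list[str], ctx: PlotContext, out_dir: str | Path) -> list[Path]:
    """Render each requested plot; returns the files written (PNG + CSV each)."""
    validate_plot_names(plot_names, ctx.problem_type)
    if not plot_names:
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in plot_names:
        written.extend(_RENDERERS[name](ctx, out_dir))
    return written
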
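"""Run orchestration: training, plotting, holdout, and prediction modes.

Training executes the fixed stage order

    load → omic pre-process → split → standardize → feature-select →
    balance → tune/evaluate → select best → plot → explain

and persists a versioned run bundle (fitted quantile map, selected feature
list, fitted models, results table, prediction caches) from which the
other three modes replay.  Standardization and balancing are fit on and
applied to the training partition only; no statistic of the test partition
influences any fitted transform.

Holdout and prediction modes re-apply only the per-dataset, stateless
normalizations (taxonomy collapse, read renormalization, TMM conversion of
raw counts) to the incoming table — never the sample-removal filters —
then align its columns to the training feature set and push it through the
persisted quantile map and feature selection.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import balancing, explain, feature_select, model_select, plotting, preprocess
from .config import RunConfig
from .io_tabular import (
    FeatureTable,
    TableError,
    TargetVector,
    align,
    read_feature_table,
    read_metadata,
    target_from_metadata,
)
from .metrics import metric_info, metric_panel
from .models import REGISTRY, REGISTRY_ORDER, ModelResult, evaluate_on_split, tune_and_fit
from .split_transform import (
    QuantileMap,
    SplitDataset,
    apply_quantile_map,
    fit_quantile_map,
    split_train_test,
)

logger = logging.getLogger(__name__)

BUNDLE_VERSION = 1


# ---------------------------------------------------------------------------
# Pre-processing dispatch
# ---------------------------------------------------------------------------

def preprocess_table(
    config: RunConfig,
    table: FeatureTable,
    target: TargetVector,
    metadata: pd.DataFrame,
) -> tuple[FeatureTable, TargetVector, list[dict]]:
    """Data-type-specific filters and normalization, in the fixed order."""
    reports: list[dict] = []

    def note(report):
        reports.append(report.to_dict())

    if config.data_type in ("gene_expression", "tabular", "metabolomic"):
        if config.filter_sample_sd is not None:
            table, rep = preprocess.filter_samples_by_sd(table, config.filter_sample_sd)
            note(rep)
        if config.filter_feature_min is not None:
            x, y = config.filter_feature_min
            table, rep = preprocess.filter_features_by_min_value(table, x, int(y))
            note(rep)
        if config.data_type == "gene_expression" and config.expression_type == "COUNTS":
            table, rep = preprocess.tmm_normalize(table)
            note(rep)
    elif config.data_type == "microbiome":
        if config.collapse_tax is not None:
            table = preprocess.collapse_taxonomy(table, config.collapse_tax)
        table, rep = preprocess.filter_min_reads(table, config.min_reads)
        note(rep)
        if config.norm_reads:
            table = preprocess.normalize_reads(table, config.norm_reads)
        table, rep = preprocess.filter_abundance(table, config.filter_abundance)
        note(rep)
        table, rep = preprocess.filter_prevalence(table, config.filter_prevalence)
        note(rep)
        table, rep = preprocess.filter_samples_by_metadata(
            table, metadata, config.filter_microbiome_samples
        )
        note(rep)

    if config.problem_type == "classification":
        if config.remove_classes:
            target, removed = preprocess.remove_classes(target, config.remove_classes)
            logger.info("remove_classes: dropped %d samples", len(removed))
        if config.merge_classes:
            target = preprocess.merge_classes(target, config.merge_classes)

    table, target = align(table, target)
    return table, target, reports


def stateless_preprocess(config: RunConfig, table: FeatureTable) -> FeatureTable:
    """The per-dataset normalizations reapplied in holdout/prediction modes."""
    if config.data_type == "gene_expression" and config.expression_type == "COUNTS":
        table, _ = preprocess.tmm_normalize(table)
    elif config.data_type == "microbiome":
        if config.collapse_tax is not None:
            table = preprocess.collapse_taxonomy(table, config.collapse_tax)
        if config.norm_reads:
            table = preprocess.normalize_reads(table, config.norm_reads)
    return table


# ---------------------------------------------------------------------------
# The run bundle
# ---------------------------------------------------------------------------

@dataclass
class RunBundle:
    """Everything a completed training run persists for the replay modes."""

    config: RunConfig
    quantile_map: QuantileMap
    selected_features: list[str]
    results: pd.DataFrame
    model_results: dict[str, ModelResult]
    best_model_name: str
    classes: list[str] | None
    plot_context: plotting.PlotContext
    tie_note: str | None = None
    selection_curve: feature_select.SelectionCurve | None = None
    preprocess_reports: list[dict] = field(default_factory=list)

    @property
    def best_result(self) -> ModelResult:
        return self.model_results[self.best_model_name]

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg = self.config.model_dump()
        manifest = {
            "bundle_version": BUNDLE_VERSION,
            "config": cfg,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "seed": self.config.seed,
            "versions": _library_versions(),
            "classes": self.classes,
            "best_model": self.best_model_name,
            "selected_features": self.selected_features,
            "n_preprocessed_features": len(self.quantile_map.feature_ids),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out_dir / "preprocess_report.json").write_text(
            json.dumps(self.preprocess_reports, indent=2)
        )
        joblib.dump(self.quantile_map.to_dict(), out_dir / "quantile_map.joblib")
        self.results.to_csv(out_dir / "results.csv", index=False)
        models_dir = out_dir / "models"
        models_dir.mkdir(exist_ok=True)
        for name, res in self.model_results.items():
            joblib.dump(res, models_dir / f"{name}.joblib")
        joblib.dump(self.plot_context, out_dir / "plot_context.joblib")
        if self.selection_curve is not None:
            self.selection_curve.to_frame().to_csv(
                out_dir / "feature_selection_curve.csv", index=False
            )
        best_dir = out_dir / "best_model"
        best_dir.mkdir(exist_ok=True)
        (best_dir / "model_name.txt").write_text(self.best_model_name + "\n")
        joblib.dump(self.best_result, best_dir / "model.joblib")
        if self.tie_note:
            (out_dir / "best_model_tie_note.txt").write_text(self.tie_note + "\n")
        return out_dir

    @classmethod
    def load(cls, run_dir: str | Path) -> "RunBundle":
        run_dir = Path(run_dir)
        manifest_path = run_dir / "manifest.json"
        if not manifest_path.exists():
            raise TableError(
                f"no training bundle at {run_dir} (manifest.json missing); "
                "run training mode first"
            )
        manifest = json.loads(manifest_path.read_text())
        config = RunConfig(**manifest["config"])
        qmap = QuantileMap.from_dict(joblib.load(run_dir / "quantile_map.joblib"))
        results = pd.read_csv(run_dir / "results.csv")
        model_results = {
            p.stem: joblib.load(p) for p in sorted((run_dir / "models").glob("*.joblib"))
        }
        curve = None
        ctx = joblib.load(run_dir / "plot_context.joblib")
        tie_path = run_dir / "best_model_tie_note.txt"
        return cls(
            config=config,
            quantile_map=qmap,
            selected_features=list(manifest["selected_features"]),
            results=results,
            model_results=model_results,
            best_model_name=manifest["best_model"],
            classes=manifest["classes"],
            plot_context=ctx,
            tie_note=tie_path.read_text().strip() if tie_path.exists() else None,
            selection_curve=curve,
        )


def _library_versions() -> dict[str, str]:
    import sklearn

    versions = {"numpy": np.__version__, "pandas": pd.__version__, "sklearn": sklearn.__version__}
    try:
        import xgboost

        versions["xgboost"] = xgboost.__version__
    except ImportError:  # pragma: no cover
        pass
    try:
        import lightgbm

        versions["lightgbm"] = lightgbm.__version__
    except ImportError:  # pragma: no cover
        pass
    return versions


# ---------------------------------------------------------------------------
# Training mode
# ---------------------------------------------------------------------------

def _ordered_models(names: list[str]) -> list[str]:
    """Configured models in fixed registry order (deterministic tie-breaks)."""
    unknown = [n for n in names if n not in REGISTRY]
    if unknown:
        raise TableError(f"unknown models {unknown}; available: {sorted(REGISTRY)}")
    return [n for n in REGISTRY_ORDER if n in names]


def run_training(
    config: RunConfig,
    out_dir: str | Path,
    table: FeatureTable | None = None,
    target: TargetVector | None = None,
    metadata: pd.DataFrame | None = None,
) -> RunBundle:
    """Execute the full training pipeline and persist the run bundle.

    ``table``/``target`` may be passed directly (already loaded) or are read
    from the configured paths.
    """
    out_dir = Path(out_dir)
    if table is None:
        table = read_feature_table(config.data_path)
    if metadata is None:
        metadata = read_metadata(config.metadata_path)
    if target is None:
        target = target_from_metadata(metadata, config.target_column, config.target_kind())
    table, target = align(table, target)

    table, target, reports = preprocess_table(config, table, target, metadata)
    split = split_train_test(table, target, config.test_size, config.seed)

    qmap = fit_quantile_map(split.X_train)
    X_train = apply_quantile_map(qmap, split.X_train)
    X_test = apply_quantile_map(qmap, split.X_test)

    curve = None
    if config.feature_selection is not None:
        fs = config.feature_selection
        X_train, _removed = feature_select.variance_filter(
            X_train, fs.variance_threshold
        )
        scoring = config.effective_scoring()
        if fs.k == "auto":
            auto_max = min(fs.auto_max, X_train.shape[1])
            k, curve = feature_select.auto_select_k(
                X_train, split.y_train, fs.auto_min, auto_max, scoring, config.seed
            )
        else:
            k = fs.k
        if k is not None:
            if k > X_train.shape[1]:
                raise TableError(
                    f"k={k} exceeds the {X_train.shape[1]} remaining features"
                )
            selected = feature_select.select_k_best(X_train, split.y_train, k)
            X_train = X_train.subset_features(selected)
        X_test = X_test.subset_features(X_train.feature_ids)
    selected_features = X_train.feature_ids

    y_train = split.y_train
    if config.problem_type == "classification" and config.balancing != "none":
        X_train, y_train = balancing.rebalance(
            X_train, y_train, config.balancing, config.seed
        )

    scoring = config.effective_scoring()
    panel = metric_panel(config.problem_type)
    if scoring not in panel:
        panel = panel + [scoring]
    eval_split = SplitDataset(
        X_train=X_train,
        X_test=X_test,
        y_train=y_train,
        y_test=split.y_test,
        seed=config.seed,
        test_size=config.test_size,
    )

    model_results: dict[str, ModelResult] = {}
    for name in _ordered_models(config.models):
        logger.info("training %s (%s search)", name, config.hyper_tuning)
        res = tune_and_fit(
            name,
            X_train.values,
            y_train.values,
            config.problem_type,
            search=config.hyper_tuning,
            scoring=scoring,
            seed=config.seed,
            target=y_train,
        )
        model_results[name] = evaluate_on_split(res, eval_split, panel, config.problem_type)

    results = results_table(model_results, panel)
    winner, tie_note = _select(model_results, scoring)

    classes = target.classes() if config.problem_type == "classification" else None
    best = model_results[winner]

    explain_parts = {"train": X_train, "test": X_test}
    on = config.explanations.on
    frames = (
        [explain_parts["train"].data, explain_parts["test"].data]
        if on == "both"
        else [explain_parts[on].data]
    )
    X_explain = pd.concat(frames)
    bundle_expl = explain.shapley_explanations(
        best.model,
        X_explain,
        config.problem_type,
        class_names=classes,
        background=X_train.values,
        top_n=config.explanations.top_n,
        seed=config.seed,
    )
    eval_part = "test" if on in ("test", "both") else "train"
    eval_X = explain_parts[eval_part]
    eval_y = (split.y_test if eval_part == "test" else y_train).values
    bundle_expl.permutation_importance = explain.permutation_importance_table(
        best.model, eval_X.data, eval_y, scoring,
        target=y_train, repeats=5, seed=config.seed,
    )

    ctx = plotting.PlotContext(
        problem_type=config.problem_type,
        scoring=scoring,
        results=results,
        cv_scores={n: r.cv_scores for n, r in model_results.items()},
        best_model_name=winner,
        predictions=best.predictions,
        classes=classes,
        selection_curve=curve.to_frame() if curve is not None else None,
        shap_ranking=bundle_expl.global_ranking(),
        shap_dot_data=_dot_data(bundle_expl, X_explain),
        permutation_importance=bundle_expl.permutation_importance,
    )

    bundle = RunBundle(
        config=config,
        quantile_map=qmap,
        selected_features=selected_features,
        results=results,
        model_results=model_results,
        best_model_name=winner,
        classes=classes,
        plot_context=ctx,
        tie_note=tie_note,
        selection_curve=curve,
        preprocess_reports=reports,
    )
    bundle.save(out_dir)
    explain.export_explanations(
        bundle_expl, winner, out_dir / "explanations", config.problem_type
    )
    plotting.render(config.plots, ctx, out_dir / "plots")
    return bundle


def _select(
    model_results: dict[str, ModelResult], scoring: str
) -> tuple[str, str | None]:
    info = metric_info(scoring)
    points = [
        model_select.PerformancePoint(
            name=name,
            train=res.train_metrics[scoring],
            test=res.test_metrics[scoring],
            orientation=info.kind,
        )
        for name, res in model_results.items()
    ]
    winner, note = model_select.select_best(points)
    return winner.name, note


def results_table(
    model_results: dict[str, ModelResult], panel: list[str]
) -> pd.DataFrame:
    """Long results table: model, metric, train, cv_mean, cv_sd, test."""
    rows = []
    for name, res in model_results.items():
        cv = np.asarray(res.cv_scores, dtype=float)
        for metric in panel:
            rows.append(
                {
                    "model": name,
                    "metric": metric,
                    "train": res.train_metrics.get(metric, float("nan")),
                    "cv_mean": cv.mean() if metric == res.scoring else float("nan"),
                    "cv_sd": cv.std() if metric == res.scoring else float("nan"),
                    "test": res.test_metrics.get(metric, float("nan")),
                }
            )
    return pd.DataFrame(rows)


def _dot_data(bundle_expl: explain.ExplanationBundle, X_explain: pd.DataFrame) -> pd.DataFrame:
    rows = []
    top = bundle_expl.global_ranking()["feature"].tolist()
    for out, df in bundle_expl.attributions.items():
        for feat in top:
            rows.append(
                pd.DataFrame(
                    {
                        "output": out,
                        "feature": feat,
                        "value": X_explain[feat].to_numpy(),
                        "attribution": df[feat].to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# Replay modes
# ---------------------------------------------------------------------------

def transform_new_table(bundle: RunBundle, table: FeatureTable) -> FeatureTable:
    """Stateless preprocessing + persisted transforms for new data."""
    table = stateless_preprocess(bundle.config, table)
    transformed = apply_quantile_map(bundle.quantile_map, table)
    return transformed.subset_features(bundle.selected_features)


def run_prediction(
    bundle_dir: str | Path,
    data_path: str | Path,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Apply the persisted best model to unlabeled data; write predictions + explanations."""
    bundle = RunBundle.load(bundle_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(data_path)
    X = transform_new_table(bundle, table)
    best = bundle.best_result
    preds = best.model.predict(X.values)
    frame = pd.DataFrame({"sample": X.sample_ids, "prediction": preds})
    if bundle.config.problem_type == "classification" and hasattr(
        best.model, "predict_proba"
    ):
        proba = best.model.predict_proba(X.values)
        for i, cls in enumerate(bundle.classes):
            frame[f"proba_{cls}"] = proba[:, i]
    frame.to_csv(out_dir / "predictions.csv", index=False)

    expl = explain.shapley_explanations(
        best.model,
        X.data,
        bundle.config.problem_type,
        class_names=bundle.classes,
        background=X.values,
        top_n=bundle.config.explanations.top_n,
        seed=bundle.config.seed,
    )
    explain.export_explanations(
        expl, bundle.best_model_name, out_dir / "explanations",
        bundle.config.problem_type,
    )
    return frame


def run_holdout(
    bundle_dir: str | Path,
    data_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Evaluate all persisted models on a new labeled dataset."""
    bundle = RunBundle.load(bundle_dir)
    config = bundle.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(data_path)
    metadata = read_metadata(metadata_path)
    target = target_from_metadata(metadata, config.target_column, config.target_kind())
    table, target = align(table, target)
    X = transform_new_table(bundle, table)
    X, target = align(X, target)

    panel = metric_panel(config.problem_type)
    scoring = config.effective_scoring()
    if scoring not in panel:
        panel = panel + [scoring]
    rows = []
    from .metrics import compute_metric

    for name, res in bundle.model_results.items():
        pred = res.model.predict(X.values)
        proba = None
        if config.problem_type == "classification" and hasattr(res.model, "predict_proba"):
            proba = res.model.predict_proba(X.values)
        for metric in panel:
            try:
                value = compute_metric(
                    metric, target.values, y_pred=pred, y_proba=proba,
                    classes=bundle.classes,
                )
            except ValueError:
                value = float("nan")
            rows.append({"model": name, "metric": metric, "holdout": value})
    frame = pd.DataFrame(rows)
    frame.to_csv(out_dir / "holdout_results.csv", index=False)
    return frame


def run_plotting(
    bundle_dir: str | Path,
    plot_names: list[str] | None,
    out_dir: str | Path,
) -> list[Path]:
    """Regenerate figures from a persisted run bundle."""
    bundle = RunBundle.load(bundle_dir)
    names = plot_names if plot_names is not None else bundle.config.plots
    return plotting.render(names, bundle.plot_context, Path(out_dir))
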
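"""Shared fixtures: small synthetic datasets and a reusable training run."""

from __future__ import annotations

import pandas as pd
import pytest

from omixplain.config import parse_config_dict
from omixplain.pipeline import run_training
from omixplain.synthetic import make_classification_table, make_regression_table


@pytest.fixture(scope="session")
def class_data():
    """Small separable classification table (80 samples × 30 features, 5 planted)."""
    return make_classification_table(
        n=80, p=30, n_informative=5, effect=2.0, family="gaussian", seed=11
    )


@pytest.fixture(scope="session")
def regress_data():
    """Small linear-regression table (100 × 40, 6 planted)."""
    return make_regression_table(
        n=100, p=40, n_informative=6, coef_scale=1.0, noise_sd=0.5,
        family="gaussian", seed=12,
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, class_data):
    """A completed small training run shared by pipeline/plotting tests."""
    tmp = tmp_path_factory.mktemp("small_run")
    table, target, truth = class_data
    data_path = tmp / "data.csv"
    meta_path = tmp / "meta.csv"
    table.data.to_csv(data_path)
    pd.DataFrame({"label": target.series}).to_csv(meta_path)
    config, _ = parse_config_dict(
        {
            "data_path": str(data_path),
            "metadata_path": str(meta_path),
            "target_column": "label",
            "problem_type": "classification",
            "models": ["rf", "knn"],
            "hyper_tuning": "none",
            "scoring": "f1",
            "seed": 7,
            "feature_selection": {"k": 10},
            "plots": ["cv_box", "test_bar", "confusion", "roc"],
        }
    )
    bundle = run_training(config, tmp / "run")
    return {
        "tmp": tmp,
        "run_dir": tmp / "run",
        "data_path": data_path,
        "meta_path": meta_path,
        "config": config,
        "bundle": bundle,
        "table": table,
        "target": target,
        "truth": truth,
    }
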
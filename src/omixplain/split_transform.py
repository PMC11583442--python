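"""Train/test partitioning and per-feature quantile standardization.

The quantile map sends each feature through its training-set empirical CDF
to a uniform [0, 1] scale — robust to the heavy skew typical of count-like
omics features.  It is fitted on the training partition only and applied
unchanged to the test partition (and later to holdout/prediction data), so
no statistic of the test rows ever leaks into a fitted transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .io_tabular import FeatureTable, TableError, TargetVector


@dataclass
class SplitDataset:
    X_train: FeatureTable
    X_test: FeatureTable
    y_train: TargetVector
    y_test: TargetVector
    seed: int
    test_size: float


def split_train_test(
    table: FeatureTable,
    target: TargetVector,
    test_size: float = 0.2,
    seed: int = 42,
) -> SplitDataset:
    """Deterministic train/test split; stratified by class for classification."""
    if table.shape[0] < 5:
        raise TableError("need at least 5 samples to split")
    if table.sample_ids != target.sample_ids:
        raise TableError("table and target must be aligned before splitting")
    stratify = None
    if target.kind == "class":
        counts = target.series.value_counts()
        singletons = counts[counts < 2].index.tolist()
        if singletons:
            raise TableError(
                f"classes with a single member cannot be stratified: {singletons}"
            )
        stratify = target.values
    train_ids, test_ids = train_test_split(
        table.sample_ids,
        test_size=test_size,
        random_state=seed,
        stratify=stratify,
    )
    return SplitDataset(
        X_train=table.subset_samples(train_ids),
        X_test=table.subset_samples(test_ids),
        y_train=target.subset(train_ids),
        y_test=target.subset(test_ids),
        seed=seed,
        test_size=test_size,
    )


@dataclass
class QuantileMap:
    """Per-feature empirical quantile grid mapping values to uniform [0, 1].

    ``quantiles`` has shape (n_grid, n_features): column ``j`` holds the
    training quantiles of feature ``j`` at ``references`` (evenly spaced
    probability levels).  Grids are non-decreasing by construction.
    """

    feature_ids: list[str]
    quantiles: np.ndarray
    references: np.ndarray

    def to_dict(self) -> dict:
        return {
            "feature_ids": self.feature_ids,
            "quantiles": self.quantiles,
            "references": self.references,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuantileMap":
        return cls(
            feature_ids=list(d["feature_ids"]),
            quantiles=np.asarray(d["quantiles"], dtype=float),
            references=np.asarray(d["references"], dtype=float),
        )


def fit_quantile_map(train: FeatureTable, max_grid: int = 1000) -> QuantileMap:
    """Fit the per-feature quantile grid on training rows only.

    The grid holds q = min(1000, n_train) empirical quantiles at evenly
    spaced probability levels in [0, 1].
    """
    n = train.shape[0]
    if n < 2:
        raise TableError("need at least 2 training rows to fit quantiles")
    q = min(max_grid, n)
    references = np.linspace(0.0, 1.0, q)
    quantiles = np.quantile(train.values, references, axis=0)
    return QuantileMap(
        feature_ids=train.feature_ids,
        quantiles=quantiles,
        references=references,
    )


def _transform_column(x: np.ndarray, grid: np.ndarray, refs: np.ndarray) -> np.ndarray:
    lo, hi = grid[0], grid[-1]
    if lo == hi:
        # constant training feature: no order information, map everything to 0
        return np.zeros_like(x, dtype=float)
    # tied training values share interpolated ranks (midpoint of the lower
    # and upper empirical CDFs)
    forward = np.interp(x, grid, refs)
    backward = np.interp(-x, -grid[::-1], -refs[::-1])
    out = 0.5 * (forward - backward)
    out[x <= lo] = 0.0
    out[x >= hi] = 1.0
    return out


def apply_quantile_map(qmap: QuantileMap, table: FeatureTable) -> FeatureTable:
    """Map each value through the training empirical CDF; clip outside [min, max]."""
    missing = [f for f in qmap.feature_ids if f not in set(table.feature_ids)]
    if missing:
        raise TableError(f"features absent from table: {missing[:5]}")
    sub = table.subset_features(qmap.feature_ids)
    values = sub.values
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        out[:, j] = _transform_column(
            values[:, j], qmap.quantiles[:, j], qmap.references
        )
    return FeatureTable(
        pd.DataFrame(out, index=sub.sample_ids, columns=qmap.feature_ids)
    )
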
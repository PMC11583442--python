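"""Optional class rebalancing of the training partition (classification only).

Random resampling without interpolation: oversampling draws minority-class
rows with replacement until every class matches the majority count;
undersampling subsamples majority classes without replacement down to the
minority count.  Duplicated rows are exact copies.  The test partition is
never touched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_tabular import FeatureTable, TableError, TargetVector

STRATEGIES = ("none", "oversample", "undersample")


def rebalance(
    X_train: FeatureTable,
    y_train: TargetVector,
    strategy: str,
    seed: int,
) -> tuple[FeatureTable, TargetVector]:
    if strategy not in STRATEGIES:
        raise TableError(f"unknown balancing strategy {strategy!r}")
    if strategy == "none":
        return X_train, y_train
    if y_train.kind != "class":
        raise TableError("class balancing applies to classification targets only")

    rng = np.random.default_rng(seed)
    counts = y_train.series.value_counts()
    chosen: list[str] = []
    if strategy == "oversample":
        top = counts.max()
        for label in counts.index:
            ids = y_train.series.index[y_train.series == label].tolist()
            chosen.extend(ids)
            extra = top - len(ids)
            if extra:
                chosen.extend(rng.choice(ids, size=extra, replace=True).tolist())
    else:  # undersample
        floor = counts.min()
        for label in counts.index:
            ids = y_train.series.index[y_train.series == label].tolist()
            if len(ids) > floor:
                ids = rng.choice(ids, size=floor, replace=False).tolist()
            chosen.extend(ids)

    # duplicated IDs get a suffix so the resampled table keeps unique rows
    data = X_train.data.loc[chosen]
    labels = y_train.series.loc[chosen]
    new_ids, seen = [], {}
    for s in chosen:
        n = seen.get(s, 0)
        new_ids.append(s if n == 0 else f"{s}__dup{n}")
        seen[s] = n + 1
    data = data.copy()
    data.index = new_ids
    labels = labels.copy()
    labels.index = new_ids
    return FeatureTable(data), TargetVector(labels, "class")
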
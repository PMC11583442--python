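"""Data-type-specific filtering and normalization applied before splitting.

Gene-expression tables given as raw counts are converted to TMM-normalized
counts-per-million.  Microbiome tables get taxonomy collapsing, read-depth
filtering/renormalization and abundance/prevalence filters.  Tabular and
metabolomic tables share the sparse-sample and minimum-value filters with
gene expression.  Every filter records what it removed in a
:class:`PreprocessReport`, emitted even when nothing is removed.

Boundary conventions follow the wording of the filters: "fewer than" /
"less than" remove strictly below the threshold; "more than X standard
deviations" removes strictly beyond.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_tabular import FeatureTable, TableError, TargetVector

logger = logging.getLogger(__name__)

TAXONOMY_RANKS = ("k", "p", "c", "o", "f", "g", "s")


@dataclass
class PreprocessReport:
    """Per-rule record of removed samples/features and normalizations."""

    samples_removed: dict[str, list[str]] = field(default_factory=dict)
    features_removed: dict[str, list[str]] = field(default_factory=dict)
    normalizations: list[str] = field(default_factory=list)
    parameters: dict[str, object] = field(default_factory=dict)

    def record_samples(self, rule: str, removed: list[str], retained: int) -> None:
        self.samples_removed[rule] = list(removed)
        logger.info("%s: removed %d samples, retained %d", rule, len(removed), retained)

    def record_features(self, rule: str, removed: list[str], retained: int) -> None:
        self.features_removed[rule] = list(removed)
        logger.info("%s: removed %d features, retained %d", rule, len(removed), retained)

    def to_dict(self) -> dict:
        return {
            "samples_removed": self.samples_removed,
            "features_removed": self.features_removed,
            "normalizations": self.normalizations,
            "parameters": {k: repr(v) for k, v in self.parameters.items()},
        }


# ---------------------------------------------------------------------------
# TMM (trimmed mean of M-values) normalization
# ---------------------------------------------------------------------------

def _upper_quartile(counts: np.ndarray, libsize: np.ndarray) -> np.ndarray:
    # 75th percentile of the depth-scaled counts, per sample
    return np.array(
        [np.quantile(row / n, 0.75) for row, n in zip(counts, libsize)]
    )


def tmm_factors(
    counts: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM scaling factors for a samples × features count matrix.

    The reference sample is the one whose upper quartile of depth-scaled
    counts is closest to the mean upper quartile.  For each sample, M-values
    (log2 ratio of depth-normalized counts against the reference) are doubly
    trimmed — 30% on M, 5% on A (mean log2 abundance) — and combined by a
    precision-weighted mean; 2**that is the factor.  Factors are rescaled so
    their geometric mean is 1.  Features with a zero count in either member
    of a pair are excluded from that pair's trimmed mean.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise TableError("TMM needs a 2-D matrix with at least 2 samples")
    if (counts < 0).any():
        raise TableError("TMM requires nonnegative counts")
    libsize = counts.sum(axis=1)
    if (libsize == 0).any():
        zero = np.where(libsize == 0)[0].tolist()
        raise TableError(f"samples with zero total count: {zero}")

    uq = _upper_quartile(counts, libsize)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[0])
    y_r, n_r = counts[ref], libsize[ref]
    for s in range(counts.shape[0]):
        if s == ref:
            continue
        y_s, n_s = counts[s], libsize[s]
        keep = (y_s > 0) & (y_r > 0)
        if not keep.any():
            continue
        ys, yr = y_s[keep], y_r[keep]
        m = np.log2((ys / n_s) / (yr / n_r))
        a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
        # precision weights from the delta method on binomial counts
        w = 1.0 / ((n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr))

        n = m.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        trimmed = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not trimmed.any() or w[trimmed].sum() == 0:
            continue
        log_tmm = np.sum(w[trimmed] * m[trimmed]) / np.sum(w[trimmed])
        if np.isfinite(log_tmm):
            factors[s] = 2.0 ** log_tmm

    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def tmm_normalize(table: FeatureTable) -> tuple[FeatureTable, PreprocessReport]:
    """Convert raw counts to counts-per-million of TMM-effective library sizes."""
    counts = table.values
    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=1) * factors
    cpm = counts / eff_lib[:, None] * 1e6
    report = PreprocessReport(
        normalizations=["TMM counts-per-million"],
        parameters={"tmm_factors": dict(zip(table.sample_ids, factors))},
    )
    out = FeatureTable(
        pd.DataFrame(cpm, index=table.sample_ids, columns=table.feature_ids)
    )
    return out, report


# ---------------------------------------------------------------------------
# Sample / feature filters
# ---------------------------------------------------------------------------

def filter_samples_by_sd(
    table: FeatureTable, x_sd: float
) -> tuple[FeatureTable, PreprocessReport]:
    """Drop samples whose covered-feature count is > x_sd population SDs off the mean.

    "Covered" means value strictly greater than zero.  With zero spread
    across samples nothing is removed.
    """
    if x_sd < 0:
        raise TableError("x_sd must be nonnegative")
    coverage = (table.values > 0).sum(axis=1).astype(float)
    mean, sd = coverage.mean(), coverage.std()  # population SD
    if sd == 0:
        keep_mask = np.ones(len(coverage), dtype=bool)
    else:
        keep_mask = np.abs(coverage - mean) <= x_sd * sd
    keep = [s for s, k in zip(table.sample_ids, keep_mask) if k]
    removed = [s for s, k in zip(table.sample_ids, keep_mask) if not k]
    report = PreprocessReport(parameters={"x_sd": x_sd})
    report.record_samples("filter_samples_by_sd", removed, len(keep))
    return table.subset_samples(keep), report


def filter_features_by_min_value(
    table: FeatureTable, x: float, y: int
) -> tuple[FeatureTable, PreprocessReport]:
    """Keep features with a value strictly over ``x`` in at least ``y`` samples."""
    if y < 0:
        raise TableError("y must be nonnegative")
    if y > table.shape[0]:
        logger.warning(
            "filter_features_by_min_value: y=%d exceeds the %d samples; "
            "every feature will be removed",
            y,
            table.shape[0],
        )
    n_over = (table.values > x).sum(axis=0)
    keep = [f for f, n in zip(table.feature_ids, n_over) if n >= y]
    removed = [f for f, n in zip(table.feature_ids, n_over) if n < y]
    report = PreprocessReport(parameters={"x": x, "y": y})
    report.record_features("filter_features_by_min_value", removed, len(keep))
    return table.subset_features(keep), report


_RANK_RE = re.compile(r"\s*([kpcofgs])__")


def _truncate_lineage(lineage: str, rank: str) -> str | None:
    """QIIME-style lineage truncated at ``rank``; None when unparseable."""
    parts = [p.strip() for p in lineage.split(";")]
    upto = TAXONOMY_RANKS.index(rank)
    kept = []
    for want in TAXONOMY_RANKS[: upto + 1]:
        match = next(
            (p for p in parts if _RANK_RE.match(p) and _RANK_RE.match(p).group(1) == want),
            None,
        )
        if match is None:
            return None
        kept.append(match)
    return ";".join(kept)


def collapse_taxonomy(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum features sharing the lineage truncated at ``rank``.

    Feature IDs must carry rank-prefixed lineage strings (k__…;p__…;…).
    Unparseable lineages are pooled under an "unassigned" bucket at that
    rank.  Per-sample totals are conserved.
    """
    if rank not in TAXONOMY_RANKS:
        raise TableError(f"rank {rank!r} not in {TAXONOMY_RANKS}")
    groups: dict[str, list[str]] = {}
    for fid in table.feature_ids:
        trunc = _truncate_lineage(fid, rank)
        if trunc is None:
            trunc = f"unassigned_{rank}"
        groups.setdefault(trunc, []).append(fid)
    collapsed = pd.DataFrame(
        {new: table.data[cols].sum(axis=1) for new, cols in groups.items()},
        index=table.data.index,
    )
    return FeatureTable(collapsed)


def filter_min_reads(
    table: FeatureTable, threshold: int
) -> tuple[FeatureTable, PreprocessReport]:
    """Remove samples with fewer reads (row sum) than ``threshold``."""
    if threshold < 0:
        raise TableError("threshold must be nonnegative")
    totals = table.values.sum(axis=1)
    keep = [s for s, t in zip(table.sample_ids, totals) if t >= threshold]
    removed = [s for s, t in zip(table.sample_ids, totals) if t < threshold]
    report = PreprocessReport(parameters={"min_reads": threshold})
    report.record_samples("filter_min_reads", removed, len(keep))
    return table.subset_samples(keep), report


def normalize_reads(table: FeatureTable, total: int) -> FeatureTable:
    """Rescale every sample so its row sum equals ``total``."""
    sums = table.values.sum(axis=1)
    if (sums <= 0).any():
        zero = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise TableError(f"cannot renormalize zero-sum samples: {zero}")
    scaled = table.values * (total / sums)[:, None]
    return FeatureTable(
        pd.DataFrame(scaled, index=table.sample_ids, columns=table.feature_ids)
    )


def filter_abundance(
    table: FeatureTable, min_total: float
) -> tuple[FeatureTable, PreprocessReport]:
    """Remove features whose total across samples is less than ``min_total``."""
    totals = table.values.sum(axis=0)
    keep = [f for f, t in zip(table.feature_ids, totals) if t >= min_total]
    removed = [f for f, t in zip(table.feature_ids, totals) if t < min_total]
    report = PreprocessReport(parameters={"filter_abundance": min_total})
    report.record_features("filter_abundance", removed, len(keep))
    return table.subset_features(keep), report


def filter_prevalence(
    table: FeatureTable, min_prop: float
) -> tuple[FeatureTable, PreprocessReport]:
    """Remove features observed (value > 0) in under ``min_prop`` of samples."""
    if not 0 <= min_prop <= 1:
        raise TableError("min_prop must be a proportion in [0, 1]")
    prev = (table.values > 0).mean(axis=0)
    keep = [f for f, p in zip(table.feature_ids, prev) if p >= min_prop]
    removed = [f for f, p in zip(table.feature_ids, prev) if p < min_prop]
    report = PreprocessReport(parameters={"filter_prevalence": min_prop})
    report.record_features("filter_prevalence", removed, len(keep))
    return table.subset_features(keep), report


def filter_samples_by_metadata(
    table: FeatureTable,
    metadata: pd.DataFrame,
    rules: list[dict[str, str]] | None,
) -> tuple[FeatureTable, PreprocessReport]:
    """Remove samples matching any {column: category} rule; null rules → identity."""
    report = PreprocessReport(parameters={"rules": rules})
    if not rules:
        report.record_samples("filter_samples_by_metadata", [], table.shape[0])
        return table, report
    to_remove: set[str] = set()
    for rule in rules:
        for column, category in rule.items():
            if column not in metadata.columns:
                raise TableError(f"metadata column {column!r} not found")
            matches = metadata.index[metadata[column] == category]
            to_remove.update(str(s) for s in matches)
    keep = [s for s in table.sample_ids if s not in to_remove]
    removed = [s for s in table.sample_ids if s in to_remove]
    report.record_samples("filter_samples_by_metadata", removed, len(keep))
    return table.subset_samples(keep), report


def remove_classes(
    target: TargetVector, labels: list[str] | None
) -> tuple[TargetVector, list[str]]:
    """Drop samples carrying any of the listed class labels."""
    if not labels:
        return target, []
    mask = target.series.isin([str(l) for l in labels])
    removed = target.series.index[mask].tolist()
    remaining = target.series[~mask]
    if remaining.empty:
        raise TableError("remove_classes removed every sample")
    return TargetVector(remaining, target.kind), removed


def merge_classes(
    target: TargetVector, mapping: dict[str, list[str]] | None
) -> TargetVector:
    """Rewrite old labels to new ones: {"X": ["A", "B"]} maps A and B to X."""
    if not mapping:
        return target
    rename: dict[str, str] = {}
    for new, olds in mapping.items():
        for old in olds:
            old = str(old).strip()
            if old in rename:
                raise TableError(
                    f"label {old!r} appears in more than one merge group"
                )
            rename[old] = str(new)
    merged = target.series.map(lambda l: rename.get(l, l))
    return TargetVector(merged, target.kind)
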
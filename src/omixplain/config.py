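"""JSON run configuration: parsing, validation, defaults.

A single JSON file drives a run.  Unknown top-level keys are rejected
rather than ignored — a silently misspelled filter name must not turn a
filter off.  Every default that gets applied is returned alongside the
parsed config so the run log can state the effective settings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


class FeatureSelectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variance_threshold: float = Field(default=0.0, ge=0.0)
    k: Optional[int | Literal["auto"]] = None
    auto_min: int = Field(default=10, ge=1)
    auto_max: int = Field(default=100, ge=2)

    @model_validator(mode="after")
    def _check_auto(self):
        if self.k == "auto" and self.auto_min >= self.auto_max:
            raise ValueError("auto_min must be < auto_max when k = 'auto'")
        if isinstance(self.k, int) and self.k < 1:
            raise ValueError("k must be a positive integer or 'auto'")
        return self


class ExplanationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    top_n: int = Field(default=15, ge=1)
    on: Literal["train", "test", "both"] = "test"


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    data_path: str
    metadata_path: str
    target_column: str
    problem_type: Literal["classification", "regression"]
    data_type: Literal[
        "gene_expression", "microbiome", "metabolomic", "tabular", "none"
    ] = "none"
    expression_type: Optional[
        Literal["FPKM", "RPKM", "TMM", "TPM", "Log2FC", "COUNTS", "OTHER"]
    ] = None
    filter_sample_sd: Optional[float] = Field(default=None, ge=0.0)
    filter_feature_min: Optional[tuple[float, int]] = None
    collapse_tax: Optional[Literal["k", "p", "c", "o", "f", "g", "s"]] = None
    min_reads: int = Field(default=1000, ge=0)
    norm_reads: int = Field(default=1000, ge=0)
    filter_abundance: float = Field(default=10.0, ge=0.0)
    filter_prevalence: float = Field(default=0.01, ge=0.0, le=1.0)
    filter_microbiome_samples: Optional[list[dict[str, str]]] = None
    remove_classes: Optional[list[str]] = None
    merge_classes: Optional[dict[str, list[str]]] = None
    test_size: float = Field(default=0.2, gt=0.0, lt=1.0)
    seed: int = 42
    feature_selection: Optional[FeatureSelectionConfig] = None
    balancing: Literal["none", "oversample", "undersample"] = "none"
    models: list[str] = Field(
        default_factory=lambda: ["rf", "gradient_boosted_trees", "adaboost", "knn", "lightgbm_style"]
    )
    scoring: Optional[str] = None
    hyper_tuning: Literal["random", "grid", "none"] = "random"
    plots: list[str] = Field(default_factory=list)
    explanations: ExplanationConfig = Field(default_factory=ExplanationConfig)

    @model_validator(mode="after")
    def _cross_field(self):
        if (self.data_type == "gene_expression") != (self.expression_type is not None):
            raise ValueError(
                "expression_type must be given exactly when data_type is gene_expression"
            )
        if not self.models:
            raise ValueError("models list cannot be empty")
        return self

    def effective_scoring(self) -> str:
        if self.scoring is not None:
            return self.scoring
        return "f1" if self.problem_type == "classification" else "mae"

    def target_kind(self) -> str:
        return "class" if self.problem_type == "classification" else "numeric"


def _defaults_applied(raw: dict, config: RunConfig) -> list[str]:
    applied = []
    for name in type(config).model_fields:
        if name not in raw:
            applied.append(f"{name} = {getattr(config, name)!r}")
    return applied


def parse_config(path: str | Path) -> tuple[RunConfig, list[str]]:
    """Parse and validate the JSON config; returns (config, applied defaults)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(
            f"malformed JSON in {path} at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    return parse_config_dict(raw)


def parse_config_dict(raw: dict) -> tuple[RunConfig, list[str]]:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a JSON object")
    try:
        config = RunConfig(**raw)
    except ValidationError as exc:
        problems = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<root>"
            problems.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid configuration — " + "; ".join(problems)) from exc
    return config, _defaults_applied(raw, config)
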
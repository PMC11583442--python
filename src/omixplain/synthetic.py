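"""Seeded generators of omics-like tables with planted signal.

Four generative families emulate the input types the pipeline accepts:

* ``counts`` — negative-binomial expression counts with log-normal library
  sizes; class effects shift informative genes on the log-mean scale.
* ``abundance`` — compositional microbiome tables from a Dirichlet-
  multinomial with log-normal sequencing depths, so read-depth filtering,
  renormalization and prevalence filters have realistic work to do; class
  effects multiply informative taxa's Dirichlet weights.
* ``genotype`` — 0/1/2 allele dosages under Hardy–Weinberg sampling; class
  effects shift the alternate-allele frequency.
* ``gaussian`` — plain numeric tabular data; class effects shift means.

Every generator is a pure function of its arguments (seed included) and
returns the ground truth needed to audit downstream feature recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tabular import FeatureTable, TableError, TargetVector

FAMILIES = ("counts", "abundance", "genotype", "gaussian")


@dataclass
class SyntheticTruth:
    informative: list[str]
    effects: dict[str, float]
    family: str
    seed: int
    noise: dict[str, float] = field(default_factory=dict)
    planted_r2: float | None = None


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def _class_labels(n: int, n_classes: int) -> np.ndarray:
    # balanced assignment, deterministic order then shuffled by caller's rng
    reps = int(np.ceil(n / n_classes))
    return np.array([f"C{i}" for i in range(n_classes)] * reps)[:n]


def _base_matrix(
    rng: np.random.Generator,
    n: int,
    p: int,
    family: str,
    shifts: np.ndarray,
) -> np.ndarray:
    """Draw a table whose per-sample informative features are shifted.

    ``shifts`` has shape (n, p): per-sample additive effect on the family's
    natural parameter scale (log-mean for counts/abundance weights, logit
    allele frequency for genotypes, mean for gaussian).
    """
    if family == "gaussian":
        return rng.normal(loc=shifts, scale=1.0, size=(n, p))
    if family == "counts":
        log_mu = rng.normal(2.0, 1.0, size=p)  # gene-specific baseline
        lib = np.exp(rng.normal(0.0, 0.3, size=n))  # library-size variation
        mu = np.exp(log_mu[None, :] + shifts) * lib[:, None]
        # NB via gamma-Poisson, dispersion 0.3
        shape = 1.0 / 0.3
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam).astype(float)
    if family == "abundance":
        base_w = rng.lognormal(0.0, 1.5, size=p)
        depth = np.maximum(
            rng.lognormal(np.log(4000.0), 0.5, size=n), 300
        ).astype(int)
        out = np.empty((n, p))
        for i in range(n):
            alpha = base_w * np.exp(shifts[i]) * 0.5
            probs = rng.dirichlet(alpha)
            out[i] = rng.multinomial(depth[i], probs)
        return out
    if family == "genotype":
        base_logit = rng.uniform(-2.0, 2.0, size=p)
        probs = 1.0 / (1.0 + np.exp(-(base_logit[None, :] + shifts)))
        return rng.binomial(2, probs).astype(float)
    raise TableError(f"unknown family {family!r}; pick one of {FAMILIES}")


def make_classification_table(
    n: int,
    p: int,
    n_informative: int,
    effect: float = 2.0,
    family: str = "gaussian",
    n_classes: int = 2,
    seed: int = 0,
) -> tuple[FeatureTable, TargetVector, SyntheticTruth]:
    """Balanced-class table with ``n_informative`` planted features.

    ``effect`` is the between-class shift on the family's natural scale;
    classes are spread over [-effect/2, +effect/2] per informative feature,
    with alternating signs across features so recovery is not direction-
    biased.  Null features are exchangeable across classes.
    """
    if n_informative > p:
        raise TableError("n_informative cannot exceed p")
    rng = np.random.default_rng(seed)
    labels = _class_labels(n, n_classes)
    rng.shuffle(labels)
    class_idx = np.array([int(l[1:]) for l in labels])

    features = _ids("feat", p)
    informative = sorted(rng.choice(p, size=n_informative, replace=False))
    signs = np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)

    shifts = np.zeros((n, p))
    if n_classes > 1:
        class_pos = class_idx / (n_classes - 1) - 0.5  # in [-1/2, 1/2]
        for j, feat in enumerate(informative):
            shifts[:, feat] = effect * signs[j] * class_pos

    values = _base_matrix(rng, n, p, family, shifts)
    table = FeatureTable(
        pd.DataFrame(values, index=_ids("S", n), columns=features)
    )
    target = TargetVector(pd.Series(labels, index=_ids("S", n)), "class")
    truth = SyntheticTruth(
        informative=[features[i] for i in informative],
        effects={features[f]: float(effect * s) for f, s in zip(informative, signs)},
        family=family,
        seed=seed,
    )
    return table, target, truth


def make_regression_table(
    n: int,
    p: int,
    n_informative: int,
    coef_scale: float = 1.0,
    noise_sd: float = 0.5,
    family: str = "gaussian",
    seed: int = 0,
) -> tuple[FeatureTable, TargetVector, SyntheticTruth]:
    """Numeric target as a linear function of planted features plus noise.

    The planted R² is computable from the coefficients and noise and is
    reported in the truth record: R² = var(signal)/(var(signal)+noise_sd²).
    """
    if n_informative > p:
        raise TableError("n_informative cannot exceed p")
    rng = np.random.default_rng(seed)
    features = _ids("feat", p)
    values = _base_matrix(rng, n, p, family, np.zeros((n, p)))
    informative = sorted(rng.choice(p, size=n_informative, replace=False))
    coefs = coef_scale * rng.choice([-1.0, 1.0], size=n_informative)

    X_inf = values[:, informative]
    sd = X_inf.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X_inf - X_inf.mean(axis=0)) / sd
    signal = Z @ coefs
    y = signal + rng.normal(0.0, noise_sd, size=n)
    signal_var = float(np.var(signal))
    planted_r2 = signal_var / (signal_var + noise_sd**2) if signal_var else 0.0

    table = FeatureTable(
        pd.DataFrame(values, index=_ids("S", n), columns=features)
    )
    target = TargetVector(pd.Series(y, index=_ids("S", n)), "numeric")
    truth = SyntheticTruth(
        informative=[features[i] for i in informative],
        effects={features[f]: float(c) for f, c in zip(informative, coefs)},
        family=family,
        seed=seed,
        noise={"noise_sd": noise_sd},
        planted_r2=planted_r2,
    )
    return table, target, truth


def noise_sd_for_r2(coef_scale: float, n_informative: int, r2: float) -> float:
    """Noise level giving an expected planted R² for independent unit-variance features."""
    if not 0 < r2 < 1:
        raise TableError("r2 must be in (0, 1)")
    signal_var = coef_scale**2 * n_informative
    return float(np.sqrt(signal_var * (1.0 - r2) / r2))


def make_genotype_calls(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Categorical genotype call matrix under Hardy–Weinberg equilibrium.

    Tokens are ``hom_ref`` / ``het`` / ``hom_alt`` / ``NN`` (missing).
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=p)
    dosage = rng.binomial(2, maf[None, :], size=(n, p))
    tokens = np.array(["hom_ref", "het", "hom_alt"], dtype=object)[dosage]
    if missing_rate > 0:
        mask = rng.random((n, p)) < missing_rate
        tokens[mask] = "NN"
    return pd.DataFrame(tokens, index=_ids("S", n), columns=_ids("snp", p))
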
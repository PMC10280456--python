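"""Stage 1 and 2 of the selection pipeline.

Stage 1 is a plain variance threshold: genes whose variance falls
strictly below the threshold (default 0.05) are discarded.  On
min-max-normalized data the largest possible per-gene population
variance is 0.25 (a balanced 0/1 gene), so 0.05 is a meaningful
fraction of the attainable range.

Stage 2 fits an extremely randomized tree ensemble to the surviving
genes and keeps only genes with strictly positive impurity-decrease
importance.  Both stages record index provenance back to the input
header.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from .datatypes import EmptyStageError, ExpressionDataset, VehError

__all__ = [
    "FilterConfig",
    "ERTConfig",
    "StageResult",
    "gene_variances",
    "variance_filter",
    "ert_importances",
    "positive_importance_filter",
    "ert_filter",
]


@dataclass
class FilterConfig:
    """Variance-threshold settings (threshold 0.05, population variance).

    ``on_normalized`` controls which values the pipeline hands to this
    stage: raw (imputed) intensities by default, where 0.05 screens
    near-constant probes, or min-max-scaled values.  On [0, 1]-scaled
    data the attainable per-gene variance is at most 0.25 and shrinks
    with sample size for unimodal genes, so normalized-mode thresholds
    bite much harder.
    """

    variance_threshold: float = 0.05
    variance_kind: str = "population"
    on_normalized: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.variance_threshold) or self.variance_threshold < 0:
            raise VehError("variance threshold must be finite and nonnegative")
        if self.variance_kind not in ("population", "sample"):
            raise VehError("variance_kind must be 'population' or 'sample'")


@dataclass
class ERTConfig:
    """Extra-trees ensemble constraints: 100 trees, min leaf 20, max 10 leaves."""

    n_estimators: int = 100
    min_samples_leaf: int = 20
    max_leaf_nodes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_estimators", "min_samples_leaf", "max_leaf_nodes"):
            if getattr(self, name) <= 0:
                raise VehError(f"{name} must be positive")


@dataclass
class StageResult:
    """Outcome of one filtering stage with provenance.

    ``kept_indices`` index into the stage's *input* dataset;
    ``scores`` are the per-input-gene diagnostics (variances or
    importances) and ``dataset`` is the reduced dataset.
    """

    kept_indices: np.ndarray
    scores: np.ndarray
    dataset: ExpressionDataset


def gene_variances(ds: ExpressionDataset, kind: str = "population") -> np.ndarray:
    """Per-gene variance; ``kind`` selects the 1/n or 1/(n-1) estimator."""
    if ds.missing_mask.any():
        raise VehError("variances require a dataset with no absent entries")
    if kind == "population":
        return ds.values.var(axis=0, ddof=0)
    if kind == "sample":
        if ds.n_samples < 2:
            raise VehError("sample variance needs at least 2 samples")
        return ds.values.var(axis=0, ddof=1)
    raise VehError(f"unknown variance kind {kind!r}")


def variance_filter(ds: ExpressionDataset, cfg: FilterConfig | None = None) -> StageResult:
    """Keep genes with variance >= threshold (strictly-smaller removed)."""
    cfg = cfg or FilterConfig()
    variances = gene_variances(ds, cfg.variance_kind)
    kept = np.where(variances >= cfg.variance_threshold)[0]
    if kept.size == 0:
        raise EmptyStageError(
            "variance_filter",
            f"no gene reaches variance threshold {cfg.variance_threshold}",
        )
    return StageResult(kept, variances, ds.subset_genes(kept))


def ert_importances(ds: ExpressionDataset, cfg: ERTConfig | None = None) -> np.ndarray:
    """Impurity-decrease importances from an extra-trees ensemble.

    The ensemble honours the configured tree constraints exactly and
    the returned vector is normalized to sum 1 (Gini importance
    averaged over trees).  Deterministic given the seed.
    """
    cfg = cfg or ERTConfig()
    if len(np.unique(ds.labels)) < 2:
        raise VehError("importance scoring needs at least 2 classes")
    forest = ExtraTreesClassifier(
        n_estimators=cfg.n_estimators,
        min_samples_leaf=cfg.min_samples_leaf,
        max_leaf_nodes=cfg.max_leaf_nodes,
        random_state=cfg.seed,
    )
    forest.fit(ds.values, ds.labels)
    imp = forest.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return imp


def positive_importance_filter(scores: np.ndarray) -> np.ndarray:
    """Indices with importance strictly greater than zero, ascending.

    The gate is the literal ``> 0`` comparison with no epsilon.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)) or (scores < 0).any():
        raise VehError("importances must be finite and nonnegative")
    kept = np.where(scores > 0)[0]
    if kept.size == 0:
        raise EmptyStageError(
            "positive_importance_filter", "no gene has positive importance"
        )
    return kept


def ert_filter(ds: ExpressionDataset, cfg: ERTConfig | None = None) -> StageResult:
    """Stage 2: importance scoring plus the positive-importance gate."""
    scores = ert_importances(ds, cfg)
    kept = positive_importance_filter(scores)
    return StageResult(kept, scores, ds.subset_genes(kept))
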
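"""Shared containers for expression data and selected gene subsets.

The central object is :class:`ExpressionDataset`, an in-memory
samples x genes matrix with feature-ID provenance: every downstream
stage that drops genes carries the surviving column identifiers along,
so a final subset can always be traced back to the original header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["ExpressionDataset", "GeneSubset", "VehError", "EmptyStageError"]


class VehError(ValueError):
    """Base class for domain errors raised by this package."""


class EmptyStageError(VehError):
    """A selection stage eliminated every gene."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        detail = message or "left zero genes"
        super().__init__(f"stage '{stage}': {detail}")


@dataclass
class ExpressionDataset:
    """A labeled samples x genes expression matrix.

    Parameters
    ----------
    values
        Real expression intensities, shape ``(n_samples, n_genes)``.
    feature_ids
        Ordered, unique probe/feature identifiers, one per column.
    labels
        Per-sample class identifiers (any hashable scalars; stored as a
        numpy array).
    name
        Free-form dataset tag used in reports.
    missing_mask
        Boolean matrix marking absent entries.  All-false after
        imputation.
    """

    values: np.ndarray
    feature_ids: list[str]
    labels: np.ndarray
    name: str = "dataset"
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise VehError("values must be a 2-D samples x genes matrix")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.labels = np.asarray(self.labels)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, d = self.values.shape
        if len(self.labels) != n:
            raise VehError(
                f"label count {len(self.labels)} != sample count {n}"
            )
        if len(self.feature_ids) != d:
            raise VehError(
                f"feature id count {len(self.feature_ids)} != gene count {d}"
            )
        if len(set(self.feature_ids)) != d:
            dupes = sorted(
                {f for f in self.feature_ids if self.feature_ids.count(f) > 1}
            )
            raise VehError(f"duplicate feature ids: {dupes[:5]}")
        if self.missing_mask.shape != self.values.shape:
            raise VehError("missing_mask shape must match values shape")
        if len(np.unique(self.labels)) < 2:
            raise VehError("dataset must contain at least 2 distinct classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Return a copy restricted to the given gene columns (in order)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise EmptyStageError("subset", "cannot restrict to zero genes")
        return replace(
            self,
            values=self.values[:, idx].copy(),
            feature_ids=[self.feature_ids[i] for i in idx],
            missing_mask=self.missing_mask[:, idx].copy(),
        )

    def subset_by_ids(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to named features; raises on an unknown ID."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise VehError(f"unknown feature id(s): {missing}")
        return self.subset_genes([pos[f] for f in feature_ids])


@dataclass
class GeneSubset:
    """A selected set of features traced back to the original header.

    ``fitness`` is the optimizer objective (lower is better) and
    ``accuracy`` a CV accuracy percentage, when known.
    """

    feature_ids: list[str]
    source_run: int = 0
    fitness: float | None = None
    accuracy: float | None = None

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        if not self.feature_ids:
            raise VehError("gene subset must be nonempty")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise VehError("gene subset contains duplicate ids")

    def __len__(self) -> int:
        return len(self.feature_ids)
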
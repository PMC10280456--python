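"""Synthetic expression matrices with known informative genes.

The generator emulates preprocessed microarray-style tables: a small
set of informative genes whose class-conditional means are shifted
apart by a chosen effect size, embedded among class-independent
Gaussian noise genes, with optional uniformly random missing entries
and configurable class imbalance.  Shapes can mirror real benchmark
datasets (tens to hundreds of samples, thousands of genes, 2-4
classes).  Because the ground-truth informative indices are returned,
every selection stage can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionDataset, VehError

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_synthetic_expression",
    "make_separable_toy",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic expression dataset.

    ``shift`` is the class-mean separation in units of ``noise_sd``;
    informative gene j has mean ``c * shift * noise_sd`` in class c.
    """

    n_samples: int = 100
    n_genes: int = 1000
    n_informative: int = 10
    n_classes: int = 2
    class_proportions: tuple[float, ...] | None = None
    shift: float = 2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise VehError("n_informative must not exceed n_genes")
        if self.n_classes < 2:
            raise VehError("need at least 2 classes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise VehError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise VehError("noise_sd must be positive")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if len(p) != self.n_classes or (p <= 0).any() or not np.isclose(p.sum(), 1.0):
                raise VehError("class_proportions must be positive and sum to 1")


@dataclass
class GroundTruth:
    """Which genes carry signal, and their class-conditional means."""

    informative_indices: np.ndarray
    class_means: np.ndarray  # shape (n_classes, n_informative)

    def informative_precision(self, feature_indices) -> float:
        """Fraction of a selected index set that is truly informative."""
        sel = np.asarray(feature_indices)
        if sel.size == 0:
            return 0.0
        return float(np.isin(sel, self.informative_indices).mean())

    def informative_recall(self, feature_indices) -> float:
        """Fraction of the truly informative genes present in a selection."""
        sel = np.asarray(feature_indices)
        return float(np.isin(self.informative_indices, sel).mean())


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    if spec.class_proportions is None:
        p = np.full(spec.n_classes, 1.0 / spec.n_classes)
    else:
        p = np.asarray(spec.class_proportions, dtype=float)
    counts = np.floor(p * spec.n_samples).astype(int)
    # distribute the remainder by largest fractional part
    rem = spec.n_samples - counts.sum()
    order = np.argsort(-(p * spec.n_samples - counts))
    counts[order[:rem]] += 1
    if (counts == 0).any():
        raise VehError("class proportions leave an empty class")
    return counts


def make_synthetic_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset from the class-shifted Gaussian model.

    Fully deterministic given ``spec.seed``.  Labels are the strings
    "c0", "c1", ...; sample order is shuffled so classes interleave.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    labels_int = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(labels_int)

    values = rng.normal(
        0.0, spec.noise_sd, size=(spec.n_samples, spec.n_genes)
    )
    informative = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )
    class_means = (
        np.arange(spec.n_classes)[:, None]
        * spec.shift
        * spec.noise_sd
        * np.ones((1, spec.n_informative))
    )
    values[:, informative] += class_means[labels_int, :]

    missing = np.zeros(values.shape, dtype=bool)
    if spec.missing_rate > 0:
        missing = rng.uniform(size=values.shape) < spec.missing_rate
        # keep every gene observable at least once
        all_gone = missing.all(axis=0)
        if all_gone.any():
            missing[0, all_gone] = False
        values = np.where(missing, np.nan, values)

    ds = ExpressionDataset(
        values=values,
        feature_ids=[f"g{j}" for j in range(spec.n_genes)],
        labels=np.array([f"c{c}" for c in labels_int]),
        name=spec.name,
        missing_mask=missing,
    )
    return ds, GroundTruth(informative_indices=informative, class_means=class_means)


def make_separable_toy(
    n_samples: int = 60, n_genes: int = 50, seed: int = 0
) -> tuple[ExpressionDataset, GroundTruth]:
    """Perfectly separable fixture: gene 0 is a noiseless label encoding.

    Balanced binary classes; genes 1..n-1 are pure standard-normal
    noise.  Any classifier given gene 0 alone classifies perfectly, and
    after min-max normalization gene 0 is a balanced 0/1 column with
    population variance 0.25.
    """
    if n_genes < 1:
        raise VehError("need at least one gene")
    rng = np.random.default_rng(seed)
    labels_int = np.arange(n_samples) % 2
    rng.shuffle(labels_int)
    values = rng.standard_normal((n_samples, n_genes))
    values[:, 0] = labels_int.astype(float)
    ds = ExpressionDataset(
        values=values,
        feature_ids=[f"g{j}" for j in range(n_genes)],
        labels=np.array([f"c{c}" for c in labels_int]),
        name="separable_toy",
        missing_mask=np.zeros(values.shape, dtype=bool),
    )
    truth = GroundTruth(
        informative_indices=np.array([0]),
        class_means=np.array([[0.0], [1.0]]),
    )
    return ds, truth


def write_synthetic_csv(ds: ExpressionDataset, path) -> None:
    """Write a dataset in the samples-in-rows CSV dialect the reader consumes."""
    import pandas as pd

    df = pd.DataFrame(ds.values, columns=ds.feature_ids)
    df[ds.feature_ids] = df[ds.feature_ids].where(~ds.missing_mask, other=np.nan)
    df["label"] = ds.labels
    df.to_csv(path, index=False)
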
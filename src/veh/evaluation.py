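"""Repeated stratified cross-validation and macro-averaged metrics.

A selected gene subset is scored with three standard classifiers —
decision tree, RBF-kernel SVM and L2 logistic regression — under
repeated stratified k-fold cross-validation (default 10 repeats of
tenfold).  Per repeat, predictions from all folds are pooled into one
confusion table; accuracy is the overall fraction correct and
precision/recall/F1 are computed per class and averaged with equal
class weights (macro averaging, 0/0 ratios defined as 0).  Reported
means are percentages; the standard deviation is taken across the
per-repeat accuracies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datatypes import ExpressionDataset, GeneSubset, VehError

__all__ = [
    "ConfusionCounts",
    "ClassifierConfig",
    "CVReport",
    "stratified_kfold_indices",
    "confusion_counts",
    "classification_metrics",
    "build_classifier",
    "repeated_cv_evaluate",
    "select_optimal_subset",
]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest confusion counts from pooled predictions."""

    classes: list
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


@dataclass
class ClassifierConfig:
    """One evaluation classifier at its fixed settings.

    kind "dt": decision tree (random_state 0, max depth 8, max features
    10 capped at the available feature count); "svm": RBF SVC with
    C = 1.0; "lr": L2 logistic regression with C = 1.0 (one-vs-rest for
    more than two classes).
    """

    kind: str = "svm"
    dt_random_state: int = 0
    dt_max_depth: int = 8
    dt_max_features: int = 10
    svm_C: float = 1.0
    svm_kernel: str = "rbf"
    lr_C: float = 1.0
    lr_penalty: str = "l2"
    lr_max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.kind not in ("dt", "svm", "lr"):
            raise VehError("classifier kind must be 'dt', 'svm' or 'lr'")


@dataclass
class CVReport:
    """Mean metrics (percent) over repeats, with the accuracy SD."""

    acc: float
    precision: float
    recall: float
    f1: float
    sd: float
    repeats: int
    folds: int
    per_repeat_acc: list[float]


def stratified_kfold_indices(
    labels: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Stratified fold assignment: k disjoint test index arrays.

    Per-class counts across folds differ by at most one.  Every class
    must have at least k members.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise VehError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise VehError(
            f"class(es) smaller than k={k}: {small.tolist()}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(len(labels)), labels)]


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Pool predictions into per-class one-vs-rest confusion counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise VehError("empty prediction set")
    classes = np.unique(y_true).tolist()
    tp = np.array([np.sum((y_true == c) & (y_pred == c)) for c in classes])
    fp = np.array([np.sum((y_true != c) & (y_pred == c)) for c in classes])
    fn = np.array([np.sum((y_true == c) & (y_pred != c)) for c in classes])
    tn = np.array([np.sum((y_true != c) & (y_pred != c)) for c in classes])
    return ConfusionCounts(classes=classes, tp=tp, fp=fp, fn=fn, tn=tn)


def classification_metrics(
    counts: ConfusionCounts,
) -> tuple[float, float, float, float]:
    """Accuracy plus macro precision/recall/F1 on the 0-1 scale.

    Accuracy is the pooled fraction of correct predictions (for a
    binary table this equals (TP + TN) / (P + N)); per-class ratios
    with a zero denominator are defined as 0 before macro averaging.
    """
    total = counts.total
    if total == 0:
        raise VehError("empty confusion table")
    acc = float(counts.tp.sum()) / total

    def safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        return np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)

    prec_c = safe_div(counts.tp, counts.tp + counts.fp)
    rec_c = safe_div(counts.tp, counts.tp + counts.fn)
    f1_c = safe_div(2 * prec_c * rec_c, prec_c + rec_c)
    return acc, float(prec_c.mean()), float(rec_c.mean()), float(f1_c.mean())


def build_classifier(cfg: ClassifierConfig, n_features: int, n_classes: int):
    """Instantiate the configured scikit-learn estimator."""
    if cfg.kind == "dt":
        return DecisionTreeClassifier(
            random_state=cfg.dt_random_state,
            max_depth=cfg.dt_max_depth,
            max_features=min(cfg.dt_max_features, n_features),
        )
    if cfg.kind == "svm":
        return SVC(C=cfg.svm_C, kernel=cfg.svm_kernel)
    lr_kwargs = {"C": cfg.lr_C, "max_iter": cfg.lr_max_iter}
    if cfg.lr_penalty != "l2":  # l2 is sklearn's default; passing it is deprecated
        lr_kwargs["penalty"] = cfg.lr_penalty
    est = LogisticRegression(**lr_kwargs)
    if n_classes > 2:
        est = OneVsRestClassifier(est)
    return est


def repeated_cv_evaluate(
    ds: ExpressionDataset,
    subset: GeneSubset,
    clf: ClassifierConfig,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    fold_normalize: bool = False,
) -> CVReport:
    """Repeated stratified k-fold CV of one classifier on one subset.

    Each repeat r uses a fresh fold split seeded ``seed + r``; per-fold
    test predictions are pooled before metrics are computed.  With
    ``fold_normalize`` the min-max scaling is refit on every training
    fold (leakage-safe mode) instead of assuming the dataset was
    normalized up front.
    """
    sub = ds.subset_by_ids(subset.feature_ids)
    X, y = sub.values, sub.labels
    n_classes = len(np.unique(y))
    accs, precs, recs, f1s = [], [], [], []
    for r in range(repeats):
        test_folds = stratified_kfold_indices(y, folds, seed + r)
        y_pred = np.empty_like(y)
        for test in test_folds:
            train = np.setdiff1d(np.arange(len(y)), test)
            Xtr, Xte = X[train], X[test]
            if fold_normalize:
                lo, hi = Xtr.min(axis=0), Xtr.max(axis=0)
                span = np.where(hi > lo, hi - lo, 1.0)
                Xtr = (Xtr - lo) / span
                Xte = (Xte - lo) / span
            est = build_classifier(clf, X.shape[1], n_classes)
            est.fit(Xtr, y[train])
            y_pred[test] = est.predict(Xte)
        acc, prec, rec, f1 = classification_metrics(confusion_counts(y, y_pred))
        accs.append(acc)
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    acc_pct = [100.0 * a for a in accs]
    return CVReport(
        acc=float(np.mean(acc_pct)),
        precision=100.0 * float(np.mean(precs)),
        recall=100.0 * float(np.mean(recs)),
        f1=100.0 * float(np.mean(f1s)),
        sd=float(np.std(acc_pct)),
        repeats=repeats,
        folds=folds,
        per_repeat_acc=acc_pct,
    )


def select_optimal_subset(candidates: list[GeneSubset]) -> GeneSubset:
    """Pick the reported subset from the per-run candidates.

    Order of preference: highest accuracy, then smallest size, then the
    subset (as an ID set) occurring most often across runs, then the
    earliest run index.
    """
    if not candidates:
        raise VehError("no candidate subsets")
    freq = Counter(frozenset(c.feature_ids) for c in candidates)

    def sort_key(c: GeneSubset):
        acc = c.accuracy if c.accuracy is not None else -np.inf
        return (
            -acc,
            len(c.feature_ids),
            -freq[frozenset(c.feature_ids)],
            c.source_run,
        )

    return min(candidates, key=sort_key)

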
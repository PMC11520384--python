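"""Balanced sampling, linear SVM classification, and agreement scoring.

The classification unit is a labeled observation table (pixel or block-mean
spectra x class). Scoring follows the study design: stratified 10-fold
cross-validation of a linear-kernel SVM at default regularization, overall
accuracy K-1 (mean held-out fold accuracy, percent), per-class accuracy
(recall: confusion-matrix diagonal over row sum), and Cohen's kappa computed
from the pooled held-out confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "CLASS_ORDER",
    "LabeledPixelTable",
    "ConfusionMatrix",
    "ClassificationScore",
    "InsufficientPoolError",
    "balanced_sample",
    "cohen_kappa",
    "kappa_band",
    "kfold_scores",
]

CLASS_ORDER = ("baseline", "control", "low", "high")

# conventional interpretation bands for kappa
_KAPPA_BANDS = (
    (0.0, "poor"),
    (0.01, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


class InsufficientPoolError(ValueError):
    """A class pool cannot supply the requested balanced sample."""

    def __init__(self, label: str, available: int, requested: int):
        self.label, self.available, self.requested = label, available, requested
        super().__init__(
            f"class {label!r} has {available} observations, "
            f"{requested} requested (deficit {requested - available})"
        )


@dataclass
class LabeledPixelTable:
    """n_obs x n_bands spectra with one class label per row."""

    spectra: np.ndarray
    labels: np.ndarray
    classes: tuple = CLASS_ORDER
    provenance: Mapping | None = None

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.spectra.ndim != 2 or self.spectra.shape[0] != self.labels.shape[0]:
            raise ValueError("spectra and labels are inconsistent")

    @property
    def n_obs(self) -> int:
        return int(self.labels.size)

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def balanced_sample(
    pools: Mapping[str, np.ndarray],
    n_per_class: int,
    seed: int = 0,
    classes: Sequence[str] | None = None,
) -> LabeledPixelTable:
    """Draw exactly n_per_class rows per class, without replacement, seeded.

    A pool smaller than n_per_class raises InsufficientPoolError naming the
    class and deficit; classes are never silently truncated, since class
    imbalance biases the margin classifier.
    """
    classes = tuple(classes) if classes is not None else tuple(pools)
    rng = np.random.default_rng(seed)
    chunks, labels = [], []
    for label in classes:
        pool = np.asarray(pools[label], dtype=float)
        if pool.shape[0] < n_per_class:
            raise InsufficientPoolError(label, pool.shape[0], n_per_class)
        if n_per_class > 0:
            idx = rng.choice(pool.shape[0], size=n_per_class, replace=False)
            chunks.append(pool[idx])
            labels.append(np.full(n_per_class, label, dtype=object))
    if not chunks:
        n_bands = next(iter(pools.values())).shape[1] if pools else 0
        return LabeledPixelTable(np.empty((0, n_bands)), np.empty(0, dtype=object), classes)
    return LabeledPixelTable(np.vstack(chunks), np.concatenate(labels), classes)


@dataclass
class ConfusionMatrix:
    """c x c counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("confusion matrix shape does not match class list")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_accuracy(self) -> np.ndarray:
        """Recall per true class: diagonal over row sum (NaN for empty rows)."""
        row_sums = self.counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(row_sums > 0, np.diag(self.counts) / row_sums, np.nan)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace / total); p_e the agreement expected
    from the row/column margins. Returns NaN when p_e == 1 (degenerate
    margins make chance correction undefined).
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    p_o = np.trace(counts) / total
    p_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0))) / total**2
    if np.isclose(p_e, 1.0):
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_band(kappa: float) -> str:
    """Conventional verbal interpretation of a kappa value."""
    if np.isnan(kappa):
        return "undefined"
    label = "poor"
    for threshold, name in _KAPPA_BANDS:
        if kappa >= threshold:
            label = name
    return label


@dataclass
class ClassificationScore:
    """Cross-validated performance of one classification configuration."""

    per_class_accuracy: dict
    k1: float  # mean held-out fold accuracy, percent
    kappa: float
    confusion: ConfusionMatrix
    n_folds: int
    seed: int

    @property
    def kappa_band(self) -> str:
        return kappa_band(self.kappa)

    def to_dict(self) -> dict:
        return {
            "per_class_accuracy": {k: float(v) for k, v in self.per_class_accuracy.items()},
            "k1": float(self.k1),
            "kappa": float(self.kappa),
            "kappa_band": self.kappa_band,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def kfold_scores(
    table: LabeledPixelTable,
    k: int = 10,
    seed: int = 0,
    standardize: bool = False,
) -> ClassificationScore:
    """Stratified k-fold CV of a linear-kernel SVM with default regularization.

    Per fold the classifier is fit on k-1 folds and scores the held-out fold;
    K-1 is the mean held-out accuracy x 100. Held-out predictions pooled over
    all folds build the confusion matrix for per-class accuracy and kappa.
    Features are raw band reflectances unless standardize=True (z-score using
    training-fold statistics).
    """
    if k < 2:
        raise ValueError("k-fold CV needs k >= 2")
    counts = table.class_counts()
    too_small = {c: n for c, n in counts.items() if n < k}
    if too_small:
        raise ValueError(f"classes with fewer than k={k} observations: {too_small}")

    X, y = table.spectra, table.labels.astype(str)
    present = [c for c in table.classes if c in counts]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc = []
    y_true_all, y_pred_all = [], []
    for train_idx, test_idx in splitter.split(X, y):
        X_train, X_test = X[train_idx], X[test_idx]
        if standardize:
            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            sd[sd == 0] = 1.0
            X_train = (X_train - mu) / sd
            X_test = (X_test - mu) / sd
        clf = SVC(kernel="linear")  # one-vs-one multiclass, default C
        clf.fit(X_train, y[train_idx])
        pred = clf.predict(X_test)
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)

    cm = ConfusionMatrix(
        _sk_confusion(
            np.concatenate(y_true_all), np.concatenate(y_pred_all), labels=present
        ),
        tuple(present),
    )
    per_class = dict(zip(present, cm.per_class_accuracy().tolist()))
    return ClassificationScore(
        per_class_accuracy=per_class,
        k1=100.0 * float(np.mean(fold_acc)),
        kappa=cohen_kappa(cm),
        confusion=cm,
        n_folds=k,
        seed=seed,
    )
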
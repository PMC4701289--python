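"""Cross-validated evaluation: stratified k-fold, confusion matrix, accuracies.

The aggregated out-of-fold confusion matrix (every instance predicted exactly
once, by a tree that never saw it) is the primary performance surface; the
classifier with the highest fold test accuracy is additionally reported as the
selected model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import c45
from .features import Dataset

__all__ = [
    "FoldAssignment",
    "ConfusionMatrix",
    "CVResult",
    "kfold_split",
    "cross_validate",
    "confusion",
    "overall_accuracy",
    "per_class_accuracy",
]


@dataclass
class FoldAssignment:
    """Fold index per instance for k-fold cross-validation."""

    folds: np.ndarray
    k: int
    seed: int
    stratified: bool


@dataclass
class ConfusionMatrix:
    """w x w count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        w = len(self.class_names)
        if self.counts.shape != (w, w):
            raise ValueError("counts must be square and match class_names")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_names), columns=list(self.class_names)
        )

    def plot(self, ax=None):
        """Heatmap of the matrix with count annotations (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4.5))
        ax.imshow(self.counts, cmap="Blues")
        w = len(self.class_names)
        ax.set_xticks(range(w), self.class_names, rotation=45, ha="right")
        ax.set_yticks(range(w), self.class_names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        vmax = self.counts.max(initial=1)
        for i in range(w):
            for j in range(w):
                ax.text(
                    j, i, str(self.counts[i, j]), ha="center", va="center",
                    color="white" if self.counts[i, j] > 0.6 * vmax else "black",
                )
        return ax


@dataclass
class CVResult:
    """Outcome of one cross-validation run."""

    trees: list[c45.DecisionTree]
    fold_accuracies: np.ndarray
    matrix: ConfusionMatrix
    best_index: int
    k: int
    seed: int

    @property
    def best_tree(self) -> c45.DecisionTree:
        return self.trees[self.best_index]

    @property
    def overall_accuracy(self) -> float:
        return overall_accuracy(self.matrix)


def kfold_split(
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    class_names: Sequence[str] | None = None,
) -> FoldAssignment:
    """Seeded shuffle then (per-class, if stratified) round-robin assignment.

    Every instance lands in exactly one fold; stratified fold sizes differ by
    at most one instance per class.
    """
    y = np.asarray(y)
    m = y.size
    if k < 2 or k > m:
        raise ValueError(f"k must be in [2, {m}], got {k}")
    rng = np.random.default_rng(seed)
    folds = np.empty(m, dtype=np.intp)
    if stratified:
        if class_names is None:
            class_names = sorted(set(y.tolist()))
        offset = 0  # rolling offset keeps fold sizes even across classes
        for c in class_names:
            idx = np.flatnonzero(y == c)
            idx = idx[rng.permutation(idx.size)]
            folds[idx] = (offset + np.arange(idx.size)) % k
            offset = (offset + idx.size) % k
    else:
        perm = rng.permutation(m)
        folds[perm] = np.arange(m) % k
    return FoldAssignment(folds=folds, k=k, seed=seed, stratified=stratified)


def confusion(
    truth: Sequence[str],
    predicted: Sequence[str],
    class_names: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #(truth = class_i and predicted = class_j)."""
    truth = np.asarray(truth, dtype=str)
    predicted = np.asarray(predicted, dtype=str)
    if truth.size != predicted.size:
        raise ValueError("truth and predicted must have equal length")
    if class_names is None:
        class_names = sorted(set(truth.tolist()) | set(predicted.tolist()))
    code = {c: i for i, c in enumerate(class_names)}
    w = len(class_names)
    counts = np.zeros((w, w), dtype=np.int64)
    for t, p in zip(truth.tolist(), predicted.tolist()):
        if t not in code or p not in code:
            raise ValueError(f"unknown class label {t if t not in code else p!r}")
        counts[code[t], code[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 x trace / total, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """100 x diagonal / row sum, per true class (percent)."""
    row_sums = cm.counts.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("per-class accuracy undefined for an absent class")
    return 100.0 * np.diag(cm.counts) / row_sums


def cross_validate(
    dataset: Dataset,
    params: c45.InductionParams = c45.InductionParams(),
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    prune: bool = True,
) -> CVResult:
    """k-fold cross-validation of the C4.5 learner on ``dataset``.

    Each fold's tree is induced (and post-pruned) on the other k-1 folds and
    predicts its held-out fold; the aggregated matrix accumulates all
    out-of-fold predictions.  The best tree is the one with the highest fold
    test accuracy (ties toward the lowest fold index).
    """
    assignment = kfold_split(dataset.y, k, seed, stratified, dataset.class_names)
    w = len(dataset.class_names)
    counts = np.zeros((w, w), dtype=np.int64)
    code = {c: i for i, c in enumerate(dataset.class_names)}
    trees: list[c45.DecisionTree] = []
    fold_accuracies = np.empty(k, dtype=np.float64)
    for fold in range(k):
        test = assignment.folds == fold
        tree = c45.induce(
            dataset.X[~test],
            dataset.y[~test],
            dataset.class_names,
            params,
            dataset.attribute_names,
        )
        if prune:
            tree = c45.prune(tree)
        predictions = tree.predict(dataset.X[test])
        truth = dataset.y[test]
        for t, p in zip(truth.tolist(), predictions.tolist()):
            counts[code[t], code[p]] += 1
        fold_accuracies[fold] = 100.0 * float(np.mean(predictions == truth))
        trees.append(tree)
    matrix = ConfusionMatrix(counts=counts, class_names=dataset.class_names)
    best_index = int(np.argmax(fold_accuracies))
    return CVResult(
        trees=trees,
        fold_accuracies=fold_accuracies,
        matrix=matrix,
        best_index=best_index,
        k=k,
        seed=seed,
    )
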
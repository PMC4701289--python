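"""Model/Results interface over the C4.5 pipeline.

``ChewingPatternModel`` holds a feature matrix of chew-movement instances;
``fit()`` induces and post-prunes a C4.5 tree and returns a results object
with the estimates (tree, rules), resubstitution diagnostics and a text
``summary()``; ``cross_validate()`` returns the out-of-fold performance
picture, which is the honest estimate of generalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import c45, evaluation
from .features import Dataset
from .synthetic import CLASSES

__all__ = ["ChewingPatternModel", "ChewingPatternResults", "CrossValidationResults"]


class ChewingPatternModel:
    """Decision-tree classifier of chewing patterns, statsmodels-style.

    Parameters
    ----------
    dataset : Dataset
        Feature matrix with labels (for example from ``features.build_dataset``
        or ``Dataset.from_csv``).
    params : c45.InductionParams, optional
        Induction and pruning parameters.
    """

    def __init__(self, dataset: Dataset, params: c45.InductionParams | None = None):
        if dataset.m == 0:
            raise ValueError("cannot model an empty dataset")
        self.dataset = dataset
        self.params = params or c45.InductionParams()

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, params: c45.InductionParams | None = None
    ) -> "ChewingPatternModel":
        return cls(Dataset.from_dataframe(frame, CLASSES), params)

    @classmethod
    def from_csv(
        cls, path, params: c45.InductionParams | None = None
    ) -> "ChewingPatternModel":
        return cls(Dataset.from_csv(path, CLASSES), params)

    def fit(self, prune: bool = True) -> "ChewingPatternResults":
        """Induce (and optionally post-prune) a tree on the full dataset."""
        tree = c45.induce(
            self.dataset.X,
            self.dataset.y,
            self.dataset.class_names,
            self.params,
            self.dataset.attribute_names,
        )
        unpruned_stats = c45.tree_stats(tree)
        if prune:
            tree = c45.prune(tree)
        return ChewingPatternResults(self, tree, unpruned_stats)

    def cross_validate(
        self, k: int = 10, seed: int = 0, stratified: bool = True, prune: bool = True
    ) -> "CrossValidationResults":
        """k-fold cross-validation; see ``evaluation.cross_validate``."""
        result = evaluation.cross_validate(
            self.dataset, self.params, k=k, seed=seed, stratified=stratified, prune=prune
        )
        return CrossValidationResults(self, result)


@dataclass
class ChewingPatternResults:
    """A fitted tree plus resubstitution diagnostics."""

    model: ChewingPatternModel
    tree: c45.DecisionTree
    unpruned_stats: tuple[int, int, int]

    def __post_init__(self) -> None:
        ds = self.model.dataset
        self._resub_pred = self.tree.predict(ds.X)
        self.resub_matrix = evaluation.confusion(ds.y, self._resub_pred, ds.class_names)

    @property
    def resubstitution_accuracy(self) -> float:
        return evaluation.overall_accuracy(self.resub_matrix)

    @property
    def tree_stats(self) -> tuple[int, int, int]:
        return c45.tree_stats(self.tree)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.tree.attribute_names)].to_numpy(dtype=np.float64)
        return self.tree.predict(np.asarray(X, dtype=np.float64))

    def rules(self) -> list[str]:
        return c45.extract_rules(self.tree)

    def summary(self) -> str:
        ds = self.model.dataset
        nodes, leaves, decision = self.tree_stats
        u_nodes, u_leaves, u_decision = self.unpruned_stats
        lines = [
            "Chewing-pattern C4.5 classifier",
            "=" * 47,
            f"Instances:              {ds.m}",
            f"Attributes:             {ds.n_attributes}",
            f"Classes:                {len(ds.class_names)}",
            f"Tree size (pruned):     {nodes} nodes = {decision} decision + {leaves} leaves",
            f"Tree size (unpruned):   {u_nodes} nodes = {u_decision} decision + {u_leaves} leaves",
            f"Resubstitution accuracy: {self.resubstitution_accuracy:.1f}%",
            "",
            "Per-class resubstitution accuracy (%):",
        ]
        for name, acc in zip(
            ds.class_names, evaluation.per_class_accuracy(self.resub_matrix)
        ):
            lines.append(f"  {name:<20s} {acc:6.1f}")
        return "\n".join(lines)


@dataclass
class CrossValidationResults:
    """Aggregated out-of-fold performance of the learner."""

    model: ChewingPatternModel
    cv: evaluation.CVResult

    @property
    def matrix(self) -> evaluation.ConfusionMatrix:
        return self.cv.matrix

    @property
    def overall_accuracy(self) -> float:
        return self.cv.overall_accuracy

    @property
    def per_class_accuracy(self) -> np.ndarray:
        return evaluation.per_class_accuracy(self.cv.matrix)

    @property
    def fold_accuracies(self) -> np.ndarray:
        return self.cv.fold_accuracies

    @property
    def best_tree(self) -> c45.DecisionTree:
        return self.cv.best_tree

    def plot_confusion(self, ax=None):
        return self.cv.matrix.plot(ax=ax)

    def summary(self) -> str:
        ds = self.model.dataset
        nodes, leaves, decision = c45.tree_stats(self.best_tree)
        lines = [
            f"{self.cv.k}-fold cross-validation (seed {self.cv.seed})",
            "=" * 47,
            f"Instances:              {ds.m}",
            f"Overall accuracy:       {self.overall_accuracy:.1f}%"
            f"  ({int(np.trace(self.matrix.counts))}/{self.matrix.total} correct)",
            f"Fold accuracies (%):    "
            + " ".join(f"{a:.0f}" for a in self.fold_accuracies),
            f"Best fold:              {self.cv.best_index + 1}"
            f" ({self.fold_accuracies[self.cv.best_index]:.1f}%)",
            f"Best tree:              {nodes} nodes = {decision} decision + {leaves} leaves",
            "",
            "Aggregated out-of-fold confusion matrix (rows = truth):",
            self.matrix.to_dataframe().to_string(),
            "",
            "Per-class accuracy (%):",
        ]
        for name, acc in zip(ds.class_names, self.per_class_accuracy):
            lines.append(f"  {name:<20s} {acc:6.1f}")
        return "\n".join(lines)
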
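"""C4.5 decision-tree induction on continuous attributes.

Implements the classical learner from scratch: entropy in bits, information
gain, gain ratio with Quinlan's average-gain guard, binary threshold splits at
midpoints between consecutive distinct values, recursive induction, and
error-based post-pruning using the binomial (Clopper-Pearson) upper confidence
limit on leaf error counts.

Missing-value handling (fractional instances) and subtree raising are not
implemented: the pipeline never produces missing attributes, and pruning is by
subtree replacement only.  Induction is fully deterministic; ties break toward
the lowest attribute index, lowest threshold and earliest class.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "InductionParams",
    "SplitCandidate",
    "TreeNode",
    "DecisionTree",
    "entropy",
    "evaluate_split",
    "best_split",
    "induce",
    "prune",
    "predict",
    "extract_rules",
    "tree_stats",
    "upper_error_bound",
]

_EPS = 1e-12


@dataclass(frozen=True)
class InductionParams:
    """Induction and pruning knobs (Quinlan's release defaults)."""

    min_leaf: int = 2
    confidence_factor: float = 0.25
    use_average_gain_guard: bool = True
    threshold_style: str = "midpoint"

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0.0 < self.confidence_factor < 1.0:
            raise ValueError("confidence_factor must be in (0, 1)")
        if self.threshold_style not in ("midpoint", "largest_leq"):
            raise ValueError("threshold_style must be 'midpoint' or 'largest_leq'")


@dataclass(frozen=True)
class SplitCandidate:
    """A binary threshold test with its impurity bookkeeping (bits)."""

    attribute_index: int  # 1-based
    threshold: float
    gain: float
    split_info: float
    gain_ratio: float


@dataclass
class TreeNode:
    """Decision node (attribute <= threshold goes left) or leaf."""

    counts: np.ndarray
    attribute_index: int | None = None  # 1-based; None for leaves
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    klass: int | None = None  # class code at leaves

    @property
    def is_leaf(self) -> bool:
        return self.attribute_index is None


@dataclass
class DecisionTree:
    """A fitted C4.5 tree together with its label/attribute vocabulary."""

    root: TreeNode
    class_names: tuple[str, ...]
    attribute_names: tuple[str, ...]
    params: InductionParams

    @property
    def n_nodes(self) -> int:
        return tree_stats(self)[0]

    @property
    def n_leaves(self) -> int:
        return tree_stats(self)[1]

    @property
    def n_decision(self) -> int:
        return tree_stats(self)[2]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def to_json(self) -> str:
        def encode(node: TreeNode) -> dict:
            counts = {
                self.class_names[i]: int(c)
                for i, c in enumerate(node.counts)
                if c
            }
            if node.is_leaf:
                return {"leaf_class": self.class_names[node.klass], "counts": counts}
            return {
                "attr": self.attribute_names[node.attribute_index - 1],
                "threshold": node.threshold,
                "counts": counts,
                "left": encode(node.left),
                "right": encode(node.right),
            }

        return json.dumps(
            {
                "class_names": list(self.class_names),
                "attribute_names": list(self.attribute_names),
                "params": {
                    "min_leaf": self.params.min_leaf,
                    "confidence_factor": self.params.confidence_factor,
                    "use_average_gain_guard": self.params.use_average_gain_guard,
                    "threshold_style": self.params.threshold_style,
                },
                "root": encode(self.root),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        doc = json.loads(text)
        class_names = tuple(doc["class_names"])
        attribute_names = tuple(doc["attribute_names"])
        class_code = {c: i for i, c in enumerate(class_names)}
        attr_code = {a: i + 1 for i, a in enumerate(attribute_names)}

        def decode(d: dict) -> TreeNode:
            counts = np.zeros(len(class_names), dtype=np.int64)
            for c, v in d.get("counts", {}).items():
                counts[class_code[c]] = v
            if "leaf_class" in d:
                return TreeNode(counts=counts, klass=class_code[d["leaf_class"]])
            return TreeNode(
                counts=counts,
                attribute_index=attr_code[d["attr"]],
                threshold=float(d["threshold"]),
                left=decode(d["left"]),
                right=decode(d["right"]),
            )

        return cls(
            root=decode(doc["root"]),
            class_names=class_names,
            attribute_names=attribute_names,
            params=InductionParams(**doc["params"]),
        )


def entropy(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy in bits of a class-count vector (0·log 0 = 0)."""
    c = np.asarray(counts, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy of an empty node is undefined")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Entropy in bits of each row of a count matrix (vectorized)."""
    totals = counts.sum(axis=1, keepdims=True)
    p = counts / totals
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=p > 0)
    return -(p * logp).sum(axis=1)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    q = 1.0 - p
    logp = np.zeros_like(p)
    logq = np.zeros_like(q)
    np.log2(p, out=logp, where=p > 0)
    np.log2(q, out=logq, where=q > 0)
    return -(p * logp + q * logq)


def evaluate_split(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    attribute_index: int,
    threshold: float,
) -> SplitCandidate | None:
    """Gain / split info / gain ratio of one explicit threshold test.

    Returns None when the threshold does not actually split the node
    (one branch would be empty).
    """
    values = X[:, attribute_index - 1]
    left = values <= threshold
    nl = int(left.sum())
    m = values.size
    if nl == 0 or nl == m:
        return None
    parent = np.bincount(y, minlength=n_classes)
    lcounts = np.bincount(y[left], minlength=n_classes)
    rcounts = parent - lcounts
    gain = entropy(parent) - (nl / m) * entropy(lcounts) - ((m - nl) / m) * entropy(rcounts)
    gain = max(gain, 0.0)
    split_info = float(_binary_entropy(np.array([nl / m]))[0])
    return SplitCandidate(
        attribute_index=attribute_index,
        threshold=float(threshold),
        gain=float(gain),
        split_info=split_info,
        gain_ratio=float(gain / split_info) if split_info > 0 else math.inf,
    )


def _attribute_candidates(
    values: np.ndarray,
    y_onehot: np.ndarray,
    parent_entropy: float,
    min_leaf: int,
    threshold_style: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None:
    """All admissible (threshold, gain, split_info, gain_ratio) for one attribute.

    Candidate boundaries fall between consecutive distinct sorted values with
    at least ``min_leaf`` instances on each side.  Returns None when the
    attribute is constant or no boundary is admissible.
    """
    m = values.size
    order = np.argsort(values, kind="stable")
    vs = values[order]
    boundaries = np.flatnonzero(vs[1:] > vs[:-1])  # split between b and b+1
    if min_leaf > 1:
        nl = boundaries + 1
        boundaries = boundaries[(nl >= min_leaf) & (m - nl >= min_leaf)]
    if boundaries.size == 0:
        return None
    csum = np.cumsum(y_onehot[order], axis=0)
    lcounts = csum[boundaries]
    rcounts = csum[-1] - lcounts
    nl = (boundaries + 1).astype(np.float64)
    gains = parent_entropy - (
        nl / m * _entropy_rows(lcounts) + (m - nl) / m * _entropy_rows(rcounts)
    )
    np.maximum(gains, 0.0, out=gains)
    split_infos = _binary_entropy(nl / m)
    ratios = gains / split_infos
    if threshold_style == "midpoint":
        thresholds = 0.5 * (vs[boundaries] + vs[boundaries + 1])
    else:
        thresholds = vs[boundaries].copy()
    return thresholds, gains, split_infos, ratios


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    params: InductionParams = InductionParams(),
) -> SplitCandidate | None:
    """Highest-gain-ratio admissible split, or None.

    With the average-gain guard on, only candidates whose gain reaches the
    mean gain of all positive-gain candidates compete on gain ratio.  Ties
    break toward the lowest attribute index, then the lowest threshold.
    """
    parent = np.bincount(y, minlength=n_classes)
    if np.count_nonzero(parent) < 2:
        return None
    parent_entropy = entropy(parent)
    y_onehot = np.zeros((y.size, n_classes), dtype=np.int64)
    y_onehot[np.arange(y.size), y] = 1
    per_attr = []
    gain_sum, gain_count = 0.0, 0
    for j in range(X.shape[1]):
        cand = _attribute_candidates(
            X[:, j], y_onehot, parent_entropy, params.min_leaf, params.threshold_style
        )
        per_attr.append(cand)
        if cand is not None:
            positive = cand[1] > _EPS
            gain_sum += float(cand[1][positive].sum())
            gain_count += int(positive.sum())
    if gain_count == 0:
        return None
    mean_gain = gain_sum / gain_count
    best: SplitCandidate | None = None
    for j, cand in enumerate(per_attr):
        if cand is None:
            continue
        thresholds, gains, split_infos, ratios = cand
        eligible = gains > _EPS
        if params.use_average_gain_guard:
            eligible &= gains >= mean_gain - _EPS
        if not eligible.any():
            continue
        # Lowest threshold among ratio ties (within float tolerance), then
        # lowest attribute index across attributes.
        idx = np.flatnonzero(eligible)
        k = idx[ratios[idx] >= ratios[idx].max() - _EPS][0]
        if best is None or ratios[k] > best.gain_ratio + _EPS:
            best = SplitCandidate(
                attribute_index=j + 1,
                threshold=float(thresholds[k]),
                gain=float(gains[k]),
                split_info=float(split_infos[k]),
                gain_ratio=float(ratios[k]),
            )
    return best


def induce(
    X: np.ndarray,
    y: np.ndarray,
    class_names: Sequence[str],
    params: InductionParams = InductionParams(),
    attribute_names: Sequence[str] | None = None,
) -> DecisionTree:
    """Grow a tree by recursive binary partitioning on gain ratio.

    A leaf is made when the node is pure, smaller than ``2 * min_leaf``, or no
    admissible split has positive gain.  Leaf classes are majorities with ties
    toward the earliest class.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] == 0:
        raise ValueError("X and y must be a non-empty consistent dataset")
    if attribute_names is None:
        attribute_names = tuple(f"a{i}" for i in range(1, X.shape[1] + 1))
    if y.dtype.kind in "UO":
        code = {c: i for i, c in enumerate(class_names)}
        y = np.asarray([code[v] for v in y], dtype=np.intp)
    else:
        y = y.astype(np.intp)
    w = len(class_names)

    def leaf(counts: np.ndarray) -> TreeNode:
        return TreeNode(counts=counts, klass=int(np.argmax(counts)))

    root = TreeNode(counts=np.bincount(y, minlength=w))
    # Explicit stack: trees grown on unstructured labels can be very deep.
    stack: list[tuple[TreeNode, np.ndarray]] = [(root, np.arange(y.size))]
    while stack:
        node, idx = stack.pop()
        counts = np.bincount(y[idx], minlength=w)
        node.counts = counts
        if np.count_nonzero(counts) < 2 or idx.size < 2 * params.min_leaf:
            node.klass = int(np.argmax(counts))
            continue
        cand = best_split(X[idx], y[idx], w, params)
        if cand is None:
            node.klass = int(np.argmax(counts))
            continue
        mask = X[idx, cand.attribute_index - 1] <= cand.threshold
        node.attribute_index = cand.attribute_index
        node.threshold = cand.threshold
        node.klass = None
        node.left = TreeNode(counts=counts)
        node.right = TreeNode(counts=counts)
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))
    return DecisionTree(
        root=root,
        class_names=tuple(class_names),
        attribute_names=tuple(attribute_names),
        params=params,
    )


def upper_error_bound(errors: int, n: int, confidence_factor: float) -> float:
    """Binomial upper confidence limit on the true error rate.

    Clopper-Pearson: the largest p with P(Bin(n, p) <= errors) >= CF, i.e.
    the (1 - CF) quantile of Beta(errors + 1, n - errors).
    """
    if n <= 0:
        return 1.0
    if errors >= n:
        return 1.0
    return float(stats.beta.ppf(1.0 - confidence_factor, errors + 1, n - errors))


def _node_pessimistic_errors(node: TreeNode, cf: float) -> float:
    total = 0.0
    for n_ in _walk(node):
        if n_.is_leaf:
            n = int(n_.counts.sum())
            e = n - int(n_.counts.max(initial=0))
            total += n * upper_error_bound(e, n, cf)
    return total


def prune(tree: DecisionTree, confidence_factor: float | None = None) -> DecisionTree:
    """Bottom-up subtree replacement by pessimistic-error comparison.

    A decision node is collapsed to a leaf when the leaf's estimated errors
    (count times binomial upper limit at CF) do not exceed the sum of its
    (already pruned) children's estimates.  Never increases the node count.
    """
    cf = tree.params.confidence_factor if confidence_factor is None else confidence_factor
    if not 0.0 < cf < 1.0:
        raise ValueError("confidence_factor must be in (0, 1)")
    pruned = copy.deepcopy(tree)
    # Iterative post-order: children are fully pruned before their parent is
    # examined, and each subtree's pessimistic error is memoized.
    est: dict[int, float] = {}
    stack: list[tuple[TreeNode, bool]] = [(pruned.root, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf:
            n = int(node.counts.sum())
            e = n - int(node.counts.max(initial=0))
            est[id(node)] = n * upper_error_bound(e, n, cf)
            continue
        if not expanded:
            stack.append((node, True))
            stack.append((node.left, False))
            stack.append((node.right, False))
            continue
        n = int(node.counts.sum())
        e = n - int(node.counts.max(initial=0))
        leaf_errors = n * upper_error_bound(e, n, cf)
        subtree_errors = est.pop(id(node.left)) + est.pop(id(node.right))
        if leaf_errors <= subtree_errors + 1e-9:
            node.attribute_index = None
            node.threshold = None
            node.left = node.right = None
            node.klass = int(np.argmax(node.counts))
            est[id(node)] = leaf_errors
        else:
            est[id(node)] = subtree_errors
    return pruned


def predict(tree: DecisionTree, X: np.ndarray) -> np.ndarray:
    """Class names for one instance (1-D) or a matrix of instances (2-D)."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    n_needed = max(
        (n.attribute_index for n in _walk(tree.root) if not n.is_leaf), default=0
    )
    if X.shape[1] < n_needed:
        raise ValueError(
            f"instances have {X.shape[1]} attributes but the tree references a{n_needed}"
        )
    out = np.empty(X.shape[0], dtype=object)
    for i, row in enumerate(X):
        node = tree.root
        while not node.is_leaf:
            node = node.left if row[node.attribute_index - 1] <= node.threshold else node.right
        out[i] = tree.class_names[node.klass]
    out = out.astype("<U20")
    return out[0] if single else out


def _walk(node: TreeNode) -> Iterator[TreeNode]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        if not n.is_leaf:
            stack.extend((n.left, n.right))


def tree_stats(tree: DecisionTree) -> tuple[int, int, int]:
    """(n_nodes, n_leaves, n_decision); always n_nodes = n_leaves + n_decision."""
    n_leaves = n_decision = 0
    for node in _walk(tree.root):
        if node.is_leaf:
            n_leaves += 1
        else:
            n_decision += 1
    return n_leaves + n_decision, n_leaves, n_decision


def _format_threshold(v: float) -> str:
    text = f"{v:.6f}".rstrip("0").rstrip(".")
    return text if text else "0"


def extract_rules(tree: DecisionTree) -> list[str]:
    """One IF/THEN rule per leaf, in left-to-right leaf order.

    Example rendering: ``IF (a851 <= 1541.107862) THEN ryegrass``.
    """
    rules: list[str] = []

    def walk(node: TreeNode, conditions: list[str]) -> None:
        if node.is_leaf:
            body = " AND ".join(f"({c})" for c in conditions) if conditions else "(TRUE)"
            rules.append(f"IF {body} THEN {tree.class_names[node.klass]}")
            return
        name = tree.attribute_names[node.attribute_index - 1]
        t = _format_threshold(node.threshold)
        walk(node.left, conditions + [f"{name} <= {t}"])
        walk(node.right, conditions + [f"{name} > {t}"])

    walk(tree.root, [])
    return rules
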
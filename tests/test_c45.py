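import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from fbgchew import c45
from fbgchew.c45 import (
    DecisionTree,
    InductionParams,
    TreeNode,
    best_split,
    entropy,
    evaluate_split,
    extract_rules,
    induce,
    predict,
    prune,
    tree_stats,
    upper_error_bound,
)


def random_dataset(rng, m, n_attrs, n_classes, informative=True):
    X = rng.normal(size=(m, n_attrs))
    y = rng.integers(0, n_classes, size=m)
    if informative:
        X[:, 0] += 3.0 * y  # one attribute carries the classes apart
    return X, y.astype(np.intp)


def exhaustive_best_split(X, y, n_classes, min_leaf=2):
    """Independent oracle: enumerate every (attribute, midpoint) candidate.

    Ties in gain ratio (within float tolerance) break toward the lowest
    attribute index, then the lowest threshold.
    """
    candidates = []
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for lo, hi in zip(values[:-1], values[1:]):
            t = 0.5 * (lo + hi)
            nl = int(np.sum(X[:, j] <= t))
            if nl < min_leaf or X.shape[0] - nl < min_leaf:
                continue
            cand = evaluate_split(X, y, n_classes, j + 1, t)
            if cand is not None and cand.gain > 1e-12:
                candidates.append(cand)
    if not candidates:
        return None
    best_ratio = max(c.gain_ratio for c in candidates)
    for cand in candidates:  # already in (attribute, threshold) order
        if cand.gain_ratio >= best_ratio - 1e-12:
            return cand
    return None


class TestEntropy:
    def test_pure_node(self):
        assert entropy([200, 0, 0, 0, 0]) == 0.0

    def test_uniform_binary(self):
        assert entropy([100, 100]) == pytest.approx(1.0)

    def test_uniform_five_classes(self):
        assert entropy([200] * 5) == pytest.approx(math.log2(5))

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            entropy([0, 0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 500), min_size=2, max_size=8))
    def test_bounds(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        h = entropy(counts)
        nonzero = sum(1 for c in counts if c > 0)
        assert 0.0 <= h <= math.log2(max(nonzero, 1)) + 1e-12


class TestEvaluateSplit:
    def test_toy_table(self):
        # values 1..6, classes AAABBB, threshold 3.5: a clean 1-bit split.
        X = np.arange(1, 7, dtype=float)[:, None]
        y = np.array([0, 0, 0, 1, 1, 1])
        cand = evaluate_split(X, y, 2, 1, 3.5)
        assert cand.gain == pytest.approx(1.0)
        assert cand.split_info == pytest.approx(1.0)
        assert cand.gain_ratio == pytest.approx(1.0)

    def test_perfect_separation_gain_equals_parent_entropy(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1], [5.2]])
        y = np.array([0, 0, 1, 1, 1])
        cand = evaluate_split(X, y, 2, 1, 2.5)
        assert cand.gain == pytest.approx(entropy([2, 3]))

    def test_non_splitting_threshold_returns_none(self):
        X = np.array([[1.0], [2.0]])
        assert evaluate_split(X, np.array([0, 1]), 2, 1, 5.0) is None

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_purity(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_dataset(rng, 30, 3, 3)
        cand = best_split(X, y, 3, InductionParams())
        if cand is None:
            return
        parent_h = entropy(np.bincount(y, minlength=3))
        assert parent_h - cand.gain <= parent_h + 1e-12
        assert cand.gain >= 0.0


class TestBestSplit:
    def test_single_class_node(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        assert best_split(X, np.zeros(10, dtype=np.intp), 2) is None

    def test_toy_table_choice(self):
        X = np.arange(1, 7, dtype=float)[:, None]
        y = np.array([0, 0, 0, 1, 1, 1])
        cand = best_split(X, y, 2)
        assert cand.attribute_index == 1
        assert cand.threshold == pytest.approx(3.5)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(6, 31))
        X, y = random_dataset(rng, m, int(rng.integers(1, 6)), 3)
        params = InductionParams(use_average_gain_guard=False)
        got = best_split(X, y, 3, params)
        want = exhaustive_best_split(X, y, 3)
        if want is None:
            assert got is None
        else:
            assert got.attribute_index == want.attribute_index
            assert got.threshold == pytest.approx(want.threshold, abs=1e-12)
            assert got.gain_ratio == pytest.approx(want.gain_ratio, abs=1e-9)
            assert got.gain == pytest.approx(want.gain, abs=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_average_gain_guard(self, seed):
        # The chosen candidate's gain reaches the mean positive gain.
        rng = np.random.default_rng(seed)
        X, y = random_dataset(rng, 24, 3, 3)
        cand = best_split(X, y, 3, InductionParams(use_average_gain_guard=True))
        if cand is None:
            return
        gains = []
        for j in range(X.shape[1]):
            values = np.unique(X[:, j])
            for lo, hi in zip(values[:-1], values[1:]):
                t = 0.5 * (lo + hi)
                nl = int(np.sum(X[:, j] <= t))
                if nl < 2 or X.shape[0] - nl < 2:
                    continue
                c = evaluate_split(X, y, 3, j + 1, t)
                if c is not None and c.gain > 1e-12:
                    gains.append(c.gain)
        assert cand.gain >= np.mean(gains) - 1e-9


class TestInduce:
    def test_separable_two_class_depth_one(self):
        X = np.array([[0.0], [0.2], [0.4], [5.0], [5.2], [5.4]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        tree = induce(X, y, ("a", "b"))
        assert tree_stats(tree) == (3, 2, 1)

    def test_separable_synthetic_dataset_resubstitutes_perfectly(self, zero_noise_dataset):
        tree = induce(
            zero_noise_dataset.X,
            zero_noise_dataset.y,
            zero_noise_dataset.class_names,
            attribute_names=zero_noise_dataset.attribute_names,
        )
        predictions = tree.predict(zero_noise_dataset.X)
        assert np.all(predictions == zero_noise_dataset.y)

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_leaf_decision_identity(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_dataset(rng, 40, 3, 3, informative=bool(seed % 2))
        tree = induce(X, y, ("a", "b", "c"))
        n_nodes, n_leaves, n_decision = tree_stats(tree)
        assert n_nodes == n_leaves + n_decision
        assert n_leaves == n_decision + 1

    def test_induction_is_deterministic(self, small_noisy_dataset):
        ds = small_noisy_dataset
        t1 = induce(ds.X, ds.y, ds.class_names, attribute_names=ds.attribute_names)
        t2 = induce(ds.X, ds.y, ds.class_names, attribute_names=ds.attribute_names)
        assert t1.to_json() == t2.to_json()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            induce(np.empty((0, 3)), np.empty(0), ("a",))


def make_leaf(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return TreeNode(counts=counts, klass=int(np.argmax(counts)))


def make_stump(counts_left, counts_right, attr=1, threshold=0.0):
    left, right = make_leaf(counts_left), make_leaf(counts_right)
    parent = TreeNode(
        counts=left.counts + right.counts,
        attribute_index=attr,
        threshold=threshold,
        left=left,
        right=right,
    )
    return DecisionTree(parent, ("a", "b"), ("a1",), InductionParams())


class TestUpperErrorBound:
    @pytest.mark.parametrize(
        "errors, n, cf", [(0, 10, 0.25), (1, 10, 0.25), (3, 20, 0.25), (2, 8, 0.1)]
    )
    def test_matches_binomial_inversion(self, errors, n, cf):
        # Independent oracle: invert P(Bin(n, p) <= errors) = cf by bisection.
        got = upper_error_bound(errors, n, cf)
        want = optimize.brentq(
            lambda p: stats.binom.cdf(errors, n, p) - cf, 1e-12, 1 - 1e-12
        )
        assert got == pytest.approx(want, abs=1e-9)

    def test_zero_errors_closed_form(self):
        # U(0, n) = 1 - CF**(1/n)
        assert upper_error_bound(0, 16, 0.25) == pytest.approx(1 - 0.25 ** (1 / 16))

    def test_saturated_node(self):
        assert upper_error_bound(5, 5, 0.25) == 1.0


class TestPrune:
    def test_children_with_same_class_always_collapsed(self):
        tree = make_stump([5, 1], [7, 2])  # both leaves predict class 'a'
        pruned = prune(tree, 0.25)
        assert pruned.root.is_leaf
        assert pruned.root.klass == 0

    def test_replacement_matches_hand_binomial_computation(self):
        # Parent: 10 instances, 1 error as a leaf.  Children: (6,0) pure and
        # (3,1).  Replacement happens iff 10*U(1,10) <= 6*U(0,6) + 4*U(1,4).
        tree = make_stump([6, 0], [3, 1])
        cf = 0.25
        leaf_errors = 10 * upper_error_bound(1, 10, cf)
        subtree_errors = 6 * upper_error_bound(0, 6, cf) + 4 * upper_error_bound(1, 4, cf)
        pruned = prune(tree, cf)
        assert pruned.root.is_leaf == (leaf_errors <= subtree_errors + 1e-9)

    def test_deep_confidence_prunes_no_more_than_default(self, small_noisy_dataset):
        # As CF -> 1 the upper bound approaches the observed error rate, so
        # pruning weakens; CF 0.99 must keep at least what CF 0.25 keeps.
        ds = small_noisy_dataset
        tree = induce(ds.X, ds.y, ds.class_names, attribute_names=ds.attribute_names)
        n_full = tree_stats(tree)[0]
        n_high = tree_stats(prune(tree, 0.99))[0]
        n_default = tree_stats(prune(tree, 0.25))[0]
        assert n_default <= n_high <= n_full

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_never_increases_node_count(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_dataset(rng, 60, 3, 3, informative=False)
        tree = induce(X, y, ("a", "b", "c"))
        assert tree_stats(prune(tree, 0.25))[0] <= tree_stats(tree)[0]

    def test_invalid_confidence_factor(self):
        tree = make_stump([3, 0], [0, 3])
        with pytest.raises(ValueError):
            prune(tree, 1.5)


class TestPredictAndRules:
    def make_wavelength_stump(self):
        # Depth-1 tree on a851 with the classic threshold rendering.
        left = TreeNode(counts=np.array([0, 5]), klass=1)
        right = TreeNode(counts=np.array([4, 0]), klass=0)
        root = TreeNode(
            counts=np.array([4, 5]),
            attribute_index=851,
            threshold=1541.107862,
            left=left,
            right=right,
        )
        names = tuple(f"a{i}" for i in range(1, 1031))
        return DecisionTree(root, ("hay", "ryegrass"), names, InductionParams())

    def test_predict_low_wavelength_goes_left(self):
        tree = self.make_wavelength_stump()
        x = np.full(1030, 1600.0)
        x[850] = 1541.10
        assert predict(tree, x) == "ryegrass"

    def test_threshold_tie_goes_left(self):
        tree = self.make_wavelength_stump()
        x = np.full(1030, 1600.0)
        x[850] = 1541.107862
        assert predict(tree, x) == "ryegrass"

    def test_leaf_only_tree_is_constant(self):
        tree = DecisionTree(make_leaf([1, 9]), ("a", "b"), ("a1",), InductionParams())
        X = np.random.default_rng(0).normal(size=(7, 1))
        assert np.all(predict(tree, X) == "b")

    def test_missing_attribute_rejected(self):
        tree = self.make_wavelength_stump()
        with pytest.raises(ValueError, match="a851"):
            predict(tree, np.zeros((2, 100)))

    def test_rule_rendering(self):
        tree = self.make_wavelength_stump()
        rules = extract_rules(tree)
        assert len(rules) == 2
        assert rules[0] == "IF (a851 <= 1541.107862) THEN ryegrass"
        assert rules[1] == "IF (a851 > 1541.107862) THEN hay"

    def test_rules_partition_instances(self, small_noisy_dataset):
        ds = small_noisy_dataset
        tree = prune(
            induce(ds.X, ds.y, ds.class_names, attribute_names=ds.attribute_names)
        )
        rules = extract_rules(tree)
        assert len(rules) == tree_stats(tree)[1]
        rng = np.random.default_rng(0)
        rows = ds.X[rng.integers(0, ds.m, size=100)]
        name_to_col = {n: i for i, n in enumerate(ds.attribute_names)}
        for row in rows:
            matched = 0
            for rule in rules:
                body, _, _ = rule.partition(" THEN ")
                conditions = body[3:].split(" AND ")
                ok = True
                for cond in conditions:
                    cond = cond.strip("()")
                    if cond == "TRUE":
                        continue
                    if " <= " in cond:
                        name, value = cond.split(" <= ")
                        ok &= row[name_to_col[name]] <= float(value)
                    else:
                        name, value = cond.split(" > ")
                        ok &= row[name_to_col[name]] > float(value)
                matched += ok
            assert matched == 1


class TestTreeStats:
    def test_single_leaf(self):
        tree = DecisionTree(make_leaf([3, 1]), ("a", "b"), ("a1",), InductionParams())
        assert tree_stats(tree) == (1, 1, 0)

    def test_depth_one(self):
        assert tree_stats(make_stump([3, 0], [0, 3])) == (3, 2, 1)


def test_json_round_trip(small_noisy_dataset):
    ds = small_noisy_dataset
    tree = prune(induce(ds.X, ds.y, ds.class_names, attribute_names=ds.attribute_names))
    back = DecisionTree.from_json(tree.to_json())
    assert tree_stats(back) == tree_stats(tree)
    assert np.all(back.predict(ds.X) == tree.predict(ds.X))
    assert json.loads(back.to_json()) == json.loads(tree.to_json())
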
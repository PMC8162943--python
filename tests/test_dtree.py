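"""Entropy, information gain, and greedy tree fitting against brute force."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mopflow import (
    REACTIVE,
    UNREACTIVE,
    FeatureMatrix,
    LabeledDataset,
    TreeConfig,
    entropy,
    fit_tree,
    information_gain,
    predict_tree,
)
from mopflow.dtree import TreeNode, tree_bits, tree_depth


def oracle_entropy(counts):
    """Independent direct evaluation of -sum p log2 p."""
    total = sum(counts)
    return -sum(c / total * math.log2(c / total) for c in counts if c > 0)


def make_dataset(X, y):
    X = np.asarray(X, dtype=np.uint8)
    y = np.asarray(y, dtype=np.int8)
    fm = FeatureMatrix(
        bits=X, radius=1, row_ids=[str(i) for i in range(X.shape[0])], bit_env={}
    )
    return LabeledDataset(features=fm, labels=y, cutoff=50.0, ratios=y * 90.0 + 5.0)


def oracle_best_split(X, y, min_leaf):
    """Exhaustive argmax-IG over all columns; ties to the lowest index."""
    best = None
    for col in range(X.shape[1]):
        mask = X[:, col] == 1
        n1, n0 = int(mask.sum()), int((~mask).sum())
        if n1 < min_leaf or n0 < min_leaf:
            continue
        parent = [int(y.sum()), int(y.size - y.sum())]
        c1 = [int(y[mask].sum()), int(n1 - y[mask].sum())]
        c0 = [int(y[~mask].sum()), int(n0 - y[~mask].sum())]
        ig = (
            oracle_entropy(parent)
            - n1 / y.size * oracle_entropy(c1)
            - n0 / y.size * oracle_entropy(c0)
        )
        if ig > 1e-12 and (best is None or ig > best[1] + 1e-12):
            best = (col, ig)
    return best


class TestEntropy:
    def test_balanced_binary_is_one_bit(self):
        assert entropy((5, 5)) == pytest.approx(1.0, abs=1e-12)

    def test_pure_set_is_zero(self):
        assert entropy((10, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_training_split(self):
        # 8 reactive vs 28 unreactive analytes
        assert entropy((8, 28)) == pytest.approx(oracle_entropy((8, 28)), abs=1e-12)
        assert entropy((8, 28)) == pytest.approx(0.7642, abs=5e-5)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            entropy((0, 0))

    @given(st.integers(0, 50), st.integers(0, 50))
    @settings(deadline=None, derandomize=True)
    def test_bounded_by_one_bit(self, a, b):
        if a + b == 0:
            return
        assert 0.0 <= entropy((a, b)) <= 1.0 + 1e-12


class TestInformationGain:
    def test_perfect_split_recovers_parent_entropy(self):
        assert information_gain((4, 4), [(4, 0), (0, 4)]) == pytest.approx(1.0)

    def test_proportional_split_gains_nothing(self):
        assert information_gain((6, 3), [(4, 2), (2, 1)]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_formula_on_training_counts(self):
        got = information_gain((8, 28), [(7, 1), (1, 27)])
        want = (
            oracle_entropy((8, 28))
            - 8 / 36 * oracle_entropy((7, 1))
            - 28 / 36 * oracle_entropy((1, 27))
        )
        assert got == pytest.approx(want, abs=1e-12)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            information_gain((4, 4), [(3, 0), (0, 4)])

    @given(
        st.integers(1, 20), st.integers(1, 20), st.integers(0, 20), st.integers(0, 20)
    )
    @settings(deadline=None, derandomize=True)
    def test_never_negative(self, a, b, c, d):
        c, d = min(c, a), min(d, b)
        if (c + d == 0) or (a - c + b - d == 0):
            return
        assert information_gain((a, b), [(c, d), (a - c, b - d)]) >= -1e-12


class TestFitTree:
    def test_perfect_feature_gives_depth_one_tree(self):
        X = np.array([[1, 0], [1, 1], [0, 0], [0, 1], [1, 0], [0, 1]])
        y = X[:, 0]
        tree = fit_tree(make_dataset(X, y), TreeConfig(feature_subset_size="all"))
        assert tree.split_bit == 0
        assert tree_depth(tree) == 1
        for i in range(6):
            assert predict_tree(tree, X[i])[0] == y[i]

    def test_constant_labels_yield_single_leaf(self):
        X = np.eye(4, dtype=np.uint8)
        tree = fit_tree(make_dataset(X, np.ones(4)), TreeConfig(feature_subset_size="all"))
        assert tree.is_leaf
        assert tree.majority_class == REACTIVE

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            fit_tree(make_dataset(np.zeros((0, 3)), np.zeros(0)))

    def test_min_leaf_size_two_forbids_singleton_leaves(self, labeled):
        tree = fit_tree(labeled, TreeConfig(min_leaf_size=2, feature_subset_size="all"))

        def leaves(node):
            if node.is_leaf:
                yield node
            else:
                yield from leaves(node.absent)
                yield from leaves(node.present)

        assert all(n.n_reactive + n.n_unreactive >= 2 for n in leaves(tree))

    def test_children_counts_sum_to_parent(self, labeled):
        tree = fit_tree(labeled, TreeConfig(feature_subset_size="all"))

        def check(node):
            if node.is_leaf:
                return
            assert node.absent.n_reactive + node.present.n_reactive == node.n_reactive
            assert (
                node.absent.n_unreactive + node.present.n_unreactive
                == node.n_unreactive
            )
            check(node.absent)
            check(node.present)

        check(tree)

    def test_no_bit_repeats_on_any_path(self, labeled):
        tree = fit_tree(labeled, TreeConfig(feature_subset_size="all"))

        def walk(node, seen):
            if node.is_leaf:
                return
            assert node.split_bit not in seen
            walk(node.absent, seen | {node.split_bit})
            walk(node.present, seen | {node.split_bit})

        walk(tree, set())

    def test_deterministic_without_subsetting_or_resampling(self, labeled):
        a = fit_tree(labeled, TreeConfig(feature_subset_size="all"))
        b = fit_tree(labeled, TreeConfig(feature_subset_size="all"))
        assert a.to_json() == b.to_json()

    def test_greedy_splits_match_exhaustive_search(self):
        """Every internal node's split equals brute-force argmax IG (spot run;
        the full 200-dataset sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n, m = rng.integers(4, 9), rng.integers(2, 7)
            X = rng.integers(0, 2, size=(n, m)).astype(np.uint8)
            y = rng.integers(0, 2, size=n).astype(np.int8)
            tree = fit_tree(make_dataset(X, y), TreeConfig(feature_subset_size="all"))
            assert_greedy_matches_oracle(tree, X, y, min_leaf=2)

    def test_max_depth_limits_tree(self, labeled):
        tree = fit_tree(labeled, TreeConfig(max_depth=1, feature_subset_size="all"))
        assert tree_depth(tree) <= 1

    def test_json_round_trip(self, labeled):
        tree = fit_tree(labeled, TreeConfig(feature_subset_size="all"))
        assert TreeNode.from_json(tree.to_json()).to_json() == tree.to_json()


def assert_greedy_matches_oracle(tree, X, y, min_leaf):
    """Walk the fitted tree, re-deriving each split with the brute-force oracle."""
    stack = [(tree, np.arange(len(y)))]
    while stack:
        node, idx = stack.pop()
        want = oracle_best_split(X[idx], y[idx], min_leaf)
        if node.is_leaf:
            pure = y[idx].min() == y[idx].max()
            assert want is None or pure or len(idx) < 2 * min_leaf
            continue
        assert want is not None
        assert node.split_bit == want[0]
        mask = X[idx, node.split_bit] == 1
        stack.append((node.present, idx[mask]))
        stack.append((node.absent, idx[~mask]))


class TestPredictTree:
    def test_pure_leaf_probability(self):
        X = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        y = np.array([1, 1, 0, 0])
        tree = fit_tree(make_dataset(X, y), TreeConfig(feature_subset_size="all"))
        cls, prob = predict_tree(tree, np.array([1]))
        assert (cls, prob) == (REACTIVE, 1.0)

    def test_all_zero_row_follows_absent_path(self, labeled):
        tree = fit_tree(labeled, TreeConfig(feature_subset_size="all"))
        node = tree
        while not node.is_leaf:
            node = node.absent
        cls, _ = predict_tree(tree, np.zeros(labeled.features.n_bits))
        assert cls == node.majority_class

    def test_width_mismatch_errors(self, labeled):
        tree = fit_tree(labeled, TreeConfig(feature_subset_size="all"))
        with pytest.raises(ValueError):
            predict_tree(tree, np.zeros(3), n_bits=labeled.features.n_bits)


class TestSklearnCrossCheck:
    def test_agrees_with_sklearn_on_unambiguous_data(self):
        """Independent route: sklearn's entropy tree must reach the same
        training predictions when best splits are unambiguous."""
        sklearn = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(30, 4)).astype(np.uint8)
        y = (X[:, 0] | (X[:, 1] & X[:, 2])).astype(np.int8)
        ds = make_dataset(X, y)
        tree = fit_tree(ds, TreeConfig(min_leaf_size=2, feature_subset_size="all"))
        ours = np.array([predict_tree(tree, x)[0] for x in X])
        ref = sklearn.DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, random_state=0
        ).fit(X, y)
        assert np.array_equal(ours, ref.predict(X))
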
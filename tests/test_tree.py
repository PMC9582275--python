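from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st

import goadf
from goadf.tree import (
    DecisionTree,
    Leaf,
    Split,
    assemble_forest,
    build_tree,
    qc_filter,
)

from conftest import make_matrix


def gini(y):
    if len(y) == 0:
        return 0.0
    p = np.mean(y)
    return 2 * p * (1 - p)


def exhaustive_best_split(X, y, min_leaf=2):
    """Brute force over every (feature, midpoint) pair; first maximizer in
    (feature asc, threshold asc) order."""
    n, f = X.shape
    parent = gini(y)
    best, best_dec = None, 1e-12
    for j in range(f):
        for thr in sorted(set((a + b) / 2
                              for a, b in zip(sorted(set(X[:, j]))[:-1],
                                              sorted(set(X[:, j]))[1:]))):
            left = X[:, j] < thr
            if left.sum() < min_leaf or (~left).sum() < min_leaf:
                continue
            dec = parent - (left.sum() * gini(y[left])
                            + (~left).sum() * gini(y[~left])) / n
            if dec > best_dec + 1e-12:
                best, best_dec = (j, thr), dec
    return best


class TestBuildTree:
    def test_perfect_single_feature_gives_depth_one(self):
        X = np.array([[0.0, 1.0, 2.0, 10.0, 11.0, 12.0],
                      [5.0, 5.1, 4.9, 5.0, 5.2, 4.8]])
        m = make_matrix(X, n_case=3)  # cases have low f0
        tree = build_tree(["f0", "f1"], m)
        assert isinstance(tree.root, Split)
        assert tree.root.feature == "f0"
        assert isinstance(tree.root.left, Leaf) and isinstance(tree.root.right, Leaf)
        pred, _ = tree.predict(m.values)
        assert (pred == m.y).all()

    def test_interaction_toy_uses_both_features(self):
        # neither feature separates alone; greedy growth must combine both
        # (cases first: make_matrix labels the leading columns case)
        X = np.array([
            [0.0, 2.0, 2.0, 0.0, 2.0],   # f0
            [0.0, 2.0, 2.1, 1.0, 3.0],   # f1
        ])
        m = make_matrix(X, n_case=3)
        tree = build_tree(["f0", "f1"], m, min_leaf=1, min_samples_split=2)
        assert set(tree.signature) == {"f0", "f1"}
        pred, _ = tree.predict(m.values)
        assert (pred == m.y).all()
        # root agrees with the exhaustive-split-search oracle
        expected = exhaustive_best_split(X.T, np.array([1, 1, 1, 0, 0]),
                                         min_leaf=1)
        assert tree.root.feature == f"f{expected[0]}"
        assert tree.root.threshold == pytest.approx(expected[1])

    def test_constant_features_yield_single_majority_leaf(self):
        X = np.ones((2, 6))
        m = make_matrix(X, n_case=2)  # 2 case, 4 control
        tree = build_tree(["f0", "f1"], m)
        assert isinstance(tree.root, Leaf)
        assert tree.root.label == 0
        assert tree.signature == []

    def test_leaf_tie_breaks_to_control(self):
        X = np.ones((1, 4))
        m = make_matrix(X, n_case=2)
        tree = build_tree(["f0"], m)
        assert isinstance(tree.root, Leaf)
        assert tree.root.label == 0

    @given(st.integers(0, 60))
    def test_root_split_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        X = rng.normal(size=(n, 2)).round(2)  # coarse grid provokes ties
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        order = np.argsort(-y, kind="stable")
        m = make_matrix(X[order].T, n_case=int(y.sum()))
        tree = build_tree(["f0", "f1"], m, min_samples_split=2)
        expected = exhaustive_best_split(X[order], np.sort(y)[::-1], min_leaf=2)
        if expected is None:
            assert isinstance(tree.root, Leaf)
        else:
            j, thr = expected
            assert isinstance(tree.root, Split)
            assert tree.root.feature == f"f{j}"
            assert tree.root.threshold == pytest.approx(thr)

    def test_boundary_value_routes_right(self):
        tree = DecisionTree(
            "t", Split("f0", 2.0, Leaf(0, 0, 4), Leaf(1, 4, 0)), ["f0"]
        )
        import pandas as pd

        values = pd.DataFrame({"s1": [2.0], "s2": [1.999]}, index=["f0"])
        pred, _ = tree.predict(values)
        assert list(pred) == [1, 0]

    def test_leaf_score_is_case_proportion(self):
        tree = DecisionTree(
            "t", Split("f0", 0.0, Leaf(1, 3, 1), Leaf(0, 1, 3)), ["f0"]
        )
        import pandas as pd

        values = pd.DataFrame({"a": [-1.0], "b": [1.0]}, index=["f0"])
        _, scores = tree.predict(values)
        assert scores == pytest.approx([0.75, 0.25])

    def test_missing_feature_rejected_by_name(self, toy_matrix):
        tree = DecisionTree(
            "t", Split("nope", 0.0, Leaf(0, 0, 1), Leaf(1, 1, 0)), ["nope"]
        )
        with pytest.raises(KeyError, match="nope"):
            tree.predict(toy_matrix.values)

    def test_deterministic_and_training_accuracy_at_purity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3, 24))
        X[0, :12] += 2.5
        m = make_matrix(X, n_case=12)
        t1 = build_tree(["f0", "f1", "f2"], m, min_leaf=1, min_samples_split=2)
        t2 = build_tree(["f0", "f1", "f2"], m, min_leaf=1, min_samples_split=2)
        assert t1.to_dict() == t2.to_dict()
        # growth to purity => perfect training accuracy
        leaves = [n for n in t1._nodes() if isinstance(n, Leaf)]
        assert all(lf.n_case == 0 or lf.n_control == 0 for lf in leaves)
        pred, _ = t1.predict(m.values)
        assert (pred == m.y).all()

    def test_single_class_input_gives_flagged_leaf(self):
        import pandas as pd

        values = pd.DataFrame(
            np.random.default_rng(0).normal(size=(2, 5)),
            index=["f0", "f1"],
            columns=[f"s{i}" for i in range(5)],
        )
        labels = pd.Series([1] * 5, index=values.columns)
        m = goadf.ExpressionMatrix(values, labels)
        tree = build_tree(["f0", "f1"], m)
        assert isinstance(tree.root, Leaf)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(2, 20))
        X[0, :10] += 2
        m = make_matrix(X, n_case=10)
        tree = build_tree(["f0", "f1"], m)
        path = tmp_path / "tree.json"
        tree.save(path)
        again = DecisionTree.load(path)
        assert again.to_dict() == tree.to_dict()
        pred1, s1 = tree.predict(m.values)
        pred2, s2 = again.predict(m.values)
        assert (pred1 == pred2).all() and np.allclose(s1, s2)


def leaf(label=0):
    return Leaf(label, 1, 1)


def chain_tree(tree_id, features):
    """Right-leaning chain using the given features at internal nodes."""
    node = leaf(1)
    for f in reversed(features):
        node = Split(f, 0.0, leaf(0), node)
    return DecisionTree(tree_id, node, list(dict.fromkeys(features)))


class TestForest:
    def test_frequency_counts(self):
        f = assemble_forest([
            chain_tree("t1", ["A", "B", "C"]),
            chain_tree("t2", ["A", "C", "D"]),
        ])
        assert f.freq == {"A": 2, "B": 1, "C": 2, "D": 1}
        assert f.forest_mean_freq == pytest.approx(1.5)

    def test_single_tree(self):
        f = assemble_forest([chain_tree("t1", ["A", "B"])])
        assert f.freq == {"A": 1, "B": 1}

    def test_empty_signature_excluded(self):
        f = assemble_forest([
            DecisionTree("empty", leaf(), []),
            chain_tree("t1", ["A"]),
        ])
        assert f.freq == {"A": 1}

    @given(st.integers(0, 100))
    def test_frequency_conservation_identity(self, seed):
        rng = np.random.default_rng(seed)
        pool = list("ABCDEFG")
        trees = []
        for i in range(int(rng.integers(1, 8))):
            k = int(rng.integers(1, 5))
            feats = list(rng.choice(pool, size=k, replace=False))
            trees.append(chain_tree(f"t{i}", feats))
        f = assemble_forest(trees)
        assert sum(len(t.signature) for t in trees) == sum(f.freq.values())


class FakeStats:
    def __init__(self, single_aucs, accuracy=0.9, sensitivity=0.9,
                 specificity=0.9):
        self.single_aucs = single_aucs
        self.accuracy = accuracy
        self.sensitivity = sensitivity
        self.specificity = specificity


class TestQcFilter:
    def forest(self):
        return assemble_forest([
            chain_tree("good", ["A", "B", "C"]),
            chain_tree("small", ["A", "B"]),
            DecisionTree("dup", Split("A", 0.0, leaf(0),
                                      Split("A", 1.0, leaf(0), leaf(1))), ["A"]),
            chain_tree("weak_auc", ["A", "B", "D"]),
            chain_tree("rare", ["E", "F", "G"]),
            chain_tree("bad_metrics", ["A", "B", "C"]),
        ])

    def stats(self):
        strong = {f: 0.9 for f in "ABCDEFG"}
        return {
            "good": FakeStats(strong),
            "small": FakeStats(strong),
            "dup": FakeStats(strong),
            "weak_auc": FakeStats({"A": 0.9, "B": 0.9, "D": 0.65}),
            "rare": FakeStats(strong),
            "bad_metrics": FakeStats(strong, sensitivity=0.4),
        }

    def test_funnel_rules_and_order(self):
        forest = self.forest()
        survivors, report = qc_filter(forest, self.stats())
        assert [t.tree_id for t in survivors] == ["good"]
        assert report.failures["small"] == "size<3"
        assert report.failures["dup"] == "duplicate-feature"
        assert report.failures["weak_auc"] == "min-single-auc"
        assert report.failures["rare"] == "avg-frequency"  # E,F,G freq 1 < mean
        assert report.failures["bad_metrics"] == "metrics"
        assert report.failures["good"] is None

    def test_stage_counts_monotone(self):
        _, report = qc_filter(self.forest(), self.stats())
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_exact_auc_threshold_fails(self):
        forest = assemble_forest([chain_tree("edge", ["A", "B", "C"])])
        stats = {"edge": FakeStats({"A": 0.7, "B": 0.9, "C": 0.9})}
        survivors, report = qc_filter(forest, stats, use_frequency=False)
        assert survivors == []  # strict > 0.7
        assert report.failures["edge"] == "min-single-auc"

    def test_mean_auc_mode(self):
        forest = assemble_forest([chain_tree("edge", ["A", "B", "C"])])
        stats = {"edge": FakeStats({"A": 0.6, "B": 0.9, "C": 0.9})}
        survivors, _ = qc_filter(forest, stats, use_frequency=False,
                                 single_auc_mode="mean")
        assert [t.tree_id for t in survivors] == ["edge"]
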
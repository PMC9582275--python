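"""Binary CART trees over key miRNAs, forest assembly and quality control.

Trees are grown greedily: at every node the (feature, threshold) pair
maximizing the impurity decrease is chosen by exhaustive search over the
midpoints of consecutive sorted unique values.  Conventions are fixed so
growth is fully deterministic: left branch takes ``x < threshold``, right
takes ``x >= threshold``; ties in impurity decrease are broken by lowest
feature index, then lowest threshold; leaf labels are the majority class
with ties going to class 0.  No pruning is applied — growth stops when a
node is pure, too small, or no split improves impurity.

The decision forest is a candidate pool (not a voting ensemble): it records
every tree with the forest-wide frequency of each signature miRNA, and the
QC funnel removes low-quality trees in a fixed stage order.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "Leaf",
    "Split",
    "DecisionTree",
    "DecisionForest",
    "TreeQCReport",
    "build_tree",
    "assemble_forest",
    "qc_filter",
    "QC_STAGES",
]

_MIN_DECREASE = 1e-12


@dataclass
class Leaf:
    label: int
    n_case: int
    n_control: int

    @property
    def score(self) -> float:
        """Case proportion of the training samples routed here."""
        total = self.n_case + self.n_control
        return self.n_case / total if total else 0.5


@dataclass
class Split:
    feature: str
    threshold: float
    left: "Split | Leaf"
    right: "Split | Leaf"


@dataclass
class DecisionTree:
    tree_id: str
    root: Split | Leaf
    feature_names: list[str]
    train_sample_ids: tuple[str, ...] = ()

    # -- structure -------------------------------------------------------
    def _nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if isinstance(node, Split):
                stack.append(node.right)
                stack.append(node.left)

    @property
    def node_features(self) -> list[str]:
        """Features at internal nodes, preorder, with repeats."""
        out = []

        def walk(node):
            if isinstance(node, Split):
                out.append(node.feature)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    @property
    def signature(self) -> list[str]:
        """Ordered distinct features used at internal nodes."""
        seen, sig = set(), []
        for f in self.node_features:
            if f not in seen:
                seen.add(f)
                sig.append(f)
        return sig

    @property
    def has_duplicate_features(self) -> bool:
        feats = self.node_features
        return len(feats) != len(set(feats))

    @property
    def n_leaves(self) -> int:
        return sum(isinstance(n, Leaf) for n in self._nodes())

    # -- prediction ------------------------------------------------------
    def predict(self, values: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Route samples (columns of ``values``) to leaves.

        Returns (labels, scores); the score is the leaf's training case
        proportion, which gives a continuous output usable for ROC curves.
        """
        missing = [f for f in self.signature if f not in values.index]
        if missing:
            raise KeyError(f"samples lack signature feature(s): {missing}")
        labels = np.empty(values.shape[1], dtype=int)
        scores = np.empty(values.shape[1], dtype=float)
        for j, sample in enumerate(values.columns):
            node = self.root
            while isinstance(node, Split):
                x = values.at[node.feature, sample]
                node = node.left if x < node.threshold else node.right
            labels[j] = node.label
            scores[j] = node.score
        return labels, scores

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def enc(node):
            if isinstance(node, Leaf):
                return {
                    "leaf": True,
                    "label": node.label,
                    "n_case": node.n_case,
                    "n_control": node.n_control,
                }
            return {
                "leaf": False,
                "feature": node.feature,
                "threshold": node.threshold,
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return {
            "tree_id": self.tree_id,
            "feature_names": self.feature_names,
            "train_sample_ids": list(self.train_sample_ids),
            "root": enc(self.root),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DecisionTree":
        def dec(node):
            if node["leaf"]:
                return Leaf(node["label"], node["n_case"], node["n_control"])
            return Split(
                node["feature"], node["threshold"],
                dec(node["left"]), dec(node["right"]),
            )

        return cls(
            tree_id=data["tree_id"],
            root=dec(data["root"]),
            feature_names=list(data["feature_names"]),
            train_sample_ids=tuple(data.get("train_sample_ids", ())),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "DecisionTree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _impurity(n_case: int, n_control: int, criterion: str) -> float:
    n = n_case + n_control
    if n == 0:
        return 0.0
    p = n_case / n
    if criterion == "gini":
        return 2.0 * p * (1.0 - p)
    if criterion == "entropy":
        e = 0.0
        for q in (p, 1.0 - p):
            if q > 0:
                e -= q * np.log2(q)
        return e
    raise ValueError(f"unknown criterion {criterion!r}")


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    min_leaf: int,
    criterion: str,
) -> tuple[int, float] | None:
    """Exhaustive search; returns (feature index, threshold) or None.

    Candidate thresholds are midpoints of consecutive distinct sorted
    values.  Only strictly positive impurity decreases are accepted; the
    first maximizer in (feature index asc, threshold asc) order wins ties.
    """
    n, n_features = X.shape
    n_case_tot = int(y.sum())
    parent = _impurity(n_case_tot, n - n_case_tot, criterion)
    best: tuple[int, float] | None = None
    best_dec = _MIN_DECREASE
    for j in range(n_features):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        cum_case = np.cumsum(y[order])
        for i in range(n - 1):
            if xs[i] == xs[i + 1]:
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            c_left = int(cum_case[i])
            imp_l = _impurity(c_left, n_left - c_left, criterion)
            imp_r = _impurity(
                n_case_tot - c_left, n_right - (n_case_tot - c_left), criterion
            )
            dec = parent - (n_left * imp_l + n_right * imp_r) / n
            if dec > best_dec + _MIN_DECREASE:
                best_dec = dec
                best = (j, (xs[i] + xs[i + 1]) / 2.0)
    return best


def build_tree(
    key_features: Sequence[str],
    matrix: ExpressionMatrix,
    *,
    min_leaf: int = 2,
    min_samples_split: int | None = None,
    criterion: str = "gini",
    tree_id: str = "T1",
) -> DecisionTree:
    """Grow a CART tree on the feature-selection samples.

    Single-class input yields a single-leaf tree (it will fail QC later
    rather than raising here).
    """
    if not key_features:
        raise ValueError("key_features is empty")
    if min_samples_split is None:
        min_samples_split = 2 * min_leaf
    features = list(key_features)
    X = matrix.values.loc[features].to_numpy(dtype=float).T  # samples x feats
    y = matrix.y

    def grow(idx: np.ndarray) -> Split | Leaf:
        yi = y[idx]
        n_case = int(yi.sum())
        n_control = len(yi) - n_case
        # majority label, tie -> control (class 0)
        label = 1 if n_case > n_control else 0
        if n_case == 0 or n_control == 0 or len(idx) < min_samples_split:
            return Leaf(label, n_case, n_control)
        found = _best_split(X[idx], yi, min_leaf, criterion)
        if found is None:
            return Leaf(label, n_case, n_control)
        j, thr = found
        mask = X[idx, j] < thr
        return Split(
            features[j], float(thr), grow(idx[mask]), grow(idx[~mask])
        )

    root = grow(np.arange(len(y)))
    return DecisionTree(
        tree_id=tree_id,
        root=root,
        feature_names=features,
        train_sample_ids=tuple(matrix.sample_ids),
    )


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

@dataclass
class DecisionForest:
    """The pooled candidate trees with forest-wide signature frequencies."""

    trees: list[DecisionTree]
    freq: dict[str, int] = field(init=False)
    forest_mean_freq: float = field(init=False)

    def __post_init__(self) -> None:
        counter: Counter[str] = Counter()
        for tree in self.trees:
            counter.update(tree.signature)  # empty signatures contribute nothing
        self.freq = dict(counter)
        self.forest_mean_freq = (
            float(np.mean(list(self.freq.values()))) if self.freq else 0.0
        )

    def tree_mean_freq(self, tree: DecisionTree) -> float:
        """Mean forest-wide frequency of the tree's signature features."""
        sig = tree.signature
        if not sig:
            return 0.0
        return float(np.mean([self.freq[f] for f in sig]))


def assemble_forest(trees: Sequence[DecisionTree]) -> DecisionForest:
    if not trees:
        raise ValueError("cannot assemble a forest from zero trees")
    return DecisionForest(list(trees))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

QC_STAGES = (
    "duplicate-feature",
    "size<3",
    "min-single-auc",
    "avg-frequency",
    "metrics",
)


@dataclass
class TreeQCReport:
    """Per-tree first failing rule (None = pass) and the stage funnel."""

    failures: dict[str, str | None]
    stage_counts: dict[str, int]

    @property
    def survivors(self) -> list[str]:
        return [t for t, rule in self.failures.items() if rule is None]


def qc_filter(
    forest: DecisionForest,
    tree_stats: Mapping[str, "object"],
    *,
    single_auc_threshold: float = 0.7,
    metric_threshold: float = 0.5,
    min_features: int = 3,
    single_auc_mode: str = "min",
    use_frequency: bool = True,
) -> tuple[list[DecisionTree], TreeQCReport]:
    """Sequential QC funnel over the forest.

    Stages, in order: (1) drop trees with a duplicated feature or fewer
    than ``min_features`` signature miRNAs; (2) keep trees whose signature
    features' single-miRNA AUCs on the feature-evaluation samples exceed
    ``single_auc_threshold`` (``single_auc_mode`` = "min" requires every
    feature to pass, "mean" the average); (3) keep trees whose mean
    forest-wide signature frequency strictly exceeds the forest mean;
    (4) keep trees with accuracy, sensitivity and specificity each above
    ``metric_threshold``.

    ``tree_stats`` maps tree_id to an object exposing ``single_aucs``
    (mapping feature -> AUC), ``accuracy``, ``sensitivity``,
    ``specificity`` for the tree's feature-evaluation samples.
    """
    failures: dict[str, str | None] = {}
    stage_counts = {"input": len(forest.trees)}
    alive = []
    for tree in forest.trees:
        if tree.has_duplicate_features:
            failures[tree.tree_id] = "duplicate-feature"
        elif len(tree.signature) < min_features:
            failures[tree.tree_id] = "size<3"
        else:
            alive.append(tree)
    stage_counts["structure"] = len(alive)

    kept = []
    for tree in alive:
        stats = tree_stats[tree.tree_id]
        aucs = [stats.single_aucs[f] for f in tree.signature]
        value = min(aucs) if single_auc_mode == "min" else float(np.mean(aucs))
        if value > single_auc_threshold:
            kept.append(tree)
        else:
            failures[tree.tree_id] = "min-single-auc"
    alive = kept
    stage_counts["single_auc"] = len(alive)

    if use_frequency:
        kept = []
        for tree in alive:
            if forest.tree_mean_freq(tree) > forest.forest_mean_freq:
                kept.append(tree)
            else:
                failures[tree.tree_id] = "avg-frequency"
        alive = kept
    stage_counts["frequency"] = len(alive)

    kept = []
    for tree in alive:
        stats = tree_stats[tree.tree_id]
        ok = all(
            getattr(stats, m) > metric_threshold
            for m in ("accuracy", "sensitivity", "specificity")
        )
        if ok:
            kept.append(tree)
            failures[tree.tree_id] = None
        else:
            failures[tree.tree_id] = "metrics"
    alive = kept
    stage_counts["metrics"] = len(alive)

    return alive, TreeQCReport(failures, stage_counts)
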
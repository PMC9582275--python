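"""Classification metrics for single miRNAs and synergistic tree panels.

AUC is the Mann-Whitney rank statistic (ties count 0.5) with the case
class positive and no score flipping, so values below 0.5 are reported
as-is.  Confidence intervals come from stratified percentile bootstrap.
The module also hosts the comparator feature selectors/classifiers used to
benchmark the decision-forest pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix
from .tree import DecisionTree, build_tree

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "ClassificationMetrics",
    "TreeEvalStats",
    "auc",
    "metrics",
    "evaluate_tree",
    "comparators",
    "COMPARATOR_METHODS",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int


@dataclass(frozen=True)
class ClassificationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    f_measure: float


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(scores)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc(
    scores,
    labels,
    n_boot: int = 0,
    seed: int | np.random.SeedSequence | None = None,
) -> RocResult:
    """Rank-based AUC with optional stratified bootstrap 95% CI.

    The case class (label 1) is positive; tied scores contribute 0.5 per
    pair, so identical scores give exactly 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    a = _rank_auc(scores, y)
    lo = hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        case_idx = np.nonzero(y == 1)[0]
        ctrl_idx = np.nonzero(y == 0)[0]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate([
                rng.choice(case_idx, size=n1, replace=True),
                rng.choice(ctrl_idx, size=n0, replace=True),
            ])
            reps[b] = _rank_auc(scores[idx], y[idx])
        lo, hi = np.percentile(reps, [2.5, 97.5])
    return RocResult(a, float(lo), float(hi), n1, n0)


def metrics(predictions, labels) -> ClassificationMetrics:
    """Confusion-table metrics; F-measure is 0 (with a warning) when no
    positive prediction exists."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if not set(np.unique(pred)) <= {0, 1}:
        raise ValueError("predictions must be in {0, 1}")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    if tp + fp == 0:
        warnings.warn("no positive predictions; F-measure set to 0", stacklevel=2)
        f = 0.0
    else:
        precision = tp / (tp + fp)
        f = (
            2 * precision * sensitivity / (precision + sensitivity)
            if precision + sensitivity > 0
            else 0.0
        )
    return ClassificationMetrics(
        tp, fp, tn, fn, accuracy, sensitivity, specificity, f
    )


@dataclass
class TreeEvalStats:
    """A tree's performance on one sample set (usually feature-evaluation)."""

    tree_id: str
    single: dict[str, RocResult]
    synergistic: RocResult
    classification: ClassificationMetrics

    @property
    def single_aucs(self) -> dict[str, float]:
        return {f: r.auc for f, r in self.single.items()}

    @property
    def min_single_auc(self) -> float:
        return min(self.single_aucs.values()) if self.single else float("nan")

    @property
    def best_single_auc(self) -> float:
        return max(self.single_aucs.values()) if self.single else float("nan")

    @property
    def synergistic_auc(self) -> float:
        return self.synergistic.auc

    @property
    def accuracy(self) -> float:
        return self.classification.accuracy

    @property
    def sensitivity(self) -> float:
        return self.classification.sensitivity

    @property
    def specificity(self) -> float:
        return self.classification.specificity


def evaluate_tree(
    tree: DecisionTree,
    eval_matrix: ExpressionMatrix,
    *,
    n_boot: int = 0,
    seed=None,
    check_disjoint: bool = True,
) -> TreeEvalStats:
    """Single-feature AUCs (raw expression as score), synergistic AUC
    (leaf case-proportion scores) and confusion metrics on held-out
    samples.

    ``check_disjoint`` enforces that the evaluation samples do not overlap
    the tree's training samples; disable only for external cohorts whose
    sample ids are unrelated to the training cohort.
    """
    if check_disjoint:
        overlap = set(eval_matrix.sample_ids) & set(tree.train_sample_ids)
        if overlap:
            raise ValueError(
                f"evaluation samples overlap training samples: {sorted(overlap)}"
            )
    y = eval_matrix.y
    single = {}
    for f in tree.signature:
        single[f] = auc(
            eval_matrix.values.loc[f].to_numpy(dtype=float), y,
            n_boot=n_boot, seed=seed,
        )
    pred, scores = tree.predict(eval_matrix.values)
    if len(set(scores)) == 1:  # degenerate (e.g. single-leaf) tree
        synergistic = auc(np.zeros_like(scores), y)
    else:
        synergistic = auc(scores, y, n_boot=n_boot, seed=seed)
    return TreeEvalStats(tree.tree_id, single, synergistic, metrics(pred, y))


# ---------------------------------------------------------------------------
# comparator feature selectors / classifiers
# ---------------------------------------------------------------------------

COMPARATOR_METHODS = ("sam", "ttest", "tree", "fisher", "knn")


@dataclass(frozen=True)
class ComparatorResult:
    method: str
    panel: tuple[str, ...]
    roc: RocResult


def _fisher_scores(
    train: np.ndarray, y: np.ndarray, test: np.ndarray, ridge: float
) -> np.ndarray:
    """Fisher linear discriminant projection oriented toward the case class.

    Singular within-class scatter is handled by a ridge on the diagonal.
    """
    m1 = train[y == 1].mean(axis=0)
    m0 = train[y == 0].mean(axis=0)
    d1 = train[y == 1] - m1
    d0 = train[y == 0] - m0
    sw = d1.T @ d1 + d0.T @ d0
    sw += ridge * np.trace(sw) / max(len(sw), 1) * np.eye(len(sw))
    sw += 1e-12 * np.eye(len(sw))
    w = np.linalg.solve(sw, m1 - m0)
    return test @ w


def _select_panel(
    train: ExpressionMatrix, panel_size: int, statistic: str
) -> list[str]:
    from .diffexpr import sam_statistic

    if statistic == "sam":
        d, _ = sam_statistic(train)
        strength = np.abs(d)
    elif statistic == "ttest":
        y = train.y
        X = train.values.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sps.ttest_ind(X[:, y == 1], X[:, y == 0], axis=1, equal_var=False)
        strength = np.nan_to_num(np.abs(res.statistic), nan=0.0)
    else:
        raise ValueError(statistic)
    order = np.argsort(-strength, kind="stable")[:panel_size]
    return [train.feature_ids[i] for i in order]


def comparators(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    panel_size: int = 4,
    method: str = "sam",
    seed=None,
    *,
    k_neighbors: int = 5,
    ridge: float = 1e-6,
) -> ComparatorResult:
    """Benchmark selectors/classifiers reported alongside the pipeline.

    * ``sam`` / ``ttest``: top-``panel_size`` features by statistic
      magnitude, classified with a Fisher linear discriminant score;
    * ``tree``: a single CART over all features, leaf scores on the test set;
    * ``fisher``: Fisher discriminant on the top t-test panel;
    * ``knn``: k-nearest-neighbour (Euclidean) case posterior on the top
      t-test panel.

    Held-out AUC is reported on ``test``.  This mapping reconstructs the
    customary usage of each selector; it is a documented choice, not a
    canonical definition.
    """
    if method not in COMPARATOR_METHODS:
        raise ValueError(f"unknown method {method!r}; use {COMPARATOR_METHODS}")
    if panel_size > train.n_features:
        raise ValueError(
            f"panel_size {panel_size} exceeds {train.n_features} features"
        )
    y_train = train.y
    y_test = test.y

    if method == "tree":
        cart = build_tree(train.feature_ids, train, tree_id="comparator-tree")
        panel = tuple(cart.signature)
        _, scores = cart.predict(test.values.loc[train.feature_ids])
    else:
        stat = "sam" if method == "sam" else "ttest"
        panel_list = _select_panel(train, panel_size, stat)
        panel = tuple(panel_list)
        Xtr = train.values.loc[panel_list].to_numpy(dtype=float).T
        Xte = test.values.loc[panel_list].to_numpy(dtype=float).T
        if method == "knn":
            from sklearn.neighbors import KNeighborsClassifier

            knn = KNeighborsClassifier(
                n_neighbors=min(k_neighbors, len(y_train))
            )
            knn.fit(Xtr, y_train)
            scores = knn.predict_proba(Xte)[:, list(knn.classes_).index(1)]
        else:  # sam / ttest / fisher all score with the Fisher discriminant
            scores = _fisher_scores(Xtr, y_train, Xte, ridge)
    return ComparatorResult(method, panel, auc(scores, y_test))
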
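"""End-to-end orchestration: resampling -> per-set differential expression
-> tree growth -> forest assembly -> QC -> entropy-weight ranking ->
held-out evaluation, plus label-shuffle significance.

All randomness flows from the master seed: repeat r of the split plan uses
the stream (seed, r) and the SAM permutations of each feature-selection set
use the stream (seed, repeat, outer, inner, 7), so any set can be
reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffexpr import cluster_coexpressed, sam_test, ttest_select
from .entropy import (
    DEFAULT_FACTORS,
    EntropyWeights,
    FactorMatrix,
    TreeScore,
    column_entropies,
    entropy_weights,
    score_trees,
    standardize,
)
from .evaluation import TreeEvalStats, evaluate_tree
from .io import ExpressionMatrix
from .sampling import (
    FeatureSelectionSetRef,
    enumerate_feature_selection_sets,
    make_split_plans,
)
from .tree import (
    DecisionForest,
    DecisionTree,
    TreeQCReport,
    assemble_forest,
    build_tree,
    qc_filter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "TreeRecord",
    "RunReport",
    "run_goadf",
    "evaluate_external",
    "permutation_null",
    "PermutationNullResult",
]


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults."""

    n_outer: int = 5
    n_inner: int = 4
    repeats: int = 100
    sam_p: float = 0.05
    sam_perms: int = 500
    pcc_r: float = 0.6
    pcc_p: float = 0.05
    pcc_abs: bool = False
    ttest_p: float = 0.01
    ttest_equal_var: bool = False
    qc_single_auc: float = 0.7
    qc_metric: float = 0.5
    qc_min_features: int = 3
    qc_single_auc_mode: str = "min"
    qc_use_frequency: bool = True
    min_leaf: int = 2
    min_samples_split: int = 20
    criterion: str = "gini"
    n_shuffles: int = 1000
    seed: int = 0

    def validate(self) -> "RunConfig":
        for name in ("sam_p", "pcc_p", "ttest_p", "qc_single_auc", "qc_metric"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        return self


@dataclass
class TreeRecord:
    """Provenance of one feature-selection set's tree (possibly empty)."""

    ref: FeatureSelectionSetRef
    de_features: list[str] = field(default_factory=list)
    key_features: list[str] = field(default_factory=list)
    tree: DecisionTree | None = None
    eval_stats: TreeEvalStats | None = None

    @property
    def is_empty(self) -> bool:
        return self.tree is None


@dataclass
class RunReport:
    config: RunConfig
    records: list[TreeRecord]
    forest: DecisionForest | None
    qc_report: TreeQCReport | None
    factor_matrix: FactorMatrix | None
    weights: EntropyWeights | None
    ranking: list[TreeScore]
    top_tree: DecisionTree | None
    top_eval_stats: TreeEvalStats | None
    top_test_stats: TreeEvalStats | None
    advisory: str | None = None

    @property
    def funnel(self) -> dict[str, int]:
        counts = {
            "feature_selection_sets": len(self.records),
            "trees_built": sum(not r.is_empty for r in self.records),
        }
        if self.qc_report is not None:
            counts.update(
                {f"qc_{k}": v for k, v in self.qc_report.stage_counts.items()}
            )
        return counts

    def ranking_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(ts.tree_id, ts.st) for ts in self.ranking],
            columns=["tree_id", "st"],
        )


def _sam_seed(config: RunConfig, ref: FeatureSelectionSetRef):
    return np.random.SeedSequence(
        config.seed,
        spawn_key=(ref.repeat_index, ref.outer_fold_index, ref.inner_fold_index, 7),
    )


def _process_ref(
    matrix: ExpressionMatrix, ref: FeatureSelectionSetRef, config: RunConfig
) -> TreeRecord:
    record = TreeRecord(ref)
    fs = matrix.subset_samples(ref.feature_selection)
    y = fs.y
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        return record  # degenerate split: explicit empty record
    sam = sam_test(
        fs, n_perm=config.sam_perms, alpha=config.sam_p, seed=_sam_seed(config, ref)
    )
    record.de_features = [r.feature_id for r in sam if r.de]
    if not record.de_features:
        return record
    sets = cluster_coexpressed(
        record.de_features, fs, config.pcc_r, config.pcc_p, config.pcc_abs
    )
    keys: list[str] = []
    for cs in sets:
        keys.extend(
            ttest_select(cs, fs, config.ttest_p, config.ttest_equal_var).key_members
        )
    record.key_features = keys
    if not keys:
        return record
    record.tree = build_tree(
        keys,
        fs,
        min_leaf=config.min_leaf,
        min_samples_split=config.min_samples_split,
        criterion=config.criterion,
        tree_id=ref.set_id,
    )
    record.eval_stats = evaluate_tree(
        record.tree, matrix.subset_samples(ref.feature_evaluation)
    )
    return record


def _empty_report(config, records, forest, qc, advisory) -> RunReport:
    logger.warning("%s", advisory)
    return RunReport(
        config, records, forest, qc, None, None, [], None, None, None, advisory
    )


def run_goadf(matrix: ExpressionMatrix, config: RunConfig | None = None) -> RunReport:
    """Execute the full pipeline and return a machine-readable report."""
    config = (config or RunConfig()).validate()
    plans = make_split_plans(
        matrix, config.repeats, config.n_outer, config.n_inner, config.seed
    )
    refs = enumerate_feature_selection_sets(plans)
    logger.info("processing %d feature-selection sets", len(refs))
    records = [_process_ref(matrix, ref, config) for ref in refs]

    trees = [r.tree for r in records if r.tree is not None]
    if not trees:
        return _empty_report(
            config, records, None, None,
            "no non-empty trees were built; data may carry no class signal",
        )
    forest = assemble_forest([r.tree for r in records if r.tree is not None])
    stats_by_id = {
        r.tree.tree_id: r.eval_stats for r in records if r.tree is not None
    }
    survivors, qc = qc_filter(
        forest,
        stats_by_id,
        single_auc_threshold=config.qc_single_auc,
        metric_threshold=config.qc_metric,
        min_features=config.qc_min_features,
        single_auc_mode=config.qc_single_auc_mode,
        use_frequency=config.qc_use_frequency,
    )
    logger.info("QC funnel: %s", qc.stage_counts)
    if not survivors:
        return _empty_report(
            config, records, forest, qc,
            "no tree survived quality control (thresholds too strict or "
            "class signal too weak)",
        )

    fm = FactorMatrix(
        tree_ids=[t.tree_id for t in survivors],
        factor_names=list(DEFAULT_FACTORS),
        x=np.array(
            [
                [
                    forest.tree_mean_freq(t),
                    stats_by_id[t.tree_id].synergistic_auc,
                    stats_by_id[t.tree_id].accuracy,
                    stats_by_id[t.tree_id].sensitivity,
                    stats_by_id[t.tree_id].specificity,
                ]
                for t in survivors
            ]
        ),
    )
    # a factor that is zero for every survivor carries no information and
    # cannot be standardized; drop it
    zero_cols = np.nonzero(fm.x.sum(axis=0) == 0)[0]
    if zero_cols.size and zero_cols.size < fm.k:
        dropped = [fm.factor_names[j] for j in zero_cols]
        logger.warning("dropping all-zero factor column(s): %s", dropped)
        keep = [j for j in range(fm.k) if j not in set(zero_cols)]
        fm = FactorMatrix(
            fm.tree_ids, [fm.factor_names[j] for j in keep], fm.x[:, keep]
        )
    if len(survivors) == 1 or fm.x.sum() == 0:
        ranking = [TreeScore(survivors[0].tree_id, float("nan"))]
        weights = None
    else:
        fm = standardize(fm)
        try:
            weights = entropy_weights(column_entropies(fm), fm.factor_names)
        except ValueError:
            # every factor identical across survivors: fall back to equal
            # weights so a top tree can still be reported
            logger.warning("all factors constant; using equal weights")
            k = fm.k
            weights = EntropyWeights(
                list(fm.factor_names), np.ones(k), np.full(k, 1.0 / k)
            )
        ranking = score_trees(fm, weights)

    by_id = {t.tree_id: t for t in survivors}
    rec_by_id = {r.tree.tree_id: r for r in records if r.tree is not None}
    top = by_id[ranking[0].tree_id]
    top_record = rec_by_id[top.tree_id]
    top_test = evaluate_tree(
        top, matrix.subset_samples(top_record.ref.internal_test)
    )
    return RunReport(
        config=config,
        records=records,
        forest=forest,
        qc_report=qc,
        factor_matrix=fm,
        weights=weights,
        ranking=ranking,
        top_tree=top,
        top_eval_stats=top_record.eval_stats,
        top_test_stats=top_test,
    )


def evaluate_external(
    tree: DecisionTree,
    external: ExpressionMatrix,
    *,
    refit: bool = False,
) -> TreeEvalStats:
    """Apply a fitted tree to an independent cohort.

    Default keeps the learned split values fixed (honest external
    validation).  ``refit=True`` regrows the tree on the external cohort
    restricted to the original signature; the refit is logged.
    """
    missing = [f for f in tree.signature if f not in external.values.index]
    if missing:
        raise ValueError(f"external matrix lacks signature feature(s): {missing}")
    if refit:
        logger.info("refitting tree %s on external cohort", tree.tree_id)
        tree = build_tree(
            tree.signature, external, tree_id=f"{tree.tree_id}-refit"
        )
    return evaluate_tree(tree, external, check_disjoint=False)


# ---------------------------------------------------------------------------
# label-shuffle significance
# ---------------------------------------------------------------------------

@dataclass
class PermutationNullResult:
    observed: dict[str, float]
    null: dict[str, np.ndarray]
    p_values: dict[str, float]
    n_shuffles_used: int
    n_no_survivor: int = 0


_NULL_STATS = ("st", "mean_frequency", "synergistic_auc")


def _top_stats(report: RunReport) -> dict[str, float] | None:
    if report.top_tree is None:
        return None
    st = report.ranking[0].st
    return {
        "st": st,
        "mean_frequency": report.forest.tree_mean_freq(report.top_tree),
        "synergistic_auc": report.top_eval_stats.synergistic_auc,
    }


def permutation_null(
    matrix: ExpressionMatrix,
    config: RunConfig,
    n_shuffles: int,
    seed: int | None = None,
) -> PermutationNullResult:
    """Label-shuffle null for the observed top tree.

    Sample labels are shuffled (feature and sample counts unchanged), the
    whole pipeline is rerun per shuffle, and the top tree's ST, signature
    mean frequency and synergistic AUC are collected.  A shuffle whose
    forest does not survive quality control contributes ``-inf`` for every
    statistic — it certainly did not beat the observed tree.  Empirical
    ``p = (1 + #{null >= observed}) / (n_shuffles + 1)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if n_shuffles < 100:
        logger.warning(
            "n_shuffles=%d is small; >= 100 is recommended for stable p-values",
            n_shuffles,
        )
    observed_report = run_goadf(matrix, config)
    observed = _top_stats(observed_report)
    if observed is None:
        raise ValueError("observed run produced no QC-surviving tree")
    rng = np.random.default_rng(seed)
    null: dict[str, list[float]] = {k: [] for k in _NULL_STATS}
    y = matrix.labels.to_numpy()
    for b in range(n_shuffles):
        perm = rng.permutation(len(y))
        shuffled = ExpressionMatrix(
            matrix.values,
            pd.Series(y[perm], index=matrix.labels.index, name="label"),
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        report = run_goadf(matrix=shuffled, config=replace(config, seed=sub_seed))
        stats = _top_stats(report)
        for k in _NULL_STATS:
            null[k].append(stats[k] if stats is not None else -np.inf)
    arrays = {k: np.asarray(v) for k, v in null.items()}
    n_no_survivor = int(np.isneginf(arrays["st"]).sum())
    p_values = {
        k: (1.0 + float((arrays[k] >= observed[k]).sum())) / (n_shuffles + 1.0)
        for k in _NULL_STATS
    }
    return PermutationNullResult(
        observed, arrays, p_values, n_shuffles, n_no_survivor
    )
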
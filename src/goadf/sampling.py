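"""Nested resampling plans: outer k-fold with an inner k'-fold of each
outer-training set, stratified by class and repeated under independent
sub-seeds.

One repeat with 5 outer and 4 inner folds yields 20 feature-selection sets;
each set splits the cohort into three disjoint roles:

* feature_selection — 3 inner blocks (SAM/clustering/t-test + tree growth),
* feature_evaluation — the held-out inner block (tree QC and factor values),
* internal_test — the held-out outer block (final assessment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "SplitPlan",
    "FeatureSelectionSetRef",
    "make_split_plan",
    "make_split_plans",
    "enumerate_feature_selection_sets",
    "write_split_plan",
]


@dataclass(frozen=True)
class FeatureSelectionSetRef:
    """One (repeat, outer fold, inner fold) cell of the resampling plan."""

    repeat_index: int
    outer_fold_index: int  # 1-based
    inner_fold_index: int  # 1-based
    feature_selection: tuple[str, ...]
    feature_evaluation: tuple[str, ...]
    internal_test: tuple[str, ...]

    @property
    def set_id(self) -> str:
        return (
            f"R{self.repeat_index:03d}"
            f"O{self.outer_fold_index}I{self.inner_fold_index}"
        )


@dataclass
class SplitPlan:
    """Outer partition plus the inner partition of each outer-training set."""

    repeat_index: int
    seed: int
    outer_folds: list[list[str]]
    inner_folds: list[list[list[str]]]  # [outer][inner block] -> sample ids

    @property
    def n_outer(self) -> int:
        return len(self.outer_folds)

    @property
    def n_inner(self) -> int:
        return len(self.inner_folds[0])

    @property
    def all_samples(self) -> list[str]:
        return [s for block in self.outer_folds for s in block]


def _stratified_blocks(
    class_groups: Sequence[Sequence[str]],
    n_blocks: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Seeded shuffle per class, then round-robin block assignment
    (remainders land in the earliest blocks)."""
    blocks: list[list[str]] = [[] for _ in range(n_blocks)]
    for group in class_groups:
        perm = list(group)
        rng.shuffle(perm)
        for i, sample in enumerate(perm):
            blocks[i % n_blocks].append(sample)
    return blocks


def make_split_plan(
    matrix: ExpressionMatrix,
    n_outer: int = 5,
    n_inner: int = 4,
    seed: int = 0,
    repeat_index: int = 1,
) -> SplitPlan:
    """Build one stratified nested split plan.

    Reproducible: each repeat consumes an independent stream derived from
    ``(seed, repeat_index)`` so repeats can be regenerated in isolation.
    """
    y = matrix.y
    samples = matrix.sample_ids
    cases = [s for s, yi in zip(samples, y) if yi == 1]
    controls = [s for s, yi in zip(samples, y) if yi == 0]
    for name, group in (("case", cases), ("control", controls)):
        if len(group) < n_outer:
            raise ValueError(
                f"class '{name}' has {len(group)} samples; stratified "
                f"{n_outer}-fold requires at least {n_outer} per class"
            )
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(repeat_index,))
    )
    outer = _stratified_blocks([cases, controls], n_outer, rng)
    inner: list[list[list[str]]] = []
    for f in range(n_outer):
        held = set(outer[f])
        train_cases = [s for s in cases if s not in held]
        train_controls = [s for s in controls if s not in held]
        inner.append(_stratified_blocks([train_cases, train_controls], n_inner, rng))
    return SplitPlan(repeat_index, seed, outer, inner)


def make_split_plans(
    matrix: ExpressionMatrix,
    repeats: int,
    n_outer: int = 5,
    n_inner: int = 4,
    seed: int = 0,
) -> list[SplitPlan]:
    return [
        make_split_plan(matrix, n_outer, n_inner, seed, repeat_index=r)
        for r in range(1, repeats + 1)
    ]


def enumerate_feature_selection_sets(
    plans: Iterable[SplitPlan],
) -> list[FeatureSelectionSetRef]:
    """Emit all (repeat, outer, inner) refs in deterministic order."""
    refs: list[FeatureSelectionSetRef] = []
    for plan in plans:
        for f in range(plan.n_outer):
            test = tuple(plan.outer_folds[f])
            blocks = plan.inner_folds[f]
            for g in range(plan.n_inner):
                selection = tuple(
                    s for h, block in enumerate(blocks) if h != g for s in block
                )
                refs.append(
                    FeatureSelectionSetRef(
                        repeat_index=plan.repeat_index,
                        outer_fold_index=f + 1,
                        inner_fold_index=g + 1,
                        feature_selection=selection,
                        feature_evaluation=tuple(blocks[g]),
                        internal_test=test,
                    )
                )
    return refs


def write_split_plan(plans: Iterable[SplitPlan], path) -> None:
    """Audit table: one row per (repeat, outer fold, sample).

    ``inner_fold`` is the sample's inner block within that outer split, or 0
    when the sample is in the held-out outer (internal test) block.
    """
    rows = []
    for plan in plans:
        for f in range(plan.n_outer):
            for s in plan.outer_folds[f]:
                rows.append((s, plan.repeat_index, f + 1, 0))
            for g, block in enumerate(plan.inner_folds[f]):
                for s in block:
                    rows.append((s, plan.repeat_index, f + 1, g + 1))
    pd.DataFrame(
        rows, columns=["sample_id", "repeat", "outer_fold", "inner_fold"]
    ).to_csv(path, sep="\t", index=False)
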
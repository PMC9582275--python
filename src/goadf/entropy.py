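"""Entropy-weight ranking of QC-surviving trees (Score of Trees, ST).

Each tree i carries k factors x_ij >= 0 (defaults: mean forest frequency of
its signature, synergistic AUC, accuracy, sensitivity, specificity on the
feature-evaluation samples).  Factors are standardized over trees,

    p_ij = x_ij / sum_i x_ij,

each factor's dispersion is summarized by its normalized Shannon entropy

    E_j = -(1 / log2 n) * sum_i p_ij log2 p_ij,        0*log(0) := 0,

low-entropy (high-variation) factors receive high weight

    W_j = (1 - E_j) / (k - sum_j E_j),                 sum_j W_j = 1,

and trees are ranked by the weighted score ST_i = sum_j p_ij W_j in
decreasing order.  A "literal" entropy mode (no sign flip, no normalizer)
and a raw-x scoring mode are exposed for audit; they are not defaults
because they leave E outside [0, 1] and mix incommensurate factor scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_FACTORS",
    "FactorMatrix",
    "EntropyWeights",
    "TreeScore",
    "standardize",
    "entropy",
    "column_entropies",
    "entropy_weights",
    "score_trees",
    "permutation_null",
]

DEFAULT_FACTORS = (
    "mean_frequency",
    "synergistic_auc",
    "accuracy",
    "sensitivity",
    "specificity",
)


@dataclass
class FactorMatrix:
    """Raw factor values x (n_trees x k) and their standardized form p."""

    tree_ids: list[str]
    factor_names: list[str]
    x: np.ndarray
    p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("factor matrix must be 2-dimensional")
        n, k = self.x.shape
        if n != len(self.tree_ids) or k != len(self.factor_names):
            raise ValueError(
                f"shape {self.x.shape} inconsistent with {len(self.tree_ids)} "
                f"trees x {len(self.factor_names)} factors"
            )
        if (self.x < 0).any():
            raise ValueError("factor values must be non-negative")

    @property
    def n_trees(self) -> int:
        return self.x.shape[0]

    @property
    def k(self) -> int:
        return self.x.shape[1]


@dataclass
class EntropyWeights:
    factor_names: list[str]
    E: np.ndarray
    W: np.ndarray


@dataclass(frozen=True)
class TreeScore:
    tree_id: str
    st: float


def standardize(fm: FactorMatrix) -> FactorMatrix:
    """Fill p_ij = x_ij / sum_i x_ij (column-wise over trees)."""
    colsum = fm.x.sum(axis=0)
    zero = np.nonzero(colsum == 0)[0]
    if zero.size:
        names = [fm.factor_names[j] for j in zero]
        raise ValueError(f"all-zero factor column(s): {names}")
    return replace(fm, p=fm.x / colsum)


def entropy(p_col: np.ndarray, mode: str = "normalized") -> float:
    """Shannon entropy of one standardized factor column.

    ``"normalized"`` (default) returns -(1/log2 n) * sum p log2 p in
    [0, 1]; ``"literal"`` returns sum p log2 p without sign or normalizer
    (audit only — it is <= 0 and breaks the weight formula's guarantees).
    """
    p = np.asarray(p_col, dtype=float)
    n = len(p)
    if n < 2:
        raise ValueError("entropy needs at least 2 trees")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("column must be a normalized distribution")
    nz = p[p > 0]  # 0 * log2(0) := 0
    plogp = float(np.sum(nz * np.log2(nz)))
    if mode == "literal":
        return plogp
    if mode == "normalized":
        return -plogp / np.log2(n)
    raise ValueError(f"unknown entropy mode {mode!r}")


def column_entropies(fm: FactorMatrix, mode: str = "normalized") -> np.ndarray:
    if fm.p is None:
        fm = standardize(fm)
    return np.array([entropy(fm.p[:, j], mode) for j in range(fm.k)])


def entropy_weights(
    E: np.ndarray, factor_names: list[str] | None = None
) -> EntropyWeights:
    """W_j = (1 - E_j) / (k - sum E); weights are >= 0 and sum to 1."""
    E = np.asarray(E, dtype=float)
    k = len(E)
    if np.any(E < -1e-12) or np.any(E > 1 + 1e-12):
        raise ValueError("entropies must lie in [0, 1]; use normalized mode")
    denom = k - E.sum()
    if denom <= 1e-12:
        raise ValueError("no discriminating factor: all entropies are 1")
    W = (1.0 - E) / denom
    if factor_names is None:
        factor_names = [f"factor_{j + 1}" for j in range(k)]
    return EntropyWeights(list(factor_names), E, W)


def score_trees(
    fm: FactorMatrix,
    weights: EntropyWeights,
    use_standardized: bool = True,
) -> list[TreeScore]:
    """ST_i = sum_j p_ij * W_j, ranked descending (ties by tree_id)."""
    if list(weights.factor_names) != list(fm.factor_names):
        raise ValueError("weights were computed for different factors")
    if use_standardized:
        if fm.p is None:
            fm = standardize(fm)
        values = fm.p
    else:
        values = fm.x
    st = values @ weights.W
    scored = [TreeScore(t, float(s)) for t, s in zip(fm.tree_ids, st)]
    return sorted(scored, key=lambda ts: (-ts.st, ts.tree_id))


def rank_factor_matrix(
    fm: FactorMatrix, use_standardized: bool = True
) -> tuple[EntropyWeights, list[TreeScore]]:
    """Convenience: standardize, weight and rank in one call."""
    fm = standardize(fm)
    weights = entropy_weights(column_entropies(fm), fm.factor_names)
    return weights, score_trees(fm, weights, use_standardized)


def permutation_null(matrix, config, n_shuffles, seed=None):
    """Label-shuffle significance of the observed top tree; see
    :func:`goadf.pipeline.permutation_null` (re-exported here because the
    null re-runs the full per-set pipeline)."""
    from .pipeline import permutation_null as _impl

    return _impl(matrix, config, n_shuffles, seed)
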
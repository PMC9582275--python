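"""Differential expression and co-expression grouping within one
feature-selection set.

Three stages, applied to the feature-selection samples only:

1. a from-scratch SAM (significance analysis of microarrays) statistic
   ``d = (mean_case - mean_control) / (s + s0)`` with permutation p-values,
2. clustering of the differentially expressed features into co-expression
   sets: connected components of the graph with an edge wherever the
   Pearson correlation exceeds ``r > 0.6`` at ``p < 0.05``,
3. a two-sample t-test (Welch by default) picking the key members of each
   co-expression set at ``p < 0.01``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from itertools import combinations

import numpy as np
from scipy import sparse, stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "CorrelationEdge",
    "SamResult",
    "CoexpressionSet",
    "pearson",
    "sam_statistic",
    "sam_test",
    "cluster_coexpressed",
    "ttest_select",
]


# ---------------------------------------------------------------------------
# Pearson correlation between two profiles
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfile:
    """A single feature's expression vector with its summary moments."""

    feature_id: str
    x: np.ndarray

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def mean(self) -> float:
        return float(np.mean(self.x))

    @property
    def sd(self) -> float:
        """Sample standard deviation (n - 1 denominator)."""
        return float(np.std(self.x, ddof=1))


@dataclass(frozen=True)
class CorrelationEdge:
    feature_a: str
    feature_b: str
    r: float
    p: float


def pearson(a: ExpressionProfile, b: ExpressionProfile) -> CorrelationEdge:
    """Pearson correlation r = (1/(n-1)) sum (x-x̄)(y-ȳ) / (s_x s_y) with a
    two-sided p-value from the t transform on n-2 degrees of freedom."""
    if a.n != b.n:
        raise ValueError(f"profile lengths differ: {a.n} vs {b.n}")
    if a.n < 3:
        raise ValueError("correlation requires n >= 3 samples")
    if a.sd == 0 or b.sd == 0:
        bad = a.feature_id if a.sd == 0 else b.feature_id
        raise ValueError(f"degenerate profile (zero variance): {bad}")
    r, p = stats.pearsonr(a.x, b.x)
    return CorrelationEdge(a.feature_id, b.feature_id, float(r), float(p))


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamResult:
    feature_id: str
    d: float
    s0: float
    p_perm: float
    de: bool


def _diff_and_se(X: np.ndarray, case: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (mean_case - mean_control) and pooled standard error."""
    n1 = int(case.sum())
    n2 = X.shape[1] - n1
    xc = X[:, case]
    xo = X[:, ~case]
    m1 = xc.mean(axis=1)
    m2 = xo.mean(axis=1)
    ss1 = ((xc - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((xo - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return m1 - m2, s


def _choose_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Fudge constant: the percentile of s (0..100 step 5) minimizing the
    coefficient of variation of |d| across features."""
    candidates = np.unique(np.percentile(s, np.arange(0, 101, 5)))
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        denom = s + s0
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
        ad = np.abs(d)
        m = ad.mean()
        if m <= 0:
            continue
        cv = ad.std(ddof=1) / m if len(ad) > 1 else 0.0
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _d_stat(diff: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)


def sam_statistic(
    matrix: ExpressionMatrix, s0: float | None = None
) -> tuple[np.ndarray, float]:
    """Observed SAM d for every feature plus the fudge constant used."""
    X = matrix.values.to_numpy(dtype=float)
    case = matrix.y == 1
    diff, s = _diff_and_se(X, case)
    if s0 is None:
        s0 = _choose_s0(diff, s)
    return _d_stat(diff, s, s0), s0


def _perm_case_indicator(
    n: int, n1: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, B) 0/1 matrix; each column marks a random case assignment."""
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    C = np.zeros((n, n_perm))
    C[order.T, np.arange(n_perm)[None, :].repeat(n1, axis=0)] = 1.0
    return C


def _perm_d(
    X: np.ndarray, C: np.ndarray, s0: float
) -> np.ndarray:
    """d* for every feature (rows) under every case assignment (columns)."""
    n = X.shape[1]
    n1 = int(C[:, 0].sum())
    n2 = n - n1
    X2 = X ** 2
    T = X.sum(axis=1, keepdims=True)
    T2 = X2.sum(axis=1, keepdims=True)
    S1 = X @ C        # per-perm case sums
    Q1 = X2 @ C
    M1 = S1 / n1
    M2 = (T - S1) / n2
    SS1 = Q1 - n1 * M1 ** 2
    SS2 = (T2 - Q1) - n2 * M2 ** 2
    # numerical floor: sums of squares cannot be negative
    np.maximum(SS1, 0.0, out=SS1)
    np.maximum(SS2, 0.0, out=SS2)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (SS1 + SS2) / (n1 + n2 - 2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, (M1 - M2) / np.where(denom > 0, denom, 1.0), 0.0)
    return d


def sam_test(
    matrix: ExpressionMatrix,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | None = None,
    s0: float | None = None,
) -> list[SamResult]:
    """SAM with permutation p-values.

    When the number of distinct case assignments C(n, n_case) does not
    exceed ``n_perm`` all assignments are enumerated and
    ``p = #{|d*| >= |d|} / n_assignments`` (the identity assignment is
    included, so p > 0); otherwise ``n_perm`` label shuffles are sampled and
    ``p = (1 + #{|d*| >= |d|}) / (n_perm + 1)``.  Features with
    ``p < alpha`` are flagged differentially expressed.
    """
    if n_perm < 10:
        raise ValueError(f"n_perm must be >= 10, got {n_perm}")
    X = matrix.values.to_numpy(dtype=float)
    y = matrix.y
    case = y == 1
    n1, n2 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >= 2 samples per class for SAM, got {n1} case / {n2} control"
        )
    n = n1 + n2
    n_assign = comb(n, n1)
    if n_assign < 20:
        warnings.warn(
            f"only {n_assign} distinct label assignments; permutation "
            "p-values are coarse",
            stacklevel=2,
        )
    diff, s = _diff_and_se(X, case)
    if s0 is None:
        s0 = _choose_s0(diff, s)
    d_obs = _d_stat(diff, s, s0)

    # exact ties (identity / label-complement assignments) are compared with
    # a tiny relative slack: |d*| and |d| follow different arithmetic paths
    thresh = np.abs(d_obs)[:, None] * (1.0 - 1e-9) - 1e-12
    if n_assign <= n_perm:  # exhaustive enumeration
        C = np.zeros((n, n_assign))
        for b, idx in enumerate(combinations(range(n), n1)):
            C[list(idx), b] = 1.0
        d_star = _perm_d(X, C, s0)
        count = (np.abs(d_star) >= thresh).sum(axis=1)
        p = count / n_assign
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(X.shape[0], dtype=int)
        batch = 512
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            C = _perm_case_indicator(n, n1, b, rng)
            d_star = _perm_d(X, C, s0)
            count += (np.abs(d_star) >= thresh).sum(axis=1)
            done += b
        p = (1.0 + count) / (n_perm + 1.0)

    return [
        SamResult(f, float(di), float(s0), float(pi), bool(pi < alpha))
        for f, di, pi in zip(matrix.feature_ids, d_obs, p)
    ]


# ---------------------------------------------------------------------------
# co-expression clustering and key-member selection
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionSet:
    """A connected component of the thresholded correlation graph."""

    set_id: str
    members: list[str]
    key_members: list[str] = field(default_factory=list)


def cluster_coexpressed(
    de_features: list[str],
    matrix: ExpressionMatrix,
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
    use_abs: bool = False,
) -> list[CoexpressionSet]:
    """Group differentially expressed features into co-expression sets.

    An edge joins two features when (signed, or absolute with ``use_abs``)
    Pearson r exceeds ``r_threshold`` with two-sided ``p < p_threshold``;
    sets are the connected components, so singletons are allowed and the
    sets partition ``de_features``.
    """
    if not de_features:
        raise ValueError("de_features is empty")
    sub = matrix.values.loc[de_features].to_numpy(dtype=float)
    m, n = sub.shape
    if m == 1:
        return [CoexpressionSet("C1", list(de_features))]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        flat = [f for f, s in zip(de_features, sd) if s == 0]
        logger.warning("zero-variance feature(s) kept as singletons: %s", flat)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(sub)
    r = np.nan_to_num(r, nan=0.0)
    # two-sided p from the t transform, n - 2 df
    rr = np.clip(r, -0.9999999999, 0.9999999999)
    t = rr * np.sqrt((n - 2) / (1.0 - rr ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    strength = np.abs(r) if use_abs else r
    adj = (strength > r_threshold) & (p < p_threshold)
    np.fill_diagonal(adj, False)
    n_comp, labels = sparse.csgraph.connected_components(
        sparse.csr_matrix(adj), directed=False
    )
    sets: list[CoexpressionSet] = []
    seen: dict[int, CoexpressionSet] = {}
    for i, f in enumerate(de_features):  # input order => deterministic ids
        comp = labels[i]
        if comp not in seen:
            cs = CoexpressionSet(f"C{len(sets) + 1}", [])
            seen[comp] = cs
            sets.append(cs)
        seen[comp].members.append(f)
    return sets


def ttest_select(
    cset: CoexpressionSet,
    matrix: ExpressionMatrix,
    p_threshold: float = 0.01,
    equal_var: bool = False,
) -> CoexpressionSet:
    """Fill ``key_members`` with members whose two-sample t-test (case vs
    control; Welch by default) gives ``p < p_threshold``."""
    y = matrix.y
    sub = matrix.values.loc[cset.members].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(
            sub[:, y == 1], sub[:, y == 0], axis=1, equal_var=equal_var
        )
    p = np.nan_to_num(res.pvalue, nan=1.0)  # zero-variance members never pass
    keys = [f for f, pi in zip(cset.members, p) if pi < p_threshold]
    return CoexpressionSet(cset.set_id, list(cset.members), keys)
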
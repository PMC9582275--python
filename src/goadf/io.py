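"""Reading, validation and probe collapsing of expression tables.

The native on-disk format is a UTF-8 tab-delimited matrix whose header row
holds sample ids and whose first column holds feature (miRNA or probe) ids,
plus a two-column label file mapping every sample id to a class in
``{1: case, 0: control}``.  Multi-probe features are collapsed to one row per
miRNA by averaging probe values within each sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ExpressionMatrixError",
    "read_expression_table",
    "write_expression_table",
    "read_labels",
    "read_probe_map",
    "collapse_probes",
]

#: tokens treated as genuinely missing (policy applies); anything else
#: non-numeric is a hard error naming the offending cell.
_NA_TOKENS = {"", "na", "nan", "null", "n/a"}


class ExpressionMatrixError(ValueError):
    """Malformed expression table, label file or probe map."""


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with binary class labels.

    ``values`` is a DataFrame (rows = features, columns = samples) and
    ``labels`` a Series indexed by sample id with values in {0, 1}
    (1 = case, 0 = control).
    """

    values: pd.DataFrame
    labels: pd.Series

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Labels aligned to the column order of ``values``."""
        return self.labels.reindex(self.values.columns).to_numpy(dtype=int)

    @property
    def case_ids(self) -> list[str]:
        y = self.y
        return [s for s, yi in zip(self.sample_ids, y) if yi == 1]

    @property
    def control_ids(self) -> list[str]:
        y = self.y
        return [s for s, yi in zip(self.sample_ids, y) if yi == 0]

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise ExpressionMatrixError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(self.values[ids], self.labels.loc[ids])

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self.values.index]
        if missing:
            raise ExpressionMatrixError(f"unknown feature ids: {missing}")
        return ExpressionMatrix(self.values.loc[ids], self.labels)

    # -- validation ------------------------------------------------------
    def validate(self, min_per_class: int = 2) -> "ExpressionMatrix":
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate feature ids: {dup}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate sample ids: {dup}")
        unlabeled = [s for s in cols if s not in self.labels.index]
        if unlabeled:
            raise ExpressionMatrixError(f"samples missing a label: {unlabeled}")
        unknown = [s for s in self.labels.index if s not in cols]
        if unknown:
            raise ExpressionMatrixError(
                f"label file names unknown samples: {unknown}"
            )
        bad = set(self.labels.unique()) - {0, 1}
        if bad:
            raise ExpressionMatrixError(f"labels must be 0/1, got {sorted(bad)}")
        if self.values.isna().to_numpy().any():
            raise ExpressionMatrixError("matrix contains missing values")
        y = self.y
        n_case, n_control = int((y == 1).sum()), int((y == 0).sum())
        if n_case < min_per_class or n_control < min_per_class:
            raise ExpressionMatrixError(
                f"need >= {min_per_class} samples per class, "
                f"got {n_case} case / {n_control} control"
            )
        return self


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_labels(label_path) -> pd.Series:
    """Read a two-column (sample_id, label) tab-delimited file.

    A single header line is tolerated (detected by a non-0/1 second field).
    """
    raw = pd.read_csv(label_path, sep="\t", header=None, dtype=str)
    if raw.shape[1] != 2:
        raise ExpressionMatrixError(
            f"label file must have 2 columns, got {raw.shape[1]}"
        )
    if raw.iloc[0, 1] not in {"0", "1"}:  # header line
        raw = raw.iloc[1:]
    if raw.empty:
        raise ExpressionMatrixError("label file has no entries")
    labels = pd.Series(
        pd.to_numeric(raw.iloc[:, 1], errors="coerce").to_numpy(),
        index=raw.iloc[:, 0].to_numpy(),
        name="label",
    )
    if labels.isna().any() or not set(labels.unique()) <= {0, 1}:
        bad = raw.loc[~raw.iloc[:, 1].isin(["0", "1"]), 0].tolist()
        raise ExpressionMatrixError(f"non-binary labels for samples: {bad}")
    if labels.index.has_duplicates:
        dup = labels.index[labels.index.duplicated()].unique().tolist()
        raise ExpressionMatrixError(f"duplicate sample ids in label file: {dup}")
    return labels.astype(int)


def _check_header_duplicates(path) -> None:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    names = header[1:]
    seen, dup = set(), []
    for name in names:
        if name in seen:
            dup.append(name)
        seen.add(name)
    if dup:
        raise ExpressionMatrixError(f"duplicate sample column header: {dup}")


def read_expression_table(
    path,
    label_path,
    *,
    missing_policy: str = "drop_feature",
    log2: bool = False,
) -> ExpressionMatrix:
    """Load a tab-delimited expression matrix plus its label file.

    Parameters
    ----------
    missing_policy:
        ``"drop_feature"`` removes any feature with a missing value (default;
        downstream correlation/SAM assume complete vectors) or
        ``"impute_median"`` fills each missing cell with the feature's
        per-sample median.
    log2:
        Apply ``log2(x + 1)`` on load.  Off by default: no transform is
        assumed for the input scale.
    """
    _check_header_duplicates(path)
    # round_trip parsing keeps read->write->read bit-identical
    raw = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    num = raw.apply(pd.to_numeric, errors="coerce")

    # hard error: a non-numeric token that is not a recognised NA marker
    coerced = num.isna() & raw.notna()
    if coerced.to_numpy().any():
        rows, cols = np.nonzero(coerced.to_numpy())
        for r, c in zip(rows, cols):
            token = str(raw.iat[r, c]).strip().lower()
            if token not in _NA_TOKENS:
                raise ExpressionMatrixError(
                    f"non-numeric cell {raw.iat[r, c]!r} at feature "
                    f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
                )

    missing = num.isna()
    if missing.to_numpy().any():
        if missing_policy == "drop_feature":
            dropped = num.index[missing.any(axis=1)].tolist()
            logger.warning(
                "dropping %d feature(s) with missing values: %s",
                len(dropped), dropped,
            )
            num = num.loc[~missing.any(axis=1)]
        elif missing_policy == "impute_median":
            med = num.median(axis=1)
            num = num.apply(lambda row: row.fillna(med[row.name]), axis=1)
            logger.warning("imputed missing values with feature medians")
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")

    if log2:
        num = np.log2(num + 1.0)

    labels = read_labels(label_path)
    matrix = ExpressionMatrix(num.astype(float), labels).validate()
    y = matrix.y
    logger.info(
        "loaded %d features x %d samples (%d case / %d control)",
        matrix.n_features, matrix.n_samples, (y == 1).sum(), (y == 0).sum(),
    )
    return matrix


def write_expression_table(matrix: ExpressionMatrix, path, label_path=None) -> None:
    """Write the native tab-delimited dialect (features in input order)."""
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
    if label_path is not None:
        matrix.labels.rename_axis("sample_id").to_csv(label_path, sep="\t")


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------

def read_probe_map(path) -> dict[str, str]:
    """Read a two-column (probe_id, mirna_id) tab-delimited file."""
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if raw.shape[1] != 2:
        raise ExpressionMatrixError(
            f"probe map must have 2 columns, got {raw.shape[1]}"
        )
    if str(raw.iloc[0, 0]).lower() in {"probe", "probe_id"}:
        raw = raw.iloc[1:]
    probes = raw.iloc[:, 0]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].tolist()
        raise ExpressionMatrixError(
            f"probe mapped to more than one miRNA: {dup}"
        )
    return dict(zip(raw.iloc[:, 0], raw.iloc[:, 1]))


def collapse_probes(
    values: pd.DataFrame,
    probe_map: Mapping[str, str],
    *,
    on_unmapped: str = "drop",
) -> pd.DataFrame:
    """Collapse probe-level rows to one row per miRNA by averaging.

    Each collapsed cell is the arithmetic mean of the feature's probes in
    that sample.  miRNAs keep the order of first probe appearance.
    ``on_unmapped`` is ``"drop"`` (default, with a warning) or ``"error"``.
    """
    unmapped = [p for p in values.index if p not in probe_map]
    if unmapped:
        if on_unmapped == "error":
            raise ExpressionMatrixError(f"probes absent from map: {unmapped}")
        logger.warning("dropping %d unmapped probe(s): %s", len(unmapped), unmapped)
        values = values.loc[[p for p in values.index if p in probe_map]]
    if values.empty:
        raise ExpressionMatrixError("no probes left after applying probe map")
    mirnas = pd.Series([probe_map[p] for p in values.index], index=values.index)
    order = mirnas.drop_duplicates().tolist()  # first-appearance order
    collapsed = values.groupby(mirnas, sort=False).mean()
    return collapsed.loc[order]
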
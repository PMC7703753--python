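"""Feature tables, CSV/TSV loading, KNN imputation and stratified splitting.

The in-memory container is :class:`FeatureTable`: a dense float matrix
(samples x features, ``NaN`` = missing) with per-feature kind metadata
(``continuous`` / ``binary`` / ``categorical``).  Categorical columns are
label-encoded to integer codes at load time so that every downstream
operator sees a purely numeric matrix; the original level sets are kept in
``categorical_levels`` and a one-hot-encoding operator is available in the
operator catalog for pipelines that need indicator expansion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

KINDS = ("continuous", "binary", "categorical")


class DataError(ValueError):
    """Raised for malformed feature tables or labels."""


@dataclass
class FeatureTable:
    """Samples x features matrix with per-feature kind metadata.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Float matrix; missing entries are ``NaN``.
    feature_names : list of str
        Unique feature identifiers (column order).
    feature_kinds : list of str
        One of ``{"continuous", "binary", "categorical"}`` per feature.
    sample_ids : list of str
        Unique sample identifiers (row order).
    categorical_levels : dict
        For categorical features, the ordered level list; code ``i`` in the
        matrix is ``levels[i]``.
    """

    values: np.ndarray
    feature_names: list
    feature_kinds: list
    sample_ids: list
    categorical_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != d or len(self.feature_kinds) != d:
            raise DataError("feature metadata length does not match column count")
        if len(set(self.feature_names)) != d:
            raise DataError("feature names are not unique")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample ids are not unique")
        for kind in self.feature_kinds:
            if kind not in KINDS:
                raise DataError(f"unknown feature kind {kind!r}")
        for j, kind in enumerate(self.feature_kinds):
            if kind == "binary":
                col = self.values[:, j]
                obs = col[~np.isnan(col)]
                if not np.isin(obs, (0.0, 1.0)).all():
                    raise DataError(
                        f"binary feature {self.feature_names[j]!r} has values "
                        "outside {0, 1}"
                    )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def copy(self) -> "FeatureTable":
        return replace(
            self,
            values=self.values.copy(),
            feature_names=list(self.feature_names),
            feature_kinds=list(self.feature_kinds),
            sample_ids=list(self.sample_ids),
            categorical_levels=dict(self.categorical_levels),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_names)
        )


@dataclass
class LabeledDataset:
    """A :class:`FeatureTable` with a binary label per sample."""

    table: FeatureTable
    labels: np.ndarray
    profile_id: str = "other"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.table.n_samples,):
            raise DataError("label vector length does not match sample count")
        if not np.isin(self.labels, (0, 1)).all():
            raise DataError("labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.table.n_samples

    def class_counts(self) -> tuple:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        table = replace(
            self.table,
            values=self.table.values[idx],
            sample_ids=[self.table.sample_ids[i] for i in idx],
            feature_names=list(self.table.feature_names),
            feature_kinds=list(self.table.feature_kinds),
            categorical_levels=dict(self.table.categorical_levels),
        )
        return LabeledDataset(table, self.labels[idx], self.profile_id)


@dataclass
class SplitPair:
    """Disjoint stratified train/validation partition of a dataset."""

    train: LabeledDataset
    validation: LabeledDataset
    fraction: float
    seed: int


def _infer_kind(col: pd.Series) -> str:
    numeric = pd.to_numeric(col, errors="coerce")
    non_missing = col.dropna()
    if len(non_missing) and numeric[non_missing.index].isna().any():
        return "categorical"
    distinct = set(numeric.dropna().unique())
    if len(distinct) <= 2 and distinct <= {0.0, 1.0}:
        return "binary"
    return "continuous"


def load_feature_table(
    path,
    label_column: str,
    kind_overrides: dict | None = None,
    id_column: str | None = None,
    profile_id: str = "other",
) -> LabeledDataset:
    """Load a CSV/TSV feature table with a binary label column.

    The first row is the header; the sample-id column defaults to the first
    column; empty cells are missing.  Feature kinds are inferred per column
    (<=2 distinct non-missing numeric values in {0,1} -> binary; any
    non-numeric value -> categorical; otherwise continuous) and may be
    overridden via ``kind_overrides``.  Labels are mapped to {0, 1} by sorted
    order of their string representation, and the mapping is logged; samples
    with a missing label are dropped (logged).
    """
    kind_overrides = dict(kind_overrides or {})
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=object)
    if id_column is None:
        id_column = df.columns[0]
    if label_column not in df.columns:
        raise DataError(f"label column {label_column!r} not found in {path}")
    if id_column not in df.columns:
        raise DataError(f"id column {id_column!r} not found in {path}")

    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()[:5]
        raise DataError(f"duplicate sample ids: {list(dupes)}")

    labels_raw = df[label_column]
    keep = labels_raw.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d samples with missing label", n_dropped)
    df = df.loc[keep]
    labels_raw = labels_raw.loc[keep]

    distinct = sorted(labels_raw.astype(str).unique())
    if len(distinct) != 2:
        raise DataError(
            f"label not binary: column {label_column!r} has "
            f"{len(distinct)} distinct values {distinct[:5]}"
        )
    mapping = {distinct[0]: 0, distinct[1]: 1}
    logger.info("label mapping: %s", mapping)
    labels = labels_raw.astype(str).map(mapping).to_numpy(dtype=int)

    feature_cols = [c for c in df.columns if c not in (id_column, label_column)]
    names, kinds, columns = [], [], []
    categorical_levels = {}
    for name in feature_cols:
        col = df[name]
        kind = kind_overrides.get(name, _infer_kind(col))
        if kind not in KINDS:
            raise DataError(f"invalid kind override {kind!r} for {name!r}")
        if kind == "categorical":
            levels = sorted(col.dropna().astype(str).unique())
            codes = col.astype(object).map(
                {lv: float(i) for i, lv in enumerate(levels)}
            )
            values = codes.to_numpy(dtype=float)
            categorical_levels[name] = levels
        else:
            values = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
        names.append(name)
        kinds.append(kind)
        columns.append(values)

    table = FeatureTable(
        values=np.column_stack(columns) if columns else np.empty((len(df), 0)),
        feature_names=names,
        feature_kinds=kinds,
        sample_ids=list(df[id_column].astype(str)),
        categorical_levels=categorical_levels,
    )
    return LabeledDataset(table, labels, profile_id)


def knn_impute(table: FeatureTable, k: int = 5) -> FeatureTable:
    """Replace missing entries by the mean over the k nearest samples.

    Nearness is Euclidean distance over the features observed in both
    samples, rescaled by the fraction of usable features (nan-Euclidean);
    donors must have the target feature observed.  Observed entries are
    unchanged and the result has no missing entries.
    """
    if k <= 0:
        raise DataError("k must be a positive integer")
    if k >= table.n_samples:
        raise DataError(f"k={k} must be smaller than the sample count {table.n_samples}")
    all_missing_rows = np.isnan(table.values).all(axis=1)
    if all_missing_rows.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(all_missing_rows)[:5]]
        raise DataError(f"samples with all features missing: {bad}")
    all_missing_cols = np.isnan(table.values).all(axis=0)
    if all_missing_cols.any():
        bad = [table.feature_names[j] for j in np.flatnonzero(all_missing_cols)[:5]]
        raise DataError(f"features with no observed values: {bad}")
    if not table.has_missing():
        return table.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputed = imputer.fit_transform(table.values)
    out = table.copy()
    out.values = np.asarray(imputed, dtype=float)
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_split(
    dataset: LabeledDataset, validation_fraction: float, seed: int
) -> SplitPair:
    """Deterministic stratified train/validation split.

    Per-class validation counts are ``round(fraction * class_size)``
    (half away from zero), then adjusted so the total equals
    ``round(fraction * n)``; the adjustment adds/removes one sample from the
    classes with the largest/smallest fractional remainder.  Membership is
    drawn from a generator seeded with ``seed`` over sample-id-sorted
    within-class orders, so the split is invariant to input row order.
    """
    if not 0.0 < validation_fraction < 1.0:
        raise DataError("validation_fraction must lie in (0, 1)")
    labels = dataset.labels
    n = dataset.n_samples
    classes = [0, 1]
    class_idx = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise DataError(f"class {c} has fewer than 2 samples; cannot split")
        order = sorted(idx, key=lambda i: str(dataset.table.sample_ids[i]))
        class_idx[c] = np.asarray(order, dtype=int)

    target_total = _round_half_away(validation_fraction * n)
    counts = {c: _round_half_away(validation_fraction * len(class_idx[c])) for c in classes}
    # Keep at least one sample of each class on each side.
    for c in classes:
        counts[c] = min(max(counts[c], 1), len(class_idx[c]) - 1)
    remainders = {
        c: validation_fraction * len(class_idx[c]) - counts[c] for c in classes
    }
    while sum(counts.values()) < target_total:
        c = max(classes, key=lambda c: (remainders[c], c))
        if counts[c] < len(class_idx[c]) - 1:
            counts[c] += 1
            remainders[c] -= 1
        else:
            break
    while sum(counts.values()) > target_total:
        c = min(classes, key=lambda c: (remainders[c], -c))
        if counts[c] > 1:
            counts[c] -= 1
            remainders[c] += 1
        else:
            break

    rng = np.random.default_rng(seed)
    val_idx = []
    for c in classes:
        perm = rng.permutation(len(class_idx[c]))
        val_idx.extend(class_idx[c][perm[: counts[c]]])
    val_mask = np.zeros(n, dtype=bool)
    val_mask[np.asarray(val_idx, dtype=int)] = True
    train = dataset.subset(np.flatnonzero(~val_mask))
    validation = dataset.subset(np.flatnonzero(val_mask))
    return SplitPair(train, validation, validation_fraction, seed)
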
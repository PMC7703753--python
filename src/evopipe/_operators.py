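"""Custom sklearn-compatible operators used by the catalog.

These are the feature constructors that have no direct scikit-learn
equivalent: per-sample zero counts, the stacking estimator (class
predictions + class probabilities appended as synthetic features), a
few-level one-hot expander that works on an already numeric matrix, and a
feature-agglomeration wrapper that clips the cluster count to the number of
available columns.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.cluster import FeatureAgglomeration
from sklearn.utils.validation import check_is_fitted


class ZeroCount(TransformerMixin, BaseEstimator):
    """Append per-sample counts of zero and non-zero entries (2 columns)."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        zeros = (X == 0).sum(axis=1).astype(float)
        non_zeros = X.shape[1] - zeros
        return np.hstack([X, zeros[:, None], non_zeros[:, None]])


class StackingEstimator(TransformerMixin, BaseEstimator):
    """Append an internal classifier's predictions and class probabilities.

    For a binary problem the output gains 3 columns: the predicted class and
    one probability column per class.  The internal classifier is fit on the
    training data only; ``transform`` never refits.
    """

    def __init__(self, estimator=None):
        self.estimator = estimator

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("StackingEstimator requires labels")
        X = np.asarray(X, dtype=float)
        self.estimator_ = clone(self.estimator)
        self.estimator_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        pred = np.asarray(self.estimator_.predict(X), dtype=float)[:, None]
        proba = np.asarray(self.estimator_.predict_proba(X), dtype=float)
        return np.hstack([X, pred, proba])


class FewLevelOneHotEncoder(TransformerMixin, BaseEstimator):
    """One-hot expand numeric columns with few distinct training values.

    Columns with ``<= max_levels`` distinct values on the training data are
    replaced by one indicator column per observed level (unseen values at
    apply time map to all-zero indicators); other columns pass through.
    """

    def __init__(self, max_levels=10):
        self.max_levels = max_levels

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.levels_ = {}
        for j in range(X.shape[1]):
            uniq = np.unique(X[:, j])
            if 2 <= len(uniq) <= self.max_levels:
                self.levels_[j] = uniq
        return self

    def transform(self, X):
        check_is_fitted(self, "levels_")
        X = np.asarray(X, dtype=float)
        cols = []
        for j in range(X.shape[1]):
            if j in self.levels_:
                for level in self.levels_[j]:
                    cols.append((X[:, j] == level).astype(float))
            else:
                cols.append(X[:, j])
        return np.column_stack(cols)


class SafeFeatureAgglomeration(TransformerMixin, BaseEstimator):
    """Feature agglomeration that never asks for more clusters than columns.

    Ward linkage forces the Euclidean metric (scikit-learn's own constraint).
    """

    def __init__(self, n_clusters=2, linkage="ward", metric="euclidean"):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.metric = metric

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        metric = "euclidean" if self.linkage == "ward" else self.metric
        self.agglo_ = FeatureAgglomeration(
            n_clusters=min(self.n_clusters, X.shape[1]),
            linkage=self.linkage,
            metric=metric,
        )
        self.agglo_.fit(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "agglo_")
        return self.agglo_.transform(np.asarray(X, dtype=float))
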
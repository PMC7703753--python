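"""Metrics, grid-search baselines, search-space combinatorics, permutation
feature importance and head-ablation sensitivity analysis.

Single-threshold metrics (balanced accuracy, precision, recall) are computed
from hard predictions; curve metrics (ROC-AUC as the Mann-Whitney rank
statistic with ties at 1/2, PR-AUC as step-wise average precision) from
real-valued class-1 scores.  Grid-search baselines reuse the pipeline-tree
machinery so that a composed baseline (e.g. standard scaler + RFE + logistic
regression) is exactly a fixed linear pipeline with complexity
``len(chain) + 1``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .data_model import DataError, LabeledDataset
from .operator_catalog import OperatorCatalog, OperatorSpec
from .pipeline_tree import (
    DataLeaf,
    FitnessRecord,
    OperatorNode,
    PipelineTree,
    evaluate_cv,
    fit_pipeline,
    iter_nodes,
)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recall: (recall_0 + recall_1) / 2."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise DataError("y_true and y_pred must have the same length")
    if len(np.unique(y_true)) < 2:
        raise DataError("y_true must contain both classes")
    return float(balanced_accuracy_score(y_true, y_pred))


@dataclass
class SplitMetrics:
    """Metric panel for one data split."""

    balanced_accuracy: float
    precision: float
    recall: float
    roc_auc: float
    pr_auc: float
    confusion: np.ndarray  # rows = true class, columns = predicted class

    def normalized_confusion(self) -> np.ndarray:
        row_sums = self.confusion.sum(axis=1, keepdims=True).astype(float)
        return self.confusion / row_sums

    def as_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "confusion": self.confusion.tolist(),
        }


@dataclass
class MetricReport:
    """Training and validation metric panels plus pipeline complexity."""

    validation: SplitMetrics
    training: SplitMetrics
    complexity: int
    model_name: str = ""

    def as_dict(self) -> dict:
        return {
            "model": self.model_name,
            "complexity": self.complexity,
            "validation": self.validation.as_dict(),
            "training": self.training.as_dict(),
        }


def classification_report(y_true, y_pred, y_score) -> SplitMetrics:
    """Compute the full metric panel for one split.

    ``y_score`` is a real-valued class-1 score (probability, decision
    function, ...); ROC-AUC and PR-AUC are invariant to strictly monotone
    transformations of it.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise DataError("y_true must contain both classes")
    return SplitMetrics(
        balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
        precision=float(precision_score(y_true, y_pred, zero_division=0.0)),
        recall=float(recall_score(y_true, y_pred, zero_division=0.0)),
        roc_auc=float(roc_auc_score(y_true, y_score)),
        pr_auc=float(average_precision_score(y_true, y_score)),
        confusion=confusion_matrix(y_true, y_pred, labels=[0, 1]),
    )


def evaluate_on_splits(
    tree: PipelineTree,
    train: LabeledDataset,
    validation: LabeledDataset,
    catalog: OperatorCatalog,
    seed: int = 0,
    model_name: str = "",
) -> MetricReport:
    """Fit a pipeline on the training split, report metrics on both splits."""
    fitted = fit_pipeline(tree, train, catalog, seed)
    report = MetricReport(
        validation=classification_report(
            validation.labels,
            fitted.predict(validation.table),
            fitted.scores(validation.table),
        ),
        training=classification_report(
            train.labels, fitted.predict(train.table), fitted.scores(train.table)
        ),
        complexity=tree.complexity(),
        model_name=model_name,
    )
    return report


# ---------------------------------------------------------------------------
# Grid search baselines
# ---------------------------------------------------------------------------

def grid_size(param_grid: dict) -> int:
    """Number of Cartesian combinations (empty grid -> 1 default combo)."""
    size = 1
    for values in param_grid.values():
        size *= len(list(values))
    return size


def preprocessor_search_space(grid_combinations: int, n_preprocessors: int) -> int:
    """Grid combinations times ordered pre-processor arrangements.

    Chains use each pre-processor at most once, order matters and the empty
    chain is included: sum_{k=0}^{p} p! / (p-k)!  (the estimate for
    pre-processors with no hyperparameters of their own).
    """
    if n_preprocessors < 0:
        raise ValueError("n_preprocessors must be >= 0")
    p = n_preprocessors
    arrangements = sum(
        math.factorial(p) // math.factorial(p - k) for k in range(p + 1)
    )
    return grid_combinations * arrangements


def make_chain_pipeline(
    classifier_name: str,
    classifier_values: dict,
    chain: list | None = None,
) -> PipelineTree:
    """Build a linear pipeline tree: chain (input end first) -> classifier."""
    node = DataLeaf()
    for name, values in chain or []:
        node = OperatorNode(name, dict(values), node)
    return PipelineTree(OperatorNode(classifier_name, dict(classifier_values), node))


@dataclass
class GridSearchResult:
    best_values: dict
    report: MetricReport
    record: FitnessRecord
    tree: PipelineTree
    n_combinations: int


def grid_search(
    classifier_name: str,
    param_grid: dict,
    train: LabeledDataset,
    validation: LabeledDataset,
    catalog: OperatorCatalog,
    n_folds: int = 10,
    seed: int = 0,
    preprocessor_chain: list | None = None,
    model_name: str = "",
) -> GridSearchResult:
    """Exhaustive grid search by k-fold CV balanced accuracy on the training
    split; the best combination (ties: first in deterministic enumeration
    order) is refit on the full training split and reported on both splits.

    ``preprocessor_chain`` is an optional fixed list of ``(operator_name,
    values)`` prepended (input end first) to every evaluated pipeline.
    """
    if not param_grid and param_grid != {}:
        raise ValueError("param_grid must be a mapping")
    keys = sorted(param_grid)
    for k in keys:
        if len(list(param_grid[k])) == 0:
            raise ValueError(f"empty domain for grid parameter {k!r}")
    combos = (
        [dict(zip(keys, vals)) for vals in itertools.product(*(list(param_grid[k]) for k in keys))]
        if keys
        else [{}]
    )
    best = None
    for i, combo in enumerate(combos):
        tree = make_chain_pipeline(classifier_name, combo, preprocessor_chain)
        record = evaluate_cv(tree, train, catalog, n_folds=n_folds, seed=seed)
        key = (record.fitness, -i)  # ties -> first combination
        if best is None or key > best[0]:
            best = (key, combo, tree, record)
    _, best_values, best_tree, best_record = best
    report = evaluate_on_splits(
        best_tree, train, validation, catalog, seed=seed, model_name=model_name
    )
    return GridSearchResult(
        best_values=best_values,
        report=report,
        record=best_record,
        tree=best_tree,
        n_combinations=len(combos),
    )


# ---------------------------------------------------------------------------
# Permutation feature importance
# ---------------------------------------------------------------------------

@dataclass
class PFIResult:
    """Mean decrease in balanced accuracy under per-feature permutation."""

    feature_names: list
    mean_decrease: np.ndarray
    per_repeat: np.ndarray  # (n_features, n_repeats)
    baseline_score: float

    def ranking(self) -> list:
        """Features sorted by mean decrease, descending (stable)."""
        order = np.argsort(-self.mean_decrease, kind="stable")
        return [
            (self.feature_names[j], float(self.mean_decrease[j])) for j in order
        ]


def permutation_importance(
    fitted_pipeline,
    data: LabeledDataset,
    n_repeats: int = 100,
    seed: int = 0,
) -> PFIResult:
    """Permutation feature importance with the model held fixed.

    Baseline = balanced accuracy of the already-fitted pipeline on ``data``.
    For feature ``f`` and repeat ``r`` the column is permuted with a seed
    derived from ``(seed, f, r)`` and the decrease baseline - permuted score
    recorded; the mean over repeats is the PFI score.  Nothing is refit.
    """
    if n_repeats <= 0:
        raise ValueError("n_repeats must be positive")
    if data.table.has_missing():
        raise DataError("PFI requires imputed data")
    baseline = balanced_accuracy(data.labels, fitted_pipeline.predict(data.table))
    n_features = data.table.n_features
    per_repeat = np.zeros((n_features, n_repeats))
    for f in range(n_features):
        col = data.table.values[:, f]
        if np.all(col == col[0]):
            continue  # every permutation is the identical dataset
        for r in range(n_repeats):
            rng = np.random.default_rng(
                (seed * 1_000_003 + f * 10_007 + r) % (2**31 - 1)
            )
            permuted = data.table.copy()
            permuted.values[:, f] = col[rng.permutation(len(col))]
            score = balanced_accuracy(data.labels, fitted_pipeline.predict(permuted))
            per_repeat[f, r] = baseline - score
    return PFIResult(
        feature_names=list(data.table.feature_names),
        mean_decrease=per_repeat.mean(axis=1),
        per_repeat=per_repeat,
        baseline_score=baseline,
    )


# ---------------------------------------------------------------------------
# Head ablation
# ---------------------------------------------------------------------------

@dataclass
class AblationTable:
    """Consecutive removal of pre-processors from the input end of a pipeline."""

    rows: list = field(default_factory=list)  # (n_removed, MetricReport, tree_text)
    source: str = ""


def _deepest_preprocessor(tree: PipelineTree):
    """The (parent, key, node) of the operator node farthest from the root."""
    best = None

    def walk(parent, key, node, depth):
        nonlocal best
        if isinstance(node, OperatorNode):
            if best is None or depth > best[3]:
                best = (parent, key, node, depth)
            walk(node, "child", node.child, depth + 1)
        elif hasattr(node, "children"):
            for i, c in enumerate(node.children):
                walk(node, i, c, depth + 1)

    walk(tree.root, "child", tree.root.child, 1)
    return best


def head_ablation(
    tree: PipelineTree,
    train: LabeledDataset,
    validation: LabeledDataset,
    catalog: OperatorCatalog,
    seed: int = 0,
) -> AblationTable:
    """Remove pre-processors one at a time from the input (leaf) end.

    Rows for 0, 1, ..., k-1 removed operators; each reduced pipeline is refit
    on the training split and reported on both splits; the final row is the
    bare classifier (complexity 1).
    """
    table = AblationTable(source=tree.serialize())
    current = tree.clone()
    k = current.complexity()
    for n_removed in range(k):
        report = evaluate_on_splits(
            current,
            train,
            validation,
            catalog,
            seed=seed,
            model_name=f"removed_{n_removed}",
        )
        table.rows.append((n_removed, report, current.serialize()))
        found = _deepest_preprocessor(current)
        if found is None:
            break
        parent, key, node, _ = found
        if isinstance(parent, OperatorNode):
            parent.child = node.child
        else:
            parent.children[key] = node.child
    return table
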
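"""Expression-tree pipelines: structure, compilation, complexity, CV fitness.

A pipeline is a tree whose leaves are copies of the entire dataset, whose
internal nodes are feature transformers / selectors / constructors, whose
optional combine nodes column-concatenate two or more branches, and whose
root is the single classifier.  Complexity is the number of operator nodes
including the classifier (a bare classifier has complexity 1); combine nodes
and dataset leaves are not counted.

Fitness of a pipeline is its mean 10-fold cross-validated balanced accuracy
paired with its complexity; invalid pipelines (operator failures, empty
feature sets) carry a ``-inf`` sentinel so selection can keep operating over
populations that contain failures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .data_model import DataError, FeatureTable, LabeledDataset
from .operator_catalog import (
    EmptyFeatureSetError,
    OperatorCatalog,
    OperatorError,
    build_estimator,
    fit_operator,
)

INVALID_FITNESS = float("-inf")


class PipelineEvaluationError(RuntimeError):
    """A pipeline could not be fit/applied; converted to worst fitness in CV."""


class TreeStructureError(ValueError):
    """The tree violates a structural invariant."""


# ---------------------------------------------------------------------------
# Nodes
# ---------------------------------------------------------------------------

@dataclass
class DataLeaf:
    """A copy of the entire dataset."""

    def clone(self):
        return DataLeaf()


@dataclass
class OperatorNode:
    """Application of one operator (chosen hyperparameter values) to a child."""

    name: str
    values: dict
    child: object

    def clone(self):
        return OperatorNode(self.name, dict(self.values), self.child.clone())


@dataclass
class CombineNode:
    """Column-concatenation of two or more branches (not counted in complexity)."""

    children: list

    def clone(self):
        return CombineNode([c.clone() for c in self.children])


def _count_ops(node) -> int:
    if isinstance(node, DataLeaf):
        return 0
    if isinstance(node, OperatorNode):
        return 1 + _count_ops(node.child)
    if isinstance(node, CombineNode):
        return sum(_count_ops(c) for c in node.children)
    raise TreeStructureError(f"unknown node type {type(node)!r}")


@dataclass
class PipelineTree:
    """A pipeline expression tree; the root operator is the classifier."""

    root: OperatorNode

    def clone(self) -> "PipelineTree":
        return PipelineTree(self.root.clone())

    def complexity(self) -> int:
        return _count_ops(self.root)

    def validate(self, catalog: OperatorCatalog, max_operators: int | None = None):
        """Raise :class:`TreeStructureError` on any invariant violation."""
        if not isinstance(self.root, OperatorNode):
            raise TreeStructureError("root must be an operator node")
        if catalog.get(self.root.name).kind != "classifier":
            raise TreeStructureError("root operator must be a classifier")
        for node in iter_nodes(self.root.child):
            if isinstance(node, OperatorNode):
                kind = catalog.get(node.name).kind
                if kind == "classifier":
                    raise TreeStructureError("classifier below the root")
            elif isinstance(node, CombineNode):
                if len(node.children) < 2:
                    raise TreeStructureError("combine node needs >= 2 children")
        c = self.complexity()
        if c < 1:
            raise TreeStructureError("complexity must be >= 1")
        if max_operators is not None and c > max_operators:
            raise TreeStructureError(f"complexity {c} exceeds cap {max_operators}")

    # -- serialization ------------------------------------------------------

    def serialize(self) -> str:
        """S-expression-like text, bit-stable across runs."""
        return _node_text(self.root)

    @classmethod
    def deserialize(cls, text: str) -> "PipelineTree":
        node = _parse_node(text)
        if not isinstance(node, OperatorNode):
            raise TreeStructureError("serialized tree must start with the classifier")
        return cls(node)

    def to_json(self) -> str:
        return json.dumps(_node_dict(self.root), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineTree":
        return cls(_node_from_dict(json.loads(text)))

    def __hash__(self):
        return hash(self.serialize())

    def __eq__(self, other):
        return isinstance(other, PipelineTree) and self.serialize() == other.serialize()


def iter_nodes(node):
    """Pre-order iteration over a subtree."""
    yield node
    if isinstance(node, OperatorNode):
        yield from iter_nodes(node.child)
    elif isinstance(node, CombineNode):
        for c in node.children:
            yield from iter_nodes(c)


# ---------------------------------------------------------------------------
# Text serialization
# ---------------------------------------------------------------------------

def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return repr(v)
    if isinstance(v, (int, np.integer)):
        return repr(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if v is None:
        return "None"
    return str(v)


def _parse_value(tok: str):
    if tok == "True":
        return True
    if tok == "False":
        return False
    if tok == "None":
        return None
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        pass
    return tok


def _node_text(node) -> str:
    if isinstance(node, DataLeaf):
        return "DATA"
    if isinstance(node, CombineNode):
        return "COMBINE[" + "; ".join(_node_text(c) for c in node.children) + "]"
    args = ",".join(f"{k}={_fmt_value(node.values[k])}" for k in sorted(node.values))
    return f"{node.name}({args})<-{_node_text(node.child)}"


def _split_top(text: str, sep: str) -> list:
    """Split on ``sep`` ignoring separators nested inside brackets."""
    parts, depth, start = [], 0, 0
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "[(":
            depth += 1
        elif ch in "])":
            depth -= 1
        elif depth == 0 and text.startswith(sep, i):
            parts.append(text[start:i])
            i += len(sep)
            start = i
            continue
        i += 1
    parts.append(text[start:])
    return parts


def _parse_node(text: str):
    text = text.strip()
    if text == "DATA":
        return DataLeaf()
    if text.startswith("COMBINE["):
        inner = text[len("COMBINE[") : -1]
        children = [_parse_node(p) for p in _split_top(inner, ";")]
        return CombineNode(children)
    head, _, rest = text.partition("<-")
    name, _, arg_text = head.partition("(")
    arg_text = arg_text.rstrip(")")
    values = {}
    if arg_text:
        for pair in arg_text.split(","):
            k, _, v = pair.partition("=")
            values[k.strip()] = _parse_value(v.strip())
    child = _parse_node(rest) if rest else DataLeaf()
    return OperatorNode(name.strip(), values, child)


def _node_dict(node):
    if isinstance(node, DataLeaf):
        return {"type": "data"}
    if isinstance(node, CombineNode):
        return {"type": "combine", "children": [_node_dict(c) for c in node.children]}
    return {
        "type": "operator",
        "name": node.name,
        "values": node.values,
        "child": _node_dict(node.child),
    }


def _node_from_dict(d):
    if d["type"] == "data":
        return DataLeaf()
    if d["type"] == "combine":
        return CombineNode([_node_from_dict(c) for c in d["children"]])
    return OperatorNode(d["name"], dict(d["values"]), _node_from_dict(d["child"]))


# ---------------------------------------------------------------------------
# Random pipelines
# ---------------------------------------------------------------------------

def random_pipeline(
    catalog: OperatorCatalog,
    rng: np.random.Generator,
    max_operators: int = 10,
    p_combine: float = 0.2,
) -> PipelineTree:
    """Draw a structurally valid random pipeline.

    Total operator count is uniform on [1, max_operators]; hyperparameters
    are sampled uniformly from their domains; with probability ``p_combine``
    a branch with >= 2 remaining operators splits into a combine node.
    """
    if max_operators < 1:
        raise ValueError("max_operators must be >= 1")
    clf_specs = catalog.classifiers
    spec = clf_specs[rng.integers(len(clf_specs))]
    n_pre = int(rng.integers(0, max_operators))  # operators below the root
    child = _random_subtree(catalog, rng, n_pre, p_combine)
    tree = PipelineTree(OperatorNode(spec.name, spec.sample_values(rng), child))
    tree.validate(catalog, max_operators)
    return tree


def _random_subtree(catalog, rng, n_ops, p_combine):
    if n_ops == 0:
        return DataLeaf()
    if n_ops >= 2 and rng.random() < p_combine:
        k = int(rng.integers(1, n_ops))
        return CombineNode(
            [
                _random_subtree(catalog, rng, k, p_combine),
                _random_subtree(catalog, rng, n_ops - k, p_combine),
            ]
        )
    pre = catalog.preprocessors
    spec = pre[rng.integers(len(pre))]
    return OperatorNode(
        spec.name,
        spec.sample_values(rng),
        _random_subtree(catalog, rng, n_ops - 1, p_combine),
    )


# ---------------------------------------------------------------------------
# Compilation: fit on train, predict on test
# ---------------------------------------------------------------------------

def _generic_table(node, values, in_table, tag):
    """Rebuild table metadata after an operator; ``tag`` (the walk counter)
    keeps generated names unique when an operator occurs twice in a chain."""
    d = values.shape[1]
    if d == in_table.n_features and node.name in (
        "standard_scaler",
        "min_max_scaler",
        "max_abs_scaler",
        "binarizer",
        "normalizer",
    ):
        names = list(in_table.feature_names)
        # scalers may push binary columns off {0,1}; re-tag as continuous
        kinds = ["binary"] * d if node.name == "binarizer" else ["continuous"] * d
    elif d >= in_table.n_features and node.name in (
        "zero_counts",
        "stacking_estimator",
    ):
        extra = d - in_table.n_features
        names = list(in_table.feature_names) + [
            f"{node.name}.{tag}_{j}" for j in range(extra)
        ]
        kinds = list(in_table.feature_kinds) + ["continuous"] * extra
    else:
        names = [f"{node.name}.{tag}_{j}" for j in range(d)]
        kinds = ["continuous"] * d
    return FeatureTable(values, names, kinds, list(in_table.sample_ids))


def _concat(parts):
    values = np.hstack([t.values for _, t in parts])
    names, kinds = [], []
    for i, t in parts:
        names.extend(f"b{i}.{n}" for n in t.feature_names)
        kinds.extend(t.feature_kinds)
    sample_ids = parts[0][1].sample_ids
    return FeatureTable(values, names, kinds, list(sample_ids))


def fit_pipeline(
    tree: PipelineTree,
    train: LabeledDataset,
    catalog: OperatorCatalog,
    random_state: int = 0,
):
    """Fit the whole tree on training data; returns an applier closure.

    The returned object exposes ``predict(table)`` and ``scores(table)``;
    nothing is refit at apply time.
    """
    if train.table.has_missing():
        raise DataError("training data must be imputed before pipeline fitting")
    return _FittedPipeline(tree, train, catalog, random_state)


class _FittedPipeline:
    """A pipeline tree with all operator state learned from one training set."""

    def __init__(self, tree, train, catalog, random_state):
        self.tree = tree
        self.catalog = catalog
        self.random_state = random_state
        self._train = train
        self._fitted = {}
        counter = [0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                final_train = self._fit_node(tree.root.child, train, counter)
                spec = catalog.get(tree.root.name)
                if spec.kind != "classifier":
                    raise TreeStructureError("root is not a classifier")
                counter[0] += 1
                seed = (random_state * 1_000_003 + counter[0]) % (2**31 - 1)
                clf = build_estimator(tree.root.name, tree.root.values, seed)
                clf.fit(final_train.values, train.labels)
                self._classifier = clf
            except (OperatorError, TreeStructureError):
                raise
            except Exception as exc:
                raise PipelineEvaluationError(
                    f"classifier {tree.root.name} fit failed: {exc}"
                ) from exc

    def _fit_node(self, node, train, counter):
        """Fit operators leaf-to-root on the training table; cache state."""
        if isinstance(node, DataLeaf):
            return train.table
        if isinstance(node, CombineNode):
            parts = [(i, self._fit_node(c, train, counter)) for i, c in enumerate(node.children)]
            return _concat(parts)
        tr_table = self._fit_node(node.child, train, counter)
        spec = self.catalog.get(node.name)
        counter[0] += 1
        seed = (self.random_state * 1_000_003 + counter[0]) % (2**31 - 1)
        needs_y = spec.kind == "selector" or node.name == "stacking_estimator"
        y = train.labels if needs_y else None
        fitted = fit_operator(spec, node.values, tr_table.values, y, seed)
        self._fitted[id(node)] = fitted
        out = fitted.apply(tr_table.values)
        if spec.kind == "selector":
            kept = fitted.selected_indices
            return FeatureTable(
                out,
                [tr_table.feature_names[j] for j in kept],
                [tr_table.feature_kinds[j] for j in kept],
                list(tr_table.sample_ids),
            )
        return _generic_table(node, out, tr_table, counter[0])

    def _apply_node(self, node, table, counter):
        if isinstance(node, DataLeaf):
            return table
        if isinstance(node, CombineNode):
            parts = [
                (i, self._apply_node(c, table, counter))
                for i, c in enumerate(node.children)
            ]
            return _concat(parts)
        in_table = self._apply_node(node.child, table, counter)
        fitted = self._fitted[id(node)]
        counter[0] += 1
        out = fitted.apply(in_table.values)
        if fitted.spec.kind == "selector":
            kept = fitted.selected_indices
            return FeatureTable(
                out,
                [in_table.feature_names[j] for j in kept],
                [in_table.feature_kinds[j] for j in kept],
                list(in_table.sample_ids),
            )
        return _generic_table(node, out, in_table, counter[0])

    def transform(self, table: FeatureTable) -> FeatureTable:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return self._apply_node(self.tree.root.child, table, [0])
            except (OperatorError, DataError) as exc:
                raise PipelineEvaluationError(f"apply failed: {exc}") from exc

    def predict(self, table: FeatureTable) -> np.ndarray:
        feats = self.transform(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return np.asarray(self._classifier.predict(feats.values), dtype=int)
            except Exception as exc:
                raise PipelineEvaluationError(f"predict failed: {exc}") from exc

    def scores(self, table: FeatureTable) -> np.ndarray:
        """Real-valued class-1 scores usable for ROC/PR curves."""
        feats = self.transform(table)
        clf = self._classifier
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                if hasattr(clf, "predict_proba"):
                    return np.asarray(clf.predict_proba(feats.values))[:, 1]
                if hasattr(clf, "decision_function"):
                    return np.asarray(clf.decision_function(feats.values), dtype=float)
                return np.asarray(clf.predict(feats.values), dtype=float)
            except Exception as exc:
                raise PipelineEvaluationError(f"scoring failed: {exc}") from exc


def fit_predict(
    tree: PipelineTree,
    train: LabeledDataset,
    test: FeatureTable,
    catalog: OperatorCatalog,
    random_state: int = 0,
):
    """Fit the tree on ``train`` and predict ``test``.

    Returns ``(predicted_classes, class_1_scores)``.  Operator failures
    surface as :class:`PipelineEvaluationError`, never a bare crash.
    """
    try:
        fitted = fit_pipeline(tree, train, catalog, random_state)
        return fitted.predict(test), fitted.scores(test)
    except (OperatorError, EmptyFeatureSetError) as exc:
        raise PipelineEvaluationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Cross-validated fitness
# ---------------------------------------------------------------------------

@dataclass
class FitnessRecord:
    """Mean CV balanced accuracy + per-fold scores + pipeline complexity."""

    mean_cv_balanced_accuracy: float
    per_fold_scores: list
    complexity: int
    valid: bool = True

    @property
    def fitness(self) -> float:
        return self.mean_cv_balanced_accuracy if self.valid else INVALID_FITNESS

    @classmethod
    def invalid(cls, complexity: int, n_folds: int) -> "FitnessRecord":
        return cls(INVALID_FITNESS, [INVALID_FITNESS] * n_folds, complexity, False)


def evaluate_cv(
    tree: PipelineTree,
    data: LabeledDataset,
    catalog: OperatorCatalog,
    n_folds: int = 10,
    seed: int = 0,
) -> FitnessRecord:
    """Stratified k-fold CV balanced accuracy of a pipeline tree.

    Folds are computed on the sample-id-sorted order so the record is
    invariant to input row permutation; any fold failure marks the whole
    record invalid (worst-fitness sentinel).
    """
    n0, n1 = data.class_counts()
    if min(n0, n1) < n_folds:
        raise DataError(
            f"smallest class has {min(n0, n1)} samples < n_folds={n_folds}; "
            "use a smaller n_folds"
        )
    order = np.asarray(
        sorted(range(data.n_samples), key=lambda i: str(data.table.sample_ids[i])),
        dtype=int,
    )
    y_sorted = data.labels[order]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31 - 1))
    complexity = tree.complexity()
    scores = []
    for fold_i, (tr_idx, te_idx) in enumerate(
        skf.split(np.zeros(len(order)), y_sorted)
    ):
        train = data.subset(order[tr_idx])
        test = data.subset(order[te_idx])
        fold_seed = (seed * 97 + fold_i) % (2**31 - 1)
        try:
            pred, _ = fit_predict(tree, train, test.table, catalog, fold_seed)
        except PipelineEvaluationError:
            return FitnessRecord.invalid(complexity, n_folds)
        scores.append(float(balanced_accuracy_score(test.labels, pred)))
    return FitnessRecord(float(np.mean(scores)), scores, complexity, True)
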
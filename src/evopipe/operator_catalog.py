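"""Operator catalog: transformers, selectors, feature constructors, classifiers.

The full configuration mirrors the search space of tree-based pipeline
optimisation for classification: 11 classification algorithms, 14 feature
transformers/constructors and 5 feature selectors.  Every hyperparameter has
a finite, non-empty value domain (the genetic search mutates by sampling
from these domains), and every operator follows a strict
fit-on-train / apply-to-any contract.

A reduced configuration keeps the complete transformer/selector set but a
single classifier, as used when the search is restricted to one model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.base import clone
from sklearn.cluster import FeatureAgglomeration  # noqa: F401  (re-export context)
from sklearn.decomposition import PCA, FastICA
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import (
    RFE,
    SelectFromModel,
    SelectFwe,
    SelectPercentile,
    VarianceThreshold,
    f_classif,
)
from sklearn.kernel_approximation import Nystroem, RBFSampler
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import BernoulliNB, GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import (
    Binarizer,
    MaxAbsScaler,
    MinMaxScaler,
    Normalizer,
    PolynomialFeatures,
    StandardScaler,
)
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from ._operators import (
    FewLevelOneHotEncoder,
    SafeFeatureAgglomeration,
    StackingEstimator,
    ZeroCount,
)
from .data_model import FeatureTable, LabeledDataset

KINDS = ("transformer", "selector", "constructor", "classifier", "combiner")

# Number of trees for the importance ranking inside RFE / select-from-model.
# This estimator only ranks features, it is never the final model.
SELECTOR_ESTIMATOR_TREES = 20


class OperatorError(RuntimeError):
    """An operator failed to fit or apply (non-convergence, bad input, ...)."""


class EmptyFeatureSetError(OperatorError):
    """A selector kept zero features; pipelines treat this as worst fitness."""


@dataclass(frozen=True)
class OperatorSpec:
    """Declaration of one pipeline operator and its hyperparameter domains."""

    name: str
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    arity: int = 1

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown operator kind {self.kind!r}")
        for hp, domain in self.hyperparameters.items():
            if len(tuple(domain)) == 0:
                raise ValueError(f"{self.name}.{hp} has an empty domain")

    def default_values(self) -> dict:
        return {hp: tuple(domain)[0] for hp, domain in self.hyperparameters.items()}

    def sample_values(self, rng: np.random.Generator) -> dict:
        return {
            hp: tuple(domain)[rng.integers(len(tuple(domain)))]
            for hp, domain in self.hyperparameters.items()
        }


def _classifier_specs() -> list:
    C = (0.01, 0.1, 1.0, 10.0, 100.0)
    alpha_nb = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
    return [
        OperatorSpec("logistic_regression", "classifier", {"C": C, "penalty": ("l2",)}),
        OperatorSpec(
            "decision_tree",
            "classifier",
            {
                "criterion": ("gini", "entropy"),
                "max_depth": (2, 3, 5, 8, 10),
                "min_samples_leaf": (1, 5, 10),
            },
        ),
        OperatorSpec(
            "random_forest",
            "classifier",
            {
                "n_estimators": (100,),
                "criterion": ("gini", "entropy"),
                "max_features": (0.25, 0.5, "sqrt"),
                "min_samples_leaf": (1, 5),
            },
        ),
        OperatorSpec(
            "extra_trees",
            "classifier",
            {
                "n_estimators": (100,),
                "criterion": ("gini", "entropy"),
                "max_features": (0.25, 0.5, "sqrt"),
                "min_samples_leaf": (1, 5),
            },
        ),
        OperatorSpec(
            "bernoulli_nb",
            "classifier",
            {"alpha": alpha_nb, "binarize": (0.0,), "fit_prior": (True, False)},
        ),
        OperatorSpec(
            "multinomial_nb",
            "classifier",
            {"alpha": alpha_nb, "fit_prior": (True, False)},
        ),
        OperatorSpec(
            "k_neighbors",
            "classifier",
            {"n_neighbors": (1, 3, 5, 11, 21), "weights": ("uniform", "distance"), "p": (1, 2)},
        ),
        OperatorSpec("gaussian_nb", "classifier", {}),
        OperatorSpec(
            "gradient_boosting",
            "classifier",
            {
                "n_estimators": (100,),
                "learning_rate": (0.1, 0.5, 1.0),
                "max_depth": (1, 3, 5),
            },
        ),
        OperatorSpec(
            "linear_svc",
            "classifier",
            {"C": C, "loss": ("squared_hinge",)},
        ),
        OperatorSpec(
            "mlp",
            "classifier",
            {"alpha": (1e-4, 1e-2, 0.1), "learning_rate_init": (0.001, 0.01, 0.1)},
        ),
    ]


def _transformer_specs(stacking_classifiers: tuple) -> list:
    return [
        OperatorSpec("standard_scaler", "transformer", {}),
        OperatorSpec("min_max_scaler", "transformer", {}),
        OperatorSpec("max_abs_scaler", "transformer", {}),
        OperatorSpec(
            "binarizer",
            "transformer",
            {"threshold": (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)},
        ),
        OperatorSpec("normalizer", "transformer", {"norm": ("l2", "l1", "max")}),
        OperatorSpec(
            "polynomial_features",
            "constructor",
            {"degree": (2,), "include_bias": (False,), "interaction_only": (False,)},
        ),
        OperatorSpec("pca", "transformer", {"iterated_power": (1, 2, 5, 10)}),
        OperatorSpec("fast_ica", "transformer", {"tol": (0.0, 0.25, 0.5, 1.0)}),
        OperatorSpec(
            "nystroem",
            "transformer",
            {
                "kernel": ("rbf", "cosine", "poly"),
                "gamma": (0.1, 0.5, 1.0),
                "n_components": (2, 5, 10),
            },
        ),
        OperatorSpec("rbf_sampler", "transformer", {"gamma": (0.05, 0.1, 0.5, 1.0)}),
        OperatorSpec("zero_counts", "constructor", {}),
        OperatorSpec(
            "stacking_estimator", "constructor", {"classifier": stacking_classifiers}
        ),
        OperatorSpec("one_hot_encoder", "constructor", {"max_levels": (10,)}),
        OperatorSpec(
            "feature_agglomeration",
            "transformer",
            {
                "n_clusters": (2, 5, 10, 20),
                "linkage": ("ward", "complete", "average"),
                "metric": ("euclidean", "l1", "l2", "cosine"),
            },
        ),
    ]


def _selector_specs() -> list:
    return [
        OperatorSpec(
            "variance_threshold", "selector", {"threshold": (0.0, 0.05, 0.1, 0.2, 0.5)}
        ),
        OperatorSpec(
            "select_percentile",
            "selector",
            {"percentile": (10, 20, 30, 40, 50, 60, 70, 80, 90)},
        ),
        OperatorSpec(
            "select_fwe", "selector", {"alpha": (0.01, 0.02, 0.03, 0.04, 0.05)}
        ),
        OperatorSpec("rfe", "selector", {"step": (0.25, 0.5, 0.75)}),
        OperatorSpec(
            "select_from_model", "selector", {"threshold": ("mean", "median")}
        ),
    ]


@dataclass
class OperatorCatalog:
    """A set of operator specs plus the configuration mode.

    mode is ``"full"`` or ``"reduced:<classifier_name>"``.
    """

    specs: list
    mode: str = "full"

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate operator names in catalog")
        self._by_name = {s.name: s for s in self.specs}

    def get(self, name: str) -> OperatorSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"unknown operator {name!r}; valid: {sorted(self._by_name)}"
            ) from None

    def by_kind(self, *kinds) -> list:
        return [s for s in self.specs if s.kind in kinds]

    @property
    def classifiers(self) -> list:
        return self.by_kind("classifier")

    @property
    def selectors(self) -> list:
        return self.by_kind("selector")

    @property
    def transformers(self) -> list:
        """Transformers and feature constructors (the 14 pre-processors)."""
        return self.by_kind("transformer", "constructor")

    @property
    def preprocessors(self) -> list:
        return self.by_kind("transformer", "constructor", "selector")

    def to_yaml(self) -> str:
        payload = {
            "mode": self.mode,
            "operators": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "arity": s.arity,
                    "hyperparameters": {k: list(v) for k, v in s.hyperparameters.items()},
                }
                for s in self.specs
            ],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "OperatorCatalog":
        payload = yaml.safe_load(text)
        specs = [
            OperatorSpec(
                name=o["name"],
                kind=o["kind"],
                arity=o.get("arity", 1),
                hyperparameters={k: tuple(v) for k, v in o["hyperparameters"].items()},
            )
            for o in payload["operators"]
        ]
        return cls(specs, payload.get("mode", "full"))


def full_configuration() -> OperatorCatalog:
    """The full search space: 11 classifiers, 14 transformers, 5 selectors."""
    classifiers = _classifier_specs()
    stackable = tuple(s.name for s in classifiers if s.name != "linear_svc")
    specs = _transformer_specs(stackable) + _selector_specs() + classifiers
    return OperatorCatalog(specs, mode="full")


def reduced_configuration(classifier_name: str) -> OperatorCatalog:
    """Full transformer/selector set, single named classifier."""
    full = full_configuration()
    valid = [s.name for s in full.classifiers]
    if classifier_name not in valid:
        raise KeyError(
            f"unknown classifier {classifier_name!r}; valid names: {sorted(valid)}"
        )
    classifier = full.get(classifier_name)
    stackable = (classifier_name,) if classifier_name != "linear_svc" else ("logistic_regression",)
    specs = _transformer_specs(stackable) + _selector_specs() + [classifier]
    return OperatorCatalog(specs, mode=f"reduced:{classifier_name}")


# ---------------------------------------------------------------------------
# Builders: spec name + chosen hyperparameter values -> sklearn estimator
# ---------------------------------------------------------------------------

def _selector_estimator(random_state):
    return ExtraTreesClassifier(
        n_estimators=SELECTOR_ESTIMATOR_TREES, random_state=random_state
    )


def build_estimator(name: str, values: dict, random_state: int = 0):
    """Instantiate the sklearn estimator behind an operator spec."""
    v = dict(values)
    if name == "standard_scaler":
        return StandardScaler()
    if name == "min_max_scaler":
        return MinMaxScaler()
    if name == "max_abs_scaler":
        return MaxAbsScaler()
    if name == "binarizer":
        return Binarizer(threshold=v.get("threshold", 0.0))
    if name == "normalizer":
        return Normalizer(norm=v.get("norm", "l2"))
    if name == "polynomial_features":
        return PolynomialFeatures(
            degree=v.get("degree", 2),
            include_bias=v.get("include_bias", False),
            interaction_only=v.get("interaction_only", False),
        )
    if name == "pca":
        return PCA(
            svd_solver="randomized",
            iterated_power=v.get("iterated_power", 2),
            random_state=random_state,
        )
    if name == "fast_ica":
        return FastICA(
            tol=v.get("tol", 0.0) or 1e-4,
            whiten="unit-variance",
            max_iter=200,
            random_state=random_state,
        )
    if name == "nystroem":
        return Nystroem(
            kernel=v.get("kernel", "rbf"),
            gamma=v.get("gamma", 0.1),
            n_components=v.get("n_components", 10),
            random_state=random_state,
        )
    if name == "rbf_sampler":
        return RBFSampler(gamma=v.get("gamma", 0.1), random_state=random_state)
    if name == "zero_counts":
        return ZeroCount()
    if name == "stacking_estimator":
        inner_name = v.get("classifier", "logistic_regression")
        inner = build_estimator(inner_name, {}, random_state=random_state)
        return StackingEstimator(estimator=inner)
    if name == "one_hot_encoder":
        return FewLevelOneHotEncoder(max_levels=v.get("max_levels", 10))
    if name == "feature_agglomeration":
        return SafeFeatureAgglomeration(
            n_clusters=v.get("n_clusters", 2),
            linkage=v.get("linkage", "ward"),
            metric=v.get("metric", "euclidean"),
        )
    if name == "variance_threshold":
        return VarianceThreshold(threshold=v.get("threshold", 0.0))
    if name == "select_percentile":
        return SelectPercentile(f_classif, percentile=v.get("percentile", 50))
    if name == "select_fwe":
        return SelectFwe(f_classif, alpha=v.get("alpha", 0.05))
    if name == "rfe":
        return RFE(
            estimator=_selector_estimator(random_state),
            n_features_to_select=0.5,
            step=v.get("step", 0.5),
        )
    if name == "select_from_model":
        return SelectFromModel(
            estimator=_selector_estimator(random_state),
            threshold=v.get("threshold", "mean"),
        )
    if name == "logistic_regression":
        return LogisticRegression(
            C=v.get("C", 1.0), penalty=v.get("penalty", "l2"), max_iter=1000
        )
    if name == "decision_tree":
        return DecisionTreeClassifier(
            criterion=v.get("criterion", "gini"),
            max_depth=v.get("max_depth", None),
            min_samples_leaf=v.get("min_samples_leaf", 1),
            random_state=random_state,
        )
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=v.get("n_estimators", 100),
            criterion=v.get("criterion", "gini"),
            max_features=v.get("max_features", "sqrt"),
            min_samples_leaf=v.get("min_samples_leaf", 1),
            random_state=random_state,
        )
    if name == "extra_trees":
        return ExtraTreesClassifier(
            n_estimators=v.get("n_estimators", 100),
            criterion=v.get("criterion", "gini"),
            max_features=v.get("max_features", "sqrt"),
            min_samples_leaf=v.get("min_samples_leaf", 1),
            random_state=random_state,
        )
    if name == "bernoulli_nb":
        return BernoulliNB(
            alpha=v.get("alpha", 1.0),
            binarize=v.get("binarize", 0.0),
            fit_prior=v.get("fit_prior", True),
        )
    if name == "multinomial_nb":
        return MultinomialNB(alpha=v.get("alpha", 1.0), fit_prior=v.get("fit_prior", True))
    if name == "k_neighbors":
        return KNeighborsClassifier(
            n_neighbors=v.get("n_neighbors", 5),
            weights=v.get("weights", "uniform"),
            p=v.get("p", 2),
        )
    if name == "gaussian_nb":
        return GaussianNB()
    if name == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=v.get("n_estimators", 100),
            learning_rate=v.get("learning_rate", 0.1),
            max_depth=v.get("max_depth", 3),
            random_state=random_state,
        )
    if name == "linear_svc":
        return LinearSVC(
            C=v.get("C", 1.0), loss=v.get("loss", "squared_hinge"), dual="auto"
        )
    if name == "mlp":
        return MLPClassifier(
            alpha=v.get("alpha", 1e-4),
            learning_rate_init=v.get("learning_rate_init", 0.001),
            max_iter=300,
            random_state=random_state,
        )
    raise KeyError(f"no builder for operator {name!r}")


# ---------------------------------------------------------------------------
# Fit / apply contract
# ---------------------------------------------------------------------------

WIDTH_PRESERVING = {
    "standard_scaler",
    "min_max_scaler",
    "max_abs_scaler",
    "binarizer",
    "normalizer",
}


@dataclass
class FittedOperator:
    """An operator with learned state, frozen after fit."""

    spec: OperatorSpec
    values: dict
    estimator: object

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Apply the learned transformation; never refits."""
        import warnings

        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                out = self.estimator.transform(X)
            except EmptyFeatureSetError:
                raise
            except Exception as exc:  # structured failure for the evaluator
                raise OperatorError(f"{self.spec.name} apply failed: {exc}") from exc
        out = np.asarray(out, dtype=float)
        if out.ndim == 1:
            out = out[:, None]
        return out

    @property
    def selected_indices(self):
        if hasattr(self.estimator, "get_support"):
            return np.flatnonzero(self.estimator.get_support())
        return None


def fit_operator(
    spec: OperatorSpec,
    values: dict,
    X_train: np.ndarray,
    y_train: np.ndarray | None = None,
    random_state: int = 0,
) -> FittedOperator:
    """Fit one operator on training data only (structured failures)."""
    import warnings

    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[1] == 0:
        raise EmptyFeatureSetError(f"{spec.name}: empty feature set on input")
    estimator = build_estimator(spec.name, values, random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            estimator.fit(X_train, y_train)
        except Exception as exc:
            if spec.kind == "selector":
                raise EmptyFeatureSetError(
                    f"{spec.name} produced no usable feature set: {exc}"
                ) from exc
            raise OperatorError(f"{spec.name} fit failed: {exc}") from exc
    fitted = FittedOperator(spec, dict(values), estimator)
    if spec.kind == "selector":
        kept = fitted.selected_indices
        if kept is not None and len(kept) == 0:
            raise EmptyFeatureSetError(f"{spec.name} kept zero features")
    return fitted


def _output_names(spec: OperatorSpec, in_names: list, out_width: int) -> list:
    if spec.name in WIDTH_PRESERVING and out_width == len(in_names):
        return list(in_names)
    if spec.name == "zero_counts":
        return list(in_names) + ["zero_count", "non_zero_count"]
    if spec.name == "stacking_estimator":
        base = spec.values_tag if hasattr(spec, "values_tag") else spec.name
        return list(in_names) + [f"{base}_pred", f"{base}_proba_0", f"{base}_proba_1"]
    return [f"{spec.name}_{j}" for j in range(out_width)]


def _as_table(spec: OperatorSpec, values: np.ndarray, in_table: FeatureTable) -> FeatureTable:
    names = _output_names(spec, in_table.feature_names, values.shape[1])
    if spec.name in ("binarizer", "one_hot_encoder"):
        kinds = ["binary"] * values.shape[1]
    elif spec.name in WIDTH_PRESERVING and values.shape[1] == in_table.n_features:
        kinds = ["continuous"] * values.shape[1]
    else:
        kinds = ["continuous"] * values.shape[1]
    return FeatureTable(
        values=values,
        feature_names=names,
        feature_kinds=kinds,
        sample_ids=list(in_table.sample_ids),
    )


def fit_apply_transformer(
    spec: OperatorSpec,
    values: dict,
    train: FeatureTable,
    apply_to: FeatureTable,
    random_state: int = 0,
) -> FeatureTable:
    """Fit a transformer/constructor on ``train`` and apply it to ``apply_to``.

    Statistics are learned from ``train`` only; the returned table carries
    deterministically regenerated feature names when the width changes.
    """
    if spec.kind not in ("transformer", "constructor"):
        raise ValueError(f"{spec.name} is not a transformer/constructor")
    if spec.name == "stacking_estimator":
        raise ValueError("use construct_stacked_features for the stacking estimator")
    fitted = fit_operator(spec, values, train.values, None, random_state)
    out = fitted.apply(apply_to.values)
    table = _as_table(spec, out, apply_to)
    if spec.name == "binarizer":
        table.feature_kinds = ["binary"] * table.n_features
    return table


def fit_apply_selector(
    spec: OperatorSpec,
    values: dict,
    train: LabeledDataset,
    apply_to: FeatureTable,
    random_state: int = 0,
):
    """Fit a selector on labelled training data, subset ``apply_to`` columns.

    Returns ``(table, selected_indices)``.
    """
    if spec.kind != "selector":
        raise ValueError(f"{spec.name} is not a selector")
    fitted = fit_operator(spec, values, train.table.values, train.labels, random_state)
    kept = fitted.selected_indices
    out = fitted.apply(apply_to.values)
    table = FeatureTable(
        values=out,
        feature_names=[apply_to.feature_names[j] for j in kept],
        feature_kinds=[apply_to.feature_kinds[j] for j in kept],
        sample_ids=list(apply_to.sample_ids),
    )
    return table, kept


def construct_stacked_features(
    classifier_values: dict,
    train: LabeledDataset,
    apply_to: FeatureTable,
    random_state: int = 0,
) -> FeatureTable:
    """Append an internal classifier's prediction and class probabilities.

    Binary labels yield exactly 3 appended columns; the internal classifier
    is fit on ``train`` only.
    """
    spec = OperatorSpec(
        "stacking_estimator", "constructor", {"classifier": ("logistic_regression",)}
    )
    fitted = fit_operator(
        spec, classifier_values, train.table.values, train.labels, random_state
    )
    out = fitted.apply(apply_to.values)
    names = list(apply_to.feature_names) + ["stacked_pred", "stacked_proba_0", "stacked_proba_1"]
    kinds = list(apply_to.feature_kinds) + ["binary", "continuous", "continuous"]
    return FeatureTable(
        values=out,
        feature_names=names,
        feature_kinds=kinds,
        sample_ids=list(apply_to.sample_ids),
    )
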
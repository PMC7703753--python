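"""Scikit-learn style estimators over the pipeline-tree machinery.

:class:`TreePipelineClassifier` wraps one fixed expression tree as an
ordinary classifier; :class:`GeneticPipelineClassifier` runs the full
genetic-programming search inside ``fit`` (optionally under the multi-seed
representative-model protocol) and then behaves as the best discovered
pipeline.  Both follow the sklearn contract (``get_params`` /
``set_params``, fitted attributes with a trailing underscore) and compose
with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .data_model import FeatureTable, LabeledDataset
from .gp_engine import GPConfig, representative_model
from .operator_catalog import full_configuration, reduced_configuration
from .pipeline_tree import PipelineTree, fit_pipeline


def dataset_from_arrays(X, y=None, feature_names=None, profile_id="other"):
    """Build a :class:`LabeledDataset` (or bare table) from numpy arrays."""
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    table = FeatureTable(
        values=X,
        feature_names=list(feature_names),
        feature_kinds=["continuous"] * X.shape[1],
        sample_ids=[f"s{i:06d}" for i in range(X.shape[0])],
    )
    if y is None:
        return table
    return LabeledDataset(table, np.asarray(y, dtype=int), profile_id)


def _catalog_for_mode(mode: str):
    return full_configuration() if mode == "full" else reduced_configuration(mode)


class TreePipelineClassifier(ClassifierMixin, BaseEstimator):
    """Classifier defined by a fixed pipeline expression tree.

    Parameters
    ----------
    tree : PipelineTree or str
        The pipeline, either as an object or in its text serialization.
    mode : str, default "full"
        Catalog configuration the tree's operator names resolve against
        ("full" or a classifier name for a reduced catalog).
    random_state : int, default 0
    """

    def __init__(self, tree=None, mode="full", random_state=0):
        self.tree = tree
        self.mode = mode
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.tree is None:
            raise ValueError("tree must be provided")
        tree = (
            PipelineTree.deserialize(self.tree)
            if isinstance(self.tree, str)
            else self.tree
        )
        self.catalog_ = _catalog_for_mode(self.mode)
        tree.validate(self.catalog_)
        self.tree_ = tree.clone()
        data = dataset_from_arrays(X, y)
        self.fitted_pipeline_ = fit_pipeline(
            self.tree_, data, self.catalog_, self.random_state
        )
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "fitted_pipeline_")
        X = check_array(X)
        return self.fitted_pipeline_.predict(dataset_from_arrays(X))

    def decision_function(self, X):
        check_is_fitted(self, "fitted_pipeline_")
        X = check_array(X)
        return self.fitted_pipeline_.scores(dataset_from_arrays(X))


class GeneticPipelineClassifier(ClassifierMixin, BaseEstimator):
    """AutoML classifier: genetic-programming search over pipeline trees.

    ``fit`` evolves a population of expression-tree pipelines under
    ``n_folds``-fold CV balanced-accuracy fitness with Pareto parsimony
    pressure, optionally repeated under ``n_seeds`` random seeds, and refits
    the best pipeline on the full training data.

    Parameters mirror the search protocol: ``population_size`` pipelines
    evolved for ``generations`` generations (or until ``time_budget``
    seconds), crossover/mutation applied to the configured fractions of each
    new generation, 10% elitism, three-way parsimony tournaments.
    """

    def __init__(
        self,
        mode="full",
        population_size=50,
        generations=10,
        n_seeds=1,
        crossover_rate=0.1,
        mutation_rate=0.9,
        max_operators=10,
        n_folds=10,
        time_budget=None,
        n_jobs=1,
        random_state=0,
    ):
        self.mode = mode
        self.population_size = population_size
        self.generations = generations
        self.n_seeds = n_seeds
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.max_operators = max_operators
        self.n_folds = n_folds
        self.time_budget = time_budget
        self.n_jobs = n_jobs
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        data = dataset_from_arrays(X, y)
        self.catalog_ = _catalog_for_mode(self.mode)
        config = GPConfig(
            population_size=self.population_size,
            max_generations=self.generations,
            time_budget=self.time_budget,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            n_folds=self.n_folds,
            seed=self.random_state,
            max_operators=self.max_operators,
            n_jobs=self.n_jobs,
        )
        result = representative_model(data, self.catalog_, config, self.n_seeds)
        self.search_result_ = result
        self.best_tree_ = result.best_tree
        self.best_record_ = result.best_record
        self.pareto_front_ = result.pareto_archive
        self.history_ = result.history
        self.fitted_pipeline_ = fit_pipeline(
            self.best_tree_, data, self.catalog_, self.random_state
        )
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "fitted_pipeline_")
        X = check_array(X)
        return self.fitted_pipeline_.predict(dataset_from_arrays(X))

    def decision_function(self, X):
        check_is_fitted(self, "fitted_pipeline_")
        X = check_array(X)
        return self.fitted_pipeline_.scores(dataset_from_arrays(X))
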
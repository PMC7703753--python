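"""Metric oracles, grid-search baselines, combinatorics, PFI and ablation."""

import itertools
import math

import numpy as np
import pytest

from evopipe import (
    DataError,
    balanced_accuracy,
    classification_report,
    evaluate_on_splits,
    grid_search,
    grid_size,
    head_ablation,
    permutation_importance,
    preprocessor_search_space,
    stratified_split,
)
from evopipe.evaluation import make_chain_pipeline
from evopipe.pipeline_tree import fit_pipeline

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def roc_auc_oracle(y, s):
    """Exhaustive pair counting; ties contribute 1/2."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def counts_oracle(y, p):
    tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
    fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
    fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
    tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
    return tp, fp, fn, tn


class TestBalancedAccuracy:
    def test_worked_example(self):
        assert balanced_accuracy([1, 1, 1, 1, 0, 0], [1, 1, 1, 0, 0, 1]) == pytest.approx(
            0.625
        )

    def test_perfect_predictions(self):
        assert balanced_accuracy([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_single_class_truth_is_error(self):
        with pytest.raises(DataError):
            balanced_accuracy([1, 1, 1], [1, 0, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_accuracy_on_balanced_data(self, seed):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * 10)
        p = rng.integers(0, 2, size=20)
        assert balanced_accuracy(y, p) == pytest.approx(float(np.mean(y == p)))


class TestClassificationReport:
    def test_perfect_ranking_roc_one(self):
        m = classification_report([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2])
        assert m.roc_auc == 1.0

    def test_half_concordant_pairs(self):
        # 2 of 4 pairs correctly ordered
        y, s = [1, 1, 0, 0], [0.9, 0.2, 0.3, 0.8]
        m = classification_report(y, [1, 0, 0, 1], s)
        assert m.roc_auc == pytest.approx(roc_auc_oracle(y, s)) == 0.5

    def test_all_positive_predictions(self):
        m = classification_report([1, 1, 0, 0], [1, 1, 1, 1], [0.6, 0.6, 0.6, 0.6])
        assert m.recall == 1.0
        assert m.precision == 0.5

    def test_confusion_convention_and_row_sums(self):
        m = classification_report([0, 0, 1, 1, 1], [0, 1, 1, 1, 0], [0.1, 0.9, 0.8, 0.7, 0.2])
        assert m.confusion.tolist() == [[1, 1], [1, 2]]
        np.testing.assert_allclose(m.normalized_confusion().sum(axis=1), 1.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_roc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        y = rng.integers(0, 2, size=n)
        if len(set(y)) < 2:
            y[:2] = [0, 1]
        s = np.round(rng.random(n), 1)  # coarse scores force ties
        m = classification_report(y, y, s)
        assert m.roc_auc == pytest.approx(roc_auc_oracle(y, s), abs=1e-12)

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda s: 3 * s + 2, lambda s: s**3]
    )
    def test_curve_metrics_invariant_to_monotone_transform(self, transform):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s = rng.random(30)
        base = classification_report(y, y, s)
        moved = classification_report(y, y, transform(s))
        assert moved.roc_auc == pytest.approx(base.roc_auc, abs=1e-12)
        assert moved.pr_auc == pytest.approx(base.pr_auc, abs=1e-12)


# ---------------------------------------------------------------------------
# Combinatorics
# ---------------------------------------------------------------------------

class TestGridSize:
    def test_five_by_ten_is_one_hundred_thousand(self):
        grid = {f"h{i}": list(range(10)) for i in range(5)}
        assert grid_size(grid) == 100_000

    def test_empty_grid_single_default(self):
        assert grid_size({}) == 1

    def test_single_parameter(self):
        assert grid_size({"a": [1, 2, 3]}) == 3


def arrangements_oracle(p):
    """Enumerate ordered chains using each pre-processor at most once."""
    items = list(range(p))
    total = 0
    for k in range(p + 1):
        total += sum(1 for _ in itertools.permutations(items, k))
    return total


class TestPreprocessorSearchSpace:
    def test_no_preprocessors_is_identity(self):
        assert preprocessor_search_space(12345, 0) == 12345

    def test_two_preprocessors_enumeration(self):
        # {empty, A, B, AB, BA} -> 5 chains
        assert preprocessor_search_space(1, 2) == 5 == arrangements_oracle(2)

    @pytest.mark.parametrize("p", range(7))
    def test_matches_enumeration_oracle(self, p):
        assert preprocessor_search_space(1, p) == arrangements_oracle(p)

    def test_recurrence(self):
        # a(p) = p * a(p-1) + 1
        for p in range(1, 12):
            assert preprocessor_search_space(1, p) == p * preprocessor_search_space(
                1, p - 1
            ) + 1

    def test_ten_preprocessors_on_ensemble_grid(self):
        assert preprocessor_search_space(100_000, 10) == 986_410_100_000


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gs_split():
    rng = np.random.default_rng(21)
    y = np.array([0, 1] * 40)
    X = rng.standard_normal((80, 6))
    X[:, 0] += y * 2.0
    ds = make_dataset(X, y)
    return stratified_split(ds, 0.25, seed=0)


class TestGridSearch:
    def test_cartesian_combination_count(self, full_catalog, gs_split):
        res = grid_search(
            "decision_tree",
            {"max_depth": [2, 3], "criterion": ["gini", "entropy", "log_loss"]},
            gs_split.train,
            gs_split.validation,
            full_catalog,
            n_folds=5,
            seed=0,
        )
        assert res.n_combinations == 6

    def test_composed_chain_complexity_three(self, full_catalog, gs_split):
        res = grid_search(
            "logistic_regression",
            {"C": [1.0]},
            gs_split.train,
            gs_split.validation,
            full_catalog,
            n_folds=5,
            seed=0,
            preprocessor_chain=[("standard_scaler", {}), ("rfe", {"step": 0.5})],
        )
        assert res.report.complexity == 3

    def test_single_point_grid(self, full_catalog, gs_split):
        res = grid_search(
            "logistic_regression",
            {"C": [10.0]},
            gs_split.train,
            gs_split.validation,
            full_catalog,
            n_folds=5,
            seed=0,
        )
        assert res.best_values == {"C": 10.0}

    def test_empty_domain_is_error(self, full_catalog, gs_split):
        with pytest.raises(ValueError, match="empty domain"):
            grid_search(
                "logistic_regression",
                {"C": []},
                gs_split.train,
                gs_split.validation,
                full_catalog,
            )


# ---------------------------------------------------------------------------
# Permutation feature importance
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def threshold_model():
    """Depth-1 tree using only feature 0; features 1-2 ignored; feature 3 constant."""
    rng = np.random.default_rng(33)
    y = np.array([0, 1] * 50)
    X = rng.standard_normal((100, 4))
    X[:, 0] = y * 5.0 + rng.standard_normal(100) * 0.1
    X[:, 3] = 2.5
    ds = make_dataset(X, y)
    from evopipe import full_configuration

    catalog = full_configuration()
    tree = make_chain_pipeline(
        "decision_tree", {"criterion": "gini", "max_depth": 1, "min_samples_leaf": 1}
    )
    fitted = fit_pipeline(tree, ds, catalog, 0)
    return fitted, ds


class TestPermutationImportance:
    def test_constant_feature_scores_exactly_zero(self, threshold_model):
        fitted, ds = threshold_model
        pfi = permutation_importance(fitted, ds, n_repeats=10, seed=0)
        assert np.all(pfi.per_repeat[3] == 0.0)

    def test_model_ignored_features_score_exactly_zero(self, threshold_model):
        # a depth-1 stump never consults features 1 and 2
        fitted, ds = threshold_model
        pfi = permutation_importance(fitted, ds, n_repeats=10, seed=0)
        assert np.all(pfi.per_repeat[1] == 0.0)
        assert np.all(pfi.per_repeat[2] == 0.0)

    def test_informative_feature_decrease_near_baseline_minus_half(self, threshold_model):
        # permuting the only used feature makes it label-independent: the
        # expected permuted score is 1/2
        fitted, ds = threshold_model
        pfi = permutation_importance(fitted, ds, n_repeats=100, seed=1)
        b = pfi.baseline_score
        dec = pfi.per_repeat[0]
        se = dec.std(ddof=1) / math.sqrt(len(dec))
        assert abs(dec.mean() - (b - 0.5)) <= 3 * max(se, 1e-6)

    def test_mean_equals_per_repeat_average(self, threshold_model):
        fitted, ds = threshold_model
        pfi = permutation_importance(fitted, ds, n_repeats=7, seed=2)
        np.testing.assert_allclose(
            pfi.mean_decrease, pfi.per_repeat.mean(axis=1), atol=1e-12
        )

    def test_ranking_stable_for_fixed_seed(self, threshold_model):
        fitted, ds = threshold_model
        a = permutation_importance(fitted, ds, n_repeats=5, seed=9).ranking()
        b = permutation_importance(fitted, ds, n_repeats=5, seed=9).ranking()
        assert a == b

    def test_nonpositive_repeats_is_error(self, threshold_model):
        fitted, ds = threshold_model
        with pytest.raises(ValueError):
            permutation_importance(fitted, ds, n_repeats=0, seed=0)


# ---------------------------------------------------------------------------
# Head ablation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def split():
    # non-negative features (concentration-like), signal in column 0
    rng = np.random.default_rng(44)
    y = np.array([0, 1] * 40)
    X = rng.uniform(0.0, 1.0, size=(80, 6))
    X[:, 0] += y * 1.5
    return stratified_split(make_dataset(X, y), 0.25, seed=1)


class TestHeadAblation:

    def test_complexity_five_yields_5_4_3_2_1(self, full_catalog, split):
        tree = make_chain_pipeline(
            "bernoulli_nb",
            {"alpha": 1.0, "binarize": 0.0, "fit_prior": True},
            [
                ("rfe", {"step": 0.5}),
                ("stacking_estimator", {"classifier": "logistic_regression"}),
                ("stacking_estimator", {"classifier": "multinomial_nb"}),
                ("standard_scaler", {}),
            ],
        )
        table = head_ablation(tree, split.train, split.validation, full_catalog, seed=0)
        assert [rep.complexity for _, rep, _ in table.rows] == [5, 4, 3, 2, 1]
        assert [n for n, _, _ in table.rows] == [0, 1, 2, 3, 4]

    def test_removal_starts_at_input_end(self, full_catalog, split):
        tree = make_chain_pipeline(
            "decision_tree",
            {"criterion": "gini", "max_depth": 3, "min_samples_leaf": 1},
            [("rfe", {"step": 0.5}), ("standard_scaler", {})],
        )
        table = head_ablation(tree, split.train, split.validation, full_catalog, seed=0)
        # after removing one operator the RFE (input end) is gone
        assert "rfe" not in table.rows[1][2]
        assert "standard_scaler" in table.rows[1][2]

    def test_bare_classifier_single_row_matches_report(self, full_catalog, split):
        tree = make_chain_pipeline(
            "decision_tree", {"criterion": "gini", "max_depth": 3, "min_samples_leaf": 1}
        )
        table = head_ablation(tree, split.train, split.validation, full_catalog, seed=3)
        assert len(table.rows) == 1
        direct = evaluate_on_splits(
            tree, split.train, split.validation, full_catalog, seed=3
        )
        assert table.rows[0][1].validation.as_dict() == direct.validation.as_dict()

    def test_full_pipeline_row_matches_unablated_report(self, full_catalog, split):
        tree = make_chain_pipeline(
            "logistic_regression",
            {"C": 1.0, "penalty": "l2"},
            [("standard_scaler", {}), ("select_percentile", {"percentile": 50})],
        )
        table = head_ablation(tree, split.train, split.validation, full_catalog, seed=5)
        direct = evaluate_on_splits(
            tree, split.train, split.validation, full_catalog, seed=5
        )
        assert table.rows[0][1].validation.as_dict() == direct.validation.as_dict()
        assert table.rows[0][1].training.as_dict() == direct.training.as_dict()

    def test_positive_rescaling_row_invariance_for_threshold_zero_nb(
        self, full_catalog, split
    ):
        # max-abs scaling preserves signs, so removing it before a
        # threshold-0 Bernoulli NB leaves every metric unchanged
        tree = make_chain_pipeline(
            "bernoulli_nb",
            {"alpha": 1.0, "binarize": 0.0, "fit_prior": True},
            [("max_abs_scaler", {})],
        )
        table = head_ablation(tree, split.train, split.validation, full_catalog, seed=0)
        with_scaler = table.rows[0][1]
        without_scaler = table.rows[1][1]
        assert with_scaler.validation.balanced_accuracy == pytest.approx(
            without_scaler.validation.balanced_accuracy
        )
        assert with_scaler.validation.confusion.tolist() == (
            without_scaler.validation.confusion.tolist()
        )
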
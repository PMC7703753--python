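import numpy as np
import pytest

from evopipe import (
    FeatureTable,
    LabeledDataset,
    full_configuration,
    reduced_configuration,
)


@pytest.fixture(scope="session")
def full_catalog():
    return full_configuration()


@pytest.fixture(scope="session")
def dt_catalog():
    return reduced_configuration("decision_tree")


def make_table(values, kinds=None, names=None):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return FeatureTable(
        values=values,
        feature_names=names or [f"f{j}" for j in range(d)],
        feature_kinds=kinds or ["continuous"] * d,
        sample_ids=[f"s{i}" for i in range(n)],
    )


def make_dataset(values, labels, kinds=None):
    return LabeledDataset(make_table(values, kinds), np.asarray(labels, dtype=int))


@pytest.fixture
def separable_dataset():
    """40 samples, 1 perfectly separating feature + 3 noise features."""
    rng = np.random.default_rng(7)
    y = np.array([0, 1] * 20)
    X = rng.standard_normal((40, 4))
    X[:, 0] = y * 4.0 + rng.standard_normal(40) * 0.1
    return make_dataset(X, y)


@pytest.fixture
def imbalanced_dataset():
    """60/40 class imbalance, pure noise features."""
    rng = np.random.default_rng(11)
    y = np.array([1] * 60 + [0] * 40)
    X = rng.standard_normal((100, 5))
    return make_dataset(X, y)
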
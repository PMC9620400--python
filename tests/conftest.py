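"""Shared fixtures: one synthetic study dataset and one trained ensemble.

The heavy artifacts (a 5,000-record planted-rule dataset with the default
imbalanced class proportions, and the ensemble trained on its first 4,000
records) are session-scoped so the classifier, importance, design and
acceptance tests all reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from agndesign.curation import CLASS_ORDER
from agndesign.ensemble import TrainingConfig, train_ensemble
from agndesign.features import featurize
from agndesign.synthetic import default_rules, generate_dataset

DATASET_SEED = 20260
TRAIN_SEED = 7
N_RECORDS = 5000
N_TRAIN = 4000


@pytest.fixture(scope="session")
def dataset():
    """Planted-rule dataset: n=5000, zero label noise, ~10:1 FarRed:NIR."""
    return generate_dataset(default_rules(), n=N_RECORDS, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def features_and_labels(dataset):
    X, _ = featurize(dataset.sequences)
    return X.astype(float), dataset.labels


@pytest.fixture(scope="session")
def split(features_and_labels):
    X, labels = features_and_labels
    return (X[:N_TRAIN], labels[:N_TRAIN]), (X[N_TRAIN:], labels[N_TRAIN:])


@pytest.fixture(scope="session")
def model(split):
    (X_tr, y_tr), _ = split
    return train_ensemble(X_tr, y_tr, TrainingConfig(seed=TRAIN_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sequences(rng: np.random.Generator, n: int, L: int = 10) -> list[str]:
    from agndesign.features import decode

    return [decode(row) for row in rng.integers(0, 4, size=(n, L))]
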
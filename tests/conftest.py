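from __future__ import annotations

import numpy as np
import pytest

from resamplebench.datasets import LabeledDataset


def make_random_dataset(
    rng: np.random.Generator,
    n_min: int = 8,
    n_maj: int = 25,
    n_features: int = 3,
    spread: float = 1.5,
) -> LabeledDataset:
    """Two overlapping Gaussian blobs; class 1 is the minority."""
    X_maj = rng.normal(0.0, 1.0, size=(n_maj, n_features))
    X_min = rng.normal(spread, 1.0, size=(n_min, n_features))
    X = np.vstack([X_maj, X_min])
    y = np.concatenate([np.zeros(n_maj, int), np.ones(n_min, int)])
    perm = rng.permutation(len(y))
    return LabeledDataset(X=X[perm], y=y[perm])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230727)


@pytest.fixture
def blob_data(rng) -> LabeledDataset:
    return make_random_dataset(rng)


@pytest.fixture
def separated_data(rng) -> LabeledDataset:
    """Two tight, far-apart clusters: no cleaning rule should fire."""
    return make_random_dataset(rng, n_min=10, n_maj=20, spread=50.0)


def oneD(values, labels) -> LabeledDataset:
    return LabeledDataset(
        X=np.asarray(values, float).reshape(-1, 1), y=np.asarray(labels, int)
    )
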
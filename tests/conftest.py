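"""Shared fixtures: small synthetic datasets and cheap trained models."""

from __future__ import annotations

import numpy as np
import pytest

from logituq.backbone import TrainConfig
from logituq.bnn import RadialBNNClassifier
from logituq.ensemble import DeepEnsembleClassifier
from logituq.preprocessing import CohortEncoder
from logituq.sngp import SNGPClassifier
from logituq.synthetic import ToyLaw, sample_toy_test, sample_toy_train


@pytest.fixture(scope="session")
def toy_law() -> ToyLaw:
    return ToyLaw(seed=11)


@pytest.fixture(scope="session")
def toy_train(toy_law):
    return sample_toy_train(toy_law)


@pytest.fixture(scope="session")
def toy_test(toy_law):
    return sample_toy_test(toy_law)


@pytest.fixture(scope="session")
def toy_arrays(toy_train):
    """Small encoded train/val arrays for fast model fitting."""
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(toy_train.frame))[:900]
    tr, val = np.sort(idx[:720]), np.sort(idx[720:])
    enc = CohortEncoder().fit(toy_train, tr)
    m_tr = enc.transform(toy_train, tr)
    m_val = enc.transform(toy_train, val)
    return {
        "encoder": enc,
        "X_tr": m_tr.X,
        "y_tr": m_tr.y.astype(float),
        "X_val": m_val.X,
        "y_val": m_val.y.astype(float),
    }


@pytest.fixture(scope="session")
def fast_config() -> TrainConfig:
    return TrainConfig(hidden=(16, 16), max_epochs=15, patience=3, batch_size=128)


@pytest.fixture(scope="session")
def small_ensemble(toy_arrays, fast_config):
    return DeepEnsembleClassifier(
        toy_arrays["X_tr"],
        toy_arrays["y_tr"],
        toy_arrays["X_val"],
        toy_arrays["y_val"],
        n_members=5,
        config=fast_config,
        seed=1,
    ).fit()


@pytest.fixture(scope="session")
def small_bnn(toy_arrays, fast_config):
    return RadialBNNClassifier(
        toy_arrays["X_tr"],
        toy_arrays["y_tr"],
        toy_arrays["X_val"],
        toy_arrays["y_val"],
        config=fast_config,
        seed=1,
    ).fit()


@pytest.fixture(scope="session")
def small_sngp(toy_arrays):
    cfg = TrainConfig(hidden=(16, 16), residual=True, max_epochs=15, patience=3)
    return SNGPClassifier(
        toy_arrays["X_tr"],
        toy_arrays["y_tr"],
        toy_arrays["X_val"],
        toy_arrays["y_val"],
        config=cfg,
        n_rff=256,
        seed=1,
    ).fit()
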
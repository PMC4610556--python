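"""Shared fixtures: expensive trained artefacts are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from drowsefuse import recognizer as rec
from drowsefuse import synthetic_data as sd
from drowsefuse.tsfnn import (
    TrainConfig,
    TSFNNParams,
    TSFNNStructure,
    init_from_clusters,
    predict_batch,
    pso_train,
)


@pytest.fixture(scope="session")
def worked_example():
    return sd.fixtures()


@pytest.fixture(scope="session")
def trained_bundle():
    """Both networks trained once on the standard 360-row training table."""
    table, targets = sd.generate_training_table(120, sd.SimConfig(seed=7))
    return rec.train_bundle(
        table, targets, train_cfg=TrainConfig(seed=3, max_iters=2000)
    )


@pytest.fixture(scope="session")
def pso_recovery():
    """Retrain a 2x2x2 network on noiseless data from a known generator.

    Returns (generator params, trained params, fitness trace, dataset).
    """
    rng = np.random.default_rng(42)
    generator = TSFNNParams(
        centers=np.array([[0.2, 0.8], [0.3, 0.7]]),
        widths=np.full((2, 2), 0.3),
        weights=rng.uniform(-1.0, 1.0, (2, 2)),
    )
    X = rng.uniform(0.0, 1.0, (200, 2))
    Y = predict_batch(generator, X)
    init = init_from_clusters(np.array([[0.25, 0.35], [0.75, 0.65]]), 2, seed=1)
    structure = TSFNNStructure(2, 2, 2, linguistic_values=2)
    trained, trace = pso_train(
        (X, Y), structure, init, TrainConfig(seed=5, max_iters=2000, target_fitness=1e-6)
    )
    return generator, trained, trace, (X, Y)
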
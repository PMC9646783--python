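import numpy as np
import pytest

from microstain.synthetic_data import generate_pattern_tiles
from microstain.tile_classifier import TrainingSchedule, build_model, train


@pytest.fixture(scope="session")
def separable_tiles():
    """Cleanly separable tile set: every tile carries >= 1 ring (class 1) or
    >= 1 blob (class 0); stratified train/validation split."""
    n = 200
    x = np.concatenate([generate_pattern_tiles("rings", n, 64, seed=11),
                        generate_pattern_tiles("blobs", n, 64, seed=12)])
    y = np.array([1] * n + [0] * n)
    rng = np.random.default_rng(7)
    idx = rng.permutation(2 * n)
    n_train = int(0.7 * 2 * n)
    return (x[idx[:n_train]], y[idx[:n_train]],
            x[idx[n_train:]], y[idx[n_train:]])


@pytest.fixture(scope="session")
def trained_tile_model(separable_tiles):
    """The small CNN trained once on the separable tile set (shared across
    tests that need a competent model)."""
    x_tr, y_tr, x_va, y_va = separable_tiles
    model = build_model(seed=3)
    history = train(model, x_tr, y_tr, x_va, y_va,
                    schedule=TrainingSchedule.from_scratch(), seed=3)
    return model, history
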
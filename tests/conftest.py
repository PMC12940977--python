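import numpy as np
import pytest

from ftirxai import (
    ModelConfig,
    SimulationConfig,
    WavenumberGrid,
    build_model,
    generate_dataset,
    train_classifier,
)

# a short grid with the canonical span, for fast unit tests
SMALL_GRID = WavenumberGrid(start=650.0, stop=3775.0, n_points=512)

SMALL_MODEL = ModelConfig(
    n_input=512,
    conv_blocks=((4, 5, 4), (8, 5, 4)),
    kan_hidden=8,
    epochs=30,
    seed=3,
)


@pytest.fixture(scope="session")
def small_grid():
    return SMALL_GRID


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(seed=11, n_spectra=160, target_group="nitriles")
    return generate_dataset(config=cfg, grid=SMALL_GRID)


@pytest.fixture(scope="session")
def small_trained(small_dataset):
    """A quickly trained nitrile classifier on the short grid."""
    model = build_model(SMALL_MODEL, target_group="nitriles")
    model, log = train_classifier(model, small_dataset, SMALL_MODEL)
    assert log[-1]["holdout_accuracy"] >= 0.8, "fixture model failed to train"
    return model
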
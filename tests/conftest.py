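"""Shared fixtures: small grids and a quickly trained phantom model."""

import numpy as np
import pytest

from petpde import (
    Grid2D,
    PhantomSpec,
    Quantity,
    ScalarField2D,
    generate_dataset,
)
from petpde.nn import TrainingConfig, train


@pytest.fixture
def grid8() -> Grid2D:
    return Grid2D(8, 8, 2.5, 2.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def field_of(values, spacing=2.5, quantity=Quantity.DIMENSIONLESS) -> ScalarField2D:
    values = np.asarray(values, dtype=float)
    grid = Grid2D(values.shape[0], values.shape[1], spacing, spacing)
    return ScalarField2D(grid, values, quantity)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Quarter-size phantoms for fast training tests."""
    return PhantomSpec(grid=Grid2D(32, 32, 2.5, 2.5), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec, 20)


@pytest.fixture(scope="session")
def quick_model(small_dataset):
    """A briefly trained model on small phantoms, reused across tests."""
    tcfg = TrainingConfig(max_epochs=16, patience=16, seed=0)
    return train(small_dataset.train, small_dataset.val, tcfg=tcfg)
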
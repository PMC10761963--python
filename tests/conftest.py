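import logging

import numpy as np
import pytest

import lvfield as lv

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def standard_dataset() -> lv.SimulatedDataset:
    """The standard validation fixture: 20 samples x 306 binary traits on a
    random tree, coordinates random-walked from a planted centre at the
    origin, 10% of cells masked at random."""
    return lv.simulate_dataset(
        seed=0, sim_params=lv.SimParams(missing_rate=0.10)
    )


@pytest.fixture(scope="session")
def standard_results(standard_dataset) -> lv.DispersalResults:
    return lv.DispersalModel.from_simulated(standard_dataset).fit()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_trait_matrix(
    rng: np.random.Generator, n: int = 12, p: int = 40, missing: float = 0.0
) -> lv.TraitMatrix:
    values = (rng.random((n, p)) < 0.5).astype(float)
    mask = rng.random((n, p)) < missing
    return lv.TraitMatrix(
        [f"s{i}" for i in range(n)], [f"t{j}" for j in range(p)], values, mask
    )


def random_coords(rng: np.random.Generator, n: int = 12) -> lv.CoordinateTable:
    return lv.CoordinateTable(
        [f"s{i}" for i in range(n)],
        rng.uniform(-20, 20, n),
        rng.uniform(-15, 15, n),
    )
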
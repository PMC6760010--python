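import warnings

import numpy as np
import pytest

import pitsc
from pitsc import threshold


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def nine_type():
    """Nine pituitary cell types, 100 cells/type/sex, no doublets/cycling."""
    config = pitsc.pituitary_config(
        n_cells_per_type=100, seed=2, doublet_rate=0.0, cycling_fraction=0.0
    )
    matrix, truth = pitsc.generate_dataset(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def nine_type_norm(nine_type):
    _, matrix, _ = nine_type
    return pitsc.normalize(matrix)


@pytest.fixture(scope="session")
def nine_type_calls(nine_type_norm):
    return threshold.expression_calls(nine_type_norm)


@pytest.fixture(scope="session")
def doublet_scenario():
    """Two well-separated types, 500 cells each, 2% planted heterotypic doublets."""
    config = pitsc.pituitary_config(
        n_cells_per_type={"E": {"F": 250, "M": 250}, "S": {"F": 250, "M": 250}},
        doublet_rate=0.02,
        cycling_fraction=0.0,
        seed=3,
    )
    return pitsc.generate_dataset(config)


@pytest.fixture(scope="session")
def cycling_scenario():
    """Nine types with a 2% cycling subpopulation carrying a 40-gene program."""
    config = pitsc.pituitary_config(
        n_cells_per_type=150, seed=5, doublet_rate=0.0, cycling_fraction=0.02
    )
    matrix, truth = pitsc.generate_dataset(config)
    norm = pitsc.normalize(matrix)
    calls = threshold.expression_calls(norm)
    return matrix, truth, norm, calls


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
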
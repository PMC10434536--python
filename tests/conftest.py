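import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from noztree import BinningSpec, CellTable, fit_tree_model

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_table() -> CellTable:
    """Four cells, two markers, hand-enumerable."""
    return CellTable(
        "tiny",
        ("a", "b"),
        np.array([[0.0, 10.0], [5.0, 20.0], [10.0, 10.0], [10.0, 20.0]]),
    )


@pytest.fixture
def toy_model():
    """A J=3, Nx=2 model fitted on 4 enumerated training cells.

    Values are chosen so that binning with Nx=2 gives the patterns
    (0,0,0), (0,1,1), (1,1,0), (1,1,1).
    """
    values = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0],
            [1.0, 1.0, 1.0],
        ]
    )
    pool = CellTable("toy_pool", ("x", "y", "z"), values)
    return fit_tree_model(pool, BinningSpec(2))


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    return CellTable(
        "random", tuple(f"m{i}" for i in range(4)), rng.normal(size=(1000, 4))
    )
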
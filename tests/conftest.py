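import numpy as np
import pytest

from scperm.core import Snapshot
from scperm.plan import GridSpec, plan_insertions
from scperm.synthetic import landscape_presets


@pytest.fixture(scope="session")
def presets():
    return landscape_presets()


@pytest.fixture(scope="session")
def reference_grid():
    """The reference design grid: 9 nm coordinate, 0.1 nm windows."""
    return GridSpec(9.0, 0.1)


@pytest.fixture(scope="session")
def reference_plan(reference_grid):
    return plan_insertions(reference_grid, 1.5, 4)


@pytest.fixture
def mixed_snapshot():
    """Tiny labeled snapshot for selection/format tests: 4 CER N, 2 CER C1,
    2 water OW atoms."""
    return Snapshot(
        resids=[1, 1, 2, 2, 3, 3, 4, 5],
        resnames=["CER", "CER", "CER", "CER", "CER", "CER", "SOL", "SOL"],
        names=["N", "C1", "N", "C1", "N", "N", "OW", "OW"],
        positions=np.arange(24, dtype=float).reshape(8, 3) / 10.0,
        box=[5.0, 5.0, 10.0],
        time=0.0,
    )
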
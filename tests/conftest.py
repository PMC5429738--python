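import numpy as np
import pytest
from hypothesis import settings

import thallus as th

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def honeycomb7():
    """The 7-cell honeycomb patch (1 central + 6 ring cells)."""
    return th.build_honeycomb(1)


@pytest.fixture
def honeycomb19():
    return th.build_honeycomb(2)


@pytest.fixture(scope="session")
def small_run():
    """One modest growth simulation shared across read-only tests."""
    cfg = th.SimulationConfig(seed=7, stop_interior_cells=60,
                              snapshot_every_divisions=40)
    return th.run_simulation(cfg)


def center_cell(t):
    """Cell whose centroid is nearest the origin (honeycomb centre)."""
    return min(t.cells, key=lambda c: float(np.hypot(*t.cell_centroid(c))))
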
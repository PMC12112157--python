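import numpy as np
import pytest
from hypothesis import settings

import lisakit as lk

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def grid22():
    return lk.grid_lattice(lk.LatticeSpec(rows=2, cols=2, times=1))


@pytest.fixture
def grid33():
    return lk.grid_lattice(lk.LatticeSpec(rows=3, cols=3, times=1))


@pytest.fixture
def strip3():
    """1x3 strip of unit squares: a path graph A-B-C under rook contiguity."""
    from shapely.geometry import box

    return [lk.AreaGeometry(aid, box(i, 0, i + 1, 1)) for i, aid in enumerate("ABC")]


@pytest.fixture
def path3_weights(strip3):
    return lk.row_normalize(lk.contiguity_weights(strip3, "rook"))


@pytest.fixture
def checkerboard22():
    return lk.checkerboard_dataset(2, 2)


def random_lattice_weights(rows, cols, rule="rook"):
    geoms = lk.grid_lattice(lk.LatticeSpec(rows=rows, cols=cols, times=1))
    return lk.contiguity_weights(geoms, rule)
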
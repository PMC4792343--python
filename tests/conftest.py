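import numpy as np
import pytest

import polycell as pc


@pytest.fixture(scope="session")
def small_tissue():
    """A 12-cell Voronoi aggregate used by several geometry tests."""
    return pc.voronoi_tissue(12, seed=1)


@pytest.fixture(scope="session")
def midsize_tissue():
    """A 20-cell aggregate for force-oracle and assembly tests."""
    return pc.voronoi_tissue(20, seed=7)


@pytest.fixture()
def unit_square_tissue():
    """One explicit unit-square cell (areas and loops known in closed form)."""
    t = pc.Tissue()
    corners = [t.new_node(p, "junction")
               for p in ([0, 0], [1, 0], [1, 1], [0, 1])]
    eids = []
    for a, b in zip(corners, corners[1:] + corners[:1]):
        eids.append(t.new_edge([a.id, b.id], 1.0).id)
    t.new_cell("cell", eids, 1.0)
    return t


@pytest.fixture(scope="session")
def hexagon_tissue():
    """A single regular hexagonal cell with six junction nodes."""
    t = pc.Tissue()
    ns = [t.new_node([np.cos(a), np.sin(a)], "junction")
          for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    eids = [t.new_edge([a.id, b.id], 1.0).id
            for a, b in zip(ns, ns[1:] + ns[:1])]
    t.new_cell("cell", eids, t_area := 1.5 * np.sqrt(3), 1.0)
    t.cells[0].target_area = t.cell_area(0)
    return t
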
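import math

import numpy as np
import pytest

import polycell as pc
from polycell.mechanics import MechAssembly


def total_energy(asm: MechAssembly, P: np.ndarray) -> float:
    d = P[asm.seg_j] - P[asm.seg_i]
    return float(np.sum(asm.seg_gamma * np.hypot(d[:, 0], d[:, 1])))


class TestTensionForces:
    def test_collinear_segments_cancel(self):
        t = pc.Tissue()
        a = t.new_node([0, 0], "junction")
        m = t.new_node([1, 0], "intermediate")
        b = t.new_node([2, 0], "junction")
        t.new_edge([a.id, m.id, b.id], 1.0)
        f = pc.assemble_tension_forces(t)
        assert np.allclose(f[m.id], 0.0, atol=1e-14)

    def test_right_angle_gives_sqrt2_bisector(self):
        t = pc.Tissue()
        a = t.new_node([1, 0], "junction")
        m = t.new_node([0, 0], "intermediate")
        b = t.new_node([0, 1], "junction")
        t.new_edge([a.id, m.id, b.id], 1.0)
        f = pc.assemble_tension_forces(t)
        assert np.hypot(*f[m.id]) == pytest.approx(math.sqrt(2))
        # force points along the interior bisector (towards (1,1))
        assert np.allclose(f[m.id] / np.hypot(*f[m.id]),
                           [1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_forces_equal_negative_energy_gradient(self, midsize_tissue):
        asm = MechAssembly(midsize_tissue)
        P = asm.positions()
        F = asm.forces(P)
        eps = 1e-6
        G = np.zeros_like(P)
        for k in range(P.shape[0]):
            for c in range(2):
                Pp, Pm = P.copy(), P.copy()
                Pp[k, c] += eps
                Pm[k, c] -= eps
                G[k, c] = -(total_energy(asm, Pp)
                            - total_energy(asm, Pm)) / (2 * eps)
        rel = np.abs(F - G).max() / np.abs(F).max()
        assert rel < 1e-6

    def test_closed_aggregate_momentum_free(self, midsize_tissue):
        asm = MechAssembly(midsize_tissue)
        F = asm.forces(asm.positions())
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)


class TestViscousMatrix:
    def test_hexagon_n_eff_six(self, hexagon_tissue):
        C, node_ids = pc.assemble_viscous_matrix(hexagon_tissue)
        area = hexagon_tissue.cell_area(0)
        expected = area / 6.0           # mu = 1, six junction nodes
        assert np.allclose(C.diagonal(), expected)

    def test_intermediate_nodes_weighted_half(self, hexagon_tissue):
        t = hexagon_tissue.copy()
        # bisect every edge: six intermediates -> n_eff = 6 + 6/2 = 9
        for eid in list(t.edges):
            e = t.edges[eid]
            a, b = e.chain
            mid = t.new_node(0.5 * (t.nodes[a].pos + t.nodes[b].pos),
                             "intermediate")
            e.chain = [a, mid.id, b]
        t.bump()
        C, _ = pc.assemble_viscous_matrix(t)
        assert np.allclose(C.diagonal(), t.cell_area(0) / 9.0)

    def test_monoline_and_stripped_polyline_agree(self, midsize_tissue):
        poly = midsize_tissue
        mono = pc.to_monoline(poly)
        Cm, ids_m = pc.assemble_viscous_matrix(mono)
        # removing all intermediate nodes must reproduce monoline dashpots
        stripped = mono.copy()
        Cs, ids_s = pc.assemble_viscous_matrix(stripped)
        assert ids_m == ids_s
        assert np.allclose(Cm.diagonal(), Cs.diagonal())

    def test_matrix_is_positive_definite(self, midsize_tissue):
        C, _ = pc.assemble_viscous_matrix(midsize_tissue)
        assert np.all(C.diagonal() > 0)


class TestAdvanceStep:
    def test_zero_tension_at_target_area_is_static(self, midsize_tissue):
        t = midsize_tissue.copy()
        for e in t.edges.values():
            e.tension = 0.0
        sol = pc.advance_step(t, pc.SimConfig(adaptive_dt=False))
        assert np.allclose(sol.displacements, 0.0, atol=1e-12)
        assert np.allclose(list(sol.cell_pressures.values()), 0.0, atol=1e-12)

    def test_area_restored_within_tolerance(self, midsize_tissue):
        t = midsize_tissue.copy()
        cfg = pc.SimConfig()
        for _ in range(200):
            pc.advance_step(t, cfg)
        for cid, cell in t.cells.items():
            drift = abs(t.cell_area(cid) - cell.target_area) / cell.target_area
            assert drift < 1e-3

    def test_pressure_sign_convention(self):
        # a lone tense cell at its target area has positive internal pressure
        t = pc.voronoi_tissue(1, seed=0)
        sol = pc.advance_step(t.copy(), pc.SimConfig())
        (p,) = sol.cell_pressures.values()
        assert p > 0

    def test_interior_of_uniform_hexagonal_patch_is_stationary(self):
        # seven regular hexagons: the central cell's nodes see symmetric
        # tension pulls and must not move
        t = _hex_patch()
        sol = pc.advance_step(t.copy(), pc.SimConfig())
        central = set(t.cell_loop(0))
        order = {nid: k for k, nid in enumerate(sol.node_ids)}
        du = np.array([sol.displacements[order[n]] for n in central])
        assert np.abs(du).max() < 1e-8


def _hex_patch() -> pc.Tissue:
    """Seven-cell honeycomb patch built from shapely hexagons."""
    from shapely.geometry import Polygon
    from polycell.voronoi import tissue_from_polygons

    def hexagon(cx, cy, r=1.0):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False) + np.pi / 6
        return Polygon(np.c_[cx + r * np.cos(ang), cy + r * np.sin(ang)])

    centers = [(0, 0)]
    for k in range(6):
        a = k * np.pi / 3
        centers.append((np.sqrt(3) * np.cos(a), np.sqrt(3) * np.sin(a)))
    polys = [hexagon(*c) for c in centers]
    return tissue_from_polygons(polys, ["cell"] * 7,
                                pc.TensionTable.uniform(1.0, ["cell"]))


class TestEquivalentShear:
    @pytest.mark.parametrize("dp,L,expected", [
        (0.0, 5.0, 0.0),
        (2.0, 3.0, 3.0),
        (2.0, 1.5, 1.5),   # halving L halves V
    ])
    def test_values(self, dp, L, expected):
        assert pc.equivalent_shear(dp, L) == pytest.approx(expected)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            pc.equivalent_shear(1.0, -1.0)


class TestLaplaceLimit:
    def test_single_cell_relaxes_to_circle(self):
        t = pc.voronoi_tissue(1, seed=0)
        cfg = pc.SimConfig(seg_max_frac=0.04, seg_min_frac=0.01,
                           n_steps=20000, record_stride=10 ** 6)
        traj = pc.run_simulation(t, pc.TensionTable.uniform(1.0, ["cell"]),
                                 cfg)
        fin = traj.final
        area = fin.cell_area(0)
        perim = sum(fin.edge_length(e) for e in fin.edges)
        assert 4 * math.pi * area / perim ** 2 > 0.999
        asm = MechAssembly(fin)
        _, lam, _ = asm.solve(asm.positions(), cfg.dt)
        R = math.sqrt(area / math.pi)
        assert -lam[0] == pytest.approx(1.0 / R, rel=0.02)
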
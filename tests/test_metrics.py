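import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import polycell as pc


class TestArcFit:
    def test_exact_circle_recovered(self):
        ang = np.linspace(0.3, 1.4, 5)
        pts = 2.0 * np.c_[np.cos(ang), np.sin(ang)]
        fit = pc.fit_circular_arc(pts)
        assert fit.radius == pytest.approx(2.0, rel=1e-9)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)
        assert abs(fit.signed_curvature) == pytest.approx(0.5, rel=1e-9)

    def test_collinear_points_are_straight(self):
        pts = np.c_[np.linspace(0, 1, 7), np.zeros(7)]
        fit = pc.fit_circular_arc(pts)
        assert fit.radius == math.inf
        assert fit.signed_curvature == 0.0

    def test_two_points_are_straight(self):
        fit = pc.fit_circular_arc([[0, 0], [1, 1]])
        assert fit.radius == math.inf

    def test_sign_convention_follows_bulge_side(self):
        ang = np.linspace(2.0, 1.0, 7)   # arc bulging left of first->last
        pts = np.c_[np.cos(ang), np.sin(ang)] + [5, 0]
        assert pc.fit_circular_arc(pts).signed_curvature > 0
        assert pc.fit_circular_arc(pts[::-1]).signed_curvature < 0

    def test_noisy_arc_matches_geometric_least_squares_oracle(self):
        rng = np.random.default_rng(11)
        ang = np.linspace(0.2, 1.9, 25)
        R = 3.7
        pts = R * np.c_[np.cos(ang), np.sin(ang)]
        pts += rng.normal(scale=0.01, size=pts.shape)
        fit = pc.fit_circular_arc(pts)

        def geom_cost(q):
            cx, cy, r = q
            return np.mean((np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r) ** 2)

        res = minimize(geom_cost, x0=[0.0, 0.0, 3.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 20000})
        assert fit.radius == pytest.approx(res.x[2], rel=1e-3)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            pc.fit_circular_arc([[0.0, 0.0]])


class TestYoungAngles:
    def test_equal_tensions_give_120(self):
        assert np.allclose(np.degrees(pc.young_angles(1, 1, 1)), 120.0)

    def test_right_angle_case(self):
        # the two unit interfaces meet at 90 deg opposite the sqrt(2) tension
        a = np.degrees(pc.young_angles(1.0, 1.0, math.sqrt(2)))
        assert a[2] == pytest.approx(90.0)
        assert a[0] == pytest.approx(135.0)
        assert a[1] == pytest.approx(135.0)

    def test_triangle_inequality_violation_rejected(self):
        with pytest.raises(ValueError):
            pc.young_angles(3.0, 1.0, 1.0)

    @given(g1=st.floats(0.2, 5), g2=st.floats(0.2, 5), g3=st.floats(0.2, 5),
           s=st.floats(0.01, 100))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sum_2pi_and_scale_invariance(self, g1, g2, g3, s):
        g = sorted([g1, g2, g3])
        if g[2] >= g[0] + g[1] - 1e-9:
            return
        a = pc.young_angles(*g)
        assert a.sum() == pytest.approx(2 * math.pi, abs=1e-9)
        assert np.allclose(pc.young_angles(*(s * np.array(g))), a, atol=1e-9)

    def test_matches_numerical_force_balance(self):
        # independent oracle: minimise |g1 u1 + g2 u2 + g3 u3| over directions
        g = (1.0, 1.3, 1.8)
        a = pc.young_angles(*g)

        def residual(q):
            t2, t3 = q
            v = (g[0] * np.array([1.0, 0.0])
                 + g[1] * np.array([np.cos(t2), np.sin(t2)])
                 + g[2] * np.array([np.cos(t3), np.sin(t3)]))
            return float(v @ v)

        res = minimize(residual, x0=[2.0, 4.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-18})
        t2, t3 = np.mod(res.x, 2 * math.pi)
        # angle between interfaces 1 and 2 is opposite tension 3, etc.
        ang12 = min(abs(t2), 2 * math.pi - abs(t2))
        assert ang12 == pytest.approx(a[2], abs=1e-5)


class TestJunctionScoring:
    def test_symmetric_junction_scores_zero(self):
        t = pc.Tissue()
        c = t.new_node([0, 0], "junction")
        outer = []
        for k in range(3):
            a = 2 * math.pi * k / 3
            outer.append(t.new_node([math.cos(a), math.sin(a)], "junction"))
        eids = [t.new_edge([c.id, o.id], 1.0).id for o in outer]
        rim = [t.new_edge([outer[k].id, outer[(k + 1) % 3].id], 1.0).id
               for k in range(3)]
        for k in range(3):
            t.new_cell("cell", [eids[k], eids[(k + 1) % 3], rim[k]], 0.1)
        reports = pc.junction_angle_errors(t, method="nearest_segment")
        rep = next(r for r in reports if r.junction_id == c.id)
        assert rep.rms_error < 1e-9
        assert rep.observed_angles.sum() == pytest.approx(2 * math.pi)

    def test_known_perturbation_scored_exactly(self):
        # move one arm by 10 degrees: errors are (10, -10, 0)/sqrt stuff
        t = pc.Tissue()
        c = t.new_node([0, 0], "junction")
        angles = [0.0, 2 * math.pi / 3 + math.radians(10), 4 * math.pi / 3]
        outer = [t.new_node([math.cos(a), math.sin(a)], "junction")
                 for a in angles]
        eids = [t.new_edge([c.id, o.id], 1.0).id for o in outer]
        rim = [t.new_edge([outer[k].id, outer[(k + 1) % 3].id], 1.0).id
               for k in range(3)]
        for k in range(3):
            t.new_cell("cell", [eids[k], eids[(k + 1) % 3], rim[k]], 0.1)
        rep = next(r for r in pc.junction_angle_errors(
            t, method="nearest_segment") if r.junction_id == c.id)
        expected = math.sqrt((10 ** 2 + 10 ** 2 + 0) / 3)
        assert rep.rms_error == pytest.approx(expected, rel=1e-9)

    def test_triangle_violating_junction_skipped(self):
        t = pc.Tissue()
        c = t.new_node([0, 0], "junction")
        outer = [t.new_node([math.cos(a), math.sin(a)], "junction")
                 for a in (0, 2.1, 4.2)]
        eids = [t.new_edge([c.id, o.id], g).id
                for o, g in zip(outer, (5.0, 1.0, 1.0))]
        rim = [t.new_edge([outer[k].id, outer[(k + 1) % 3].id], 1.0).id
               for k in range(3)]
        for k in range(3):
            t.new_cell("cell", [eids[k], eids[(k + 1) % 3], rim[k]], 0.1)
        assert all(r.junction_id != c.id
                   for r in pc.junction_angle_errors(t))


@pytest.fixture(scope="module")
def tiny_pair():
    sc = pc.build_scenario("annealing", n_cells=10, seed=3)
    cfg = sc.config.replace(n_steps=400, record_stride=100)
    mono = pc.run_simulation(sc.monoline_tissue(), sc.tensions,
                             cfg.replace(mode="monoline"),
                             scenario="annealing")
    poly = pc.run_simulation(sc.tissue, sc.tensions,
                             cfg.replace(mode="polyline"),
                             scenario="annealing")
    return mono, poly


class TestAggregateMetrics:
    def test_initial_normalised_length_is_one(self, tiny_pair):
        _, poly = tiny_pair
        table = pc.aggregate_metrics(poly, ("cell", "cell"))
        assert table.boundary_len_norm.iloc[0] == pytest.approx(1.0)
        assert table.displacement_norm.iloc[0] == pytest.approx(0.0)

    def test_monoline_curvature_is_exactly_zero(self, tiny_pair):
        mono, _ = tiny_pair
        table = pc.aggregate_metrics(mono, ("cell", "cell"))
        assert (table.mean_abs_curv_norm == 0.0).all()

    def test_self_comparison_has_zero_discrepancy(self, tiny_pair):
        mono, _ = tiny_pair
        rep = pc.compare_trajectories(mono, mono, ("cell", "cell"))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in rep.values())

    def test_mismatched_seeds_refused(self, tiny_pair):
        mono, poly = tiny_pair
        poly2 = pc.Trajectory(poly.snapshots, [], poly.status, poly.config,
                              poly.scenario, seed=999)
        with pytest.raises(ValueError):
            pc.compare_trajectories(mono, poly2, ("cell", "cell"))

    def test_absent_interface_class_flagged(self, tiny_pair):
        _, poly = tiny_pair
        table = pc.aggregate_metrics(poly, ("green", "yellow"))
        assert table.boundary_len_norm.isna().all()


class TestDiscrepancy:
    @pytest.mark.parametrize("a,b,expected", [
        (1.0, 1.0, 0.0),
        (0.0, 0.0, 0.0),
        (1.0, 3.0, 100.0),
    ])
    def test_values(self, a, b, expected):
        assert pc.discrepancy_percent(a, b) == pytest.approx(expected)

    @given(a=st.floats(0.01, 100), b=st.floats(0.01, 100))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry(self, a, b):
        assert pc.discrepancy_percent(a, b) == pytest.approx(
            pc.discrepancy_percent(b, a))
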
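"""Quantitative comparison measures: circular-arc fits, Young angles and
junction RMS errors, curvature / boundary-length / displacement time series,
and monoline-vs-polyline discrepancy percentages.

At a mechanical equilibrium the three interfacial tensions meeting at a triple
junction must balance, which fixes the angles between the interfaces (the
Young angles): the angle between the interfaces carrying ``g_i`` and ``g_j``
is ``arccos((g_k^2 - g_i^2 - g_j^2) / (2 g_i g_j))``.  Observed angles are
measured either from tangents of least-squares circular arcs fit to each
edge's polyline points (``arc_tangent``) or from the first polyline segment of
each incident edge (``nearest_segment``, the only option for a monoline
model).  Each scored junction gets the RMS of its three observed-minus-Young
differences, in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mesh import Tissue, mean_cell_diameter
from .simulate import Trajectory
from .tensions import TensionTable


# ------------------------------------------------------------------ arc fit

@dataclass
class ArcFit:
    center: Optional[np.ndarray]     # None for a straight fit
    radius: float                    # inf for a straight fit
    signed_curvature: float          # positive: bulges left of first->last
    rms_residual: float


def fit_circular_arc(points: Sequence[Sequence[float]]) -> ArcFit:
    """Least-squares circle (Taubin algebraic fit) through an edge's points.

    Near-collinear chains report infinite radius and zero curvature.  The
    curvature sign is a chord-side convention: positive when the arc bulges to
    the left of the first-to-last chord direction.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two points")
    chord = pts[-1] - pts[0]
    chord_len = float(np.hypot(*chord))
    if pts.shape[0] == 2:
        return ArcFit(None, math.inf, 0.0, 0.0)

    # deviation of interior points from the straight chord line
    c = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    line_rms = s[-1] / math.sqrt(len(pts))
    scale = max(chord_len, float(s[0]))
    if line_rms <= 1e-9 * max(scale, 1e-30):
        return ArcFit(None, math.inf, 0.0, float(line_rms))

    # Taubin fit (Chernov's formulation)
    x, y = c[:, 0], c[:, 1]
    z = x * x + y * y
    Mxx, Myy, Mxy = np.mean(x * x), np.mean(y * y), np.mean(x * y)
    Mxz, Myz, Mzz = np.mean(x * z), np.mean(y * z), np.mean(z * z)
    Mz = Mxx + Myy
    Cov_xy = Mxx * Myy - Mxy * Mxy
    Var_z = Mzz - Mz * Mz
    A3 = 4 * Mz
    A2 = -3 * Mz * Mz - Mzz
    A1 = Var_z * Mz + 4 * Cov_xy * Mz - Mxz * Mxz - Myz * Myz
    A0 = Mxz * (Mxz * Myy - Myz * Mxy) + Myz * (Myz * Mxx - Mxz * Mxy) \
        - Var_z * Cov_xy
    # Newton from 0 on the characteristic polynomial
    t = 0.0
    for _ in range(50):
        f = A0 + t * (A1 + t * (A2 + t * A3))
        fp = A1 + t * (2 * A2 + 3 * A3 * t)
        if fp == 0:
            break
        t_new = t - f / fp
        if not np.isfinite(t_new) or abs(t_new - t) < 1e-14 * max(1.0, abs(t)):
            t = t_new
            break
        t = t_new
    det = t * t - t * Mz + Cov_xy
    if det == 0 or not np.isfinite(det):
        return ArcFit(None, math.inf, 0.0, float(line_rms))
    cx = (Mxz * (Myy - t) - Myz * Mxy) / det / 2
    cy = (Myz * (Mxx - t) - Mxz * Mxy) / det / 2
    center = np.array([cx, cy]) + pts.mean(axis=0)
    radii = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    radius = float(radii.mean())
    rms = float(np.sqrt(np.mean((radii - radius) ** 2)))
    if not np.isfinite(radius) or radius <= 0 or radius > 1e9 * max(scale, 1e-30):
        return ArcFit(None, math.inf, 0.0, float(line_rms))
    rel = center - pts[0]
    side = float(chord[0] * rel[1] - chord[1] * rel[0])
    sign = -1.0 if side > 0 else 1.0   # centre right of chord -> bulges left
    return ArcFit(center, radius, sign / radius, rms)


# ------------------------------------------------------------- Young angles

def young_angles(g1: float, g2: float, g3: float) -> np.ndarray:
    """Force-balance angles at a triple junction, in radians.

    ``angles[k]`` is the angle between the two interfaces *other than* the one
    carrying ``g_k``; the three angles sum to ``2*pi``.  Raises ``ValueError``
    when one tension is at least the sum of the others (no equilibrium
    junction exists).
    """
    g = np.asarray([g1, g2, g3], dtype=float)
    if np.any(g <= 0):
        raise ValueError("tensions must be positive")
    for k in range(3):
        if g[k] >= g[(k + 1) % 3] + g[(k + 2) % 3]:
            raise ValueError(
                f"tension triangle inequality violated: gamma_{k + 1} = "
                f"{g[k]:g} >= sum of the other two; no equilibrium junction")
    out = np.empty(3)
    for k in range(3):
        i, j = (k + 1) % 3, (k + 2) % 3
        cosang = (g[k] ** 2 - g[i] ** 2 - g[j] ** 2) / (2 * g[i] * g[j])
        out[k] = math.acos(min(1.0, max(-1.0, cosang)))
    return out


# -------------------------------------------------------- junction scoring

@dataclass
class JunctionReport:
    junction_id: int
    observed_angles: np.ndarray       # radians, sum 2*pi
    young: np.ndarray                 # radians, matched pairing, sum 2*pi
    rms_error: float                  # degrees


def _direction_at(tissue: Tissue, eid: int, nid: int, method: str) -> np.ndarray:
    ch = tissue.edges[eid].chain
    pts = tissue.edge_points(eid)
    if ch[0] == nid:
        p0, seg_dir = pts[0], pts[1] - pts[0]
    else:
        p0, seg_dir = pts[-1], pts[-2] - pts[-1]
    seg_dir = seg_dir / np.hypot(*seg_dir)
    if method == "nearest_segment" or len(ch) == 2:
        return seg_dir
    fit = fit_circular_arc(pts)
    if fit.center is None:
        return seg_dir
    radial = p0 - fit.center
    tang = np.array([-radial[1], radial[0]])
    n = np.hypot(*tang)
    if n == 0:
        return seg_dir
    tang = tang / n
    return tang if float(np.dot(tang, seg_dir)) >= 0 else -tang


def junction_angle_errors(tissue: Tissue,
                          tensions: Optional[TensionTable] = None,
                          method: str = "arc_tangent",
                          interior_only: bool = False) -> List[JunctionReport]:
    """Score every eligible 3-valent junction against its Young angles.

    Junctions incident to connector edges (split quad junctions / rosettes)
    are excluded, as are junctions whose tensions violate the triangle
    inequality (no finite equilibrium angle exists there).  With
    ``interior_only`` the three incident interfaces must all be cell-cell.
    """
    if method not in ("arc_tangent", "nearest_segment"):
        raise ValueError(f"unknown method {method!r}")
    out: List[JunctionReport] = []
    incidence = tissue.node_edges()
    regions = tissue.edge_regions()
    for nid, node in sorted(tissue.nodes.items()):
        if node.kind != "junction":
            continue
        inc = incidence.get(nid, [])
        if len(inc) != 3 or len(set(inc)) != 3:
            continue
        if any(tissue.edges[e].connector for e in inc):
            continue
        if interior_only and any(
                tissue.medium_label in regions[e] for e in inc):
            continue
        if tensions is not None:
            gam = [tensions.get(*(tissue.region_type(r) for r in regions[e]))
                   for e in inc]
        else:
            gam = [tissue.edges[e].tension for e in inc]
        try:
            dirs = [_direction_at(tissue, e, nid, method) for e in inc]
        except (ValueError, ZeroDivisionError):
            continue
        order = sorted(range(3),
                       key=lambda k: math.atan2(dirs[k][1], dirs[k][0]))
        thetas = [math.atan2(dirs[k][1], dirs[k][0]) for k in order]
        obs = np.array([
            (thetas[(i + 1) % 3] - thetas[i]) % (2 * math.pi)
            for i in range(3)])
        try:
            ya = young_angles(*[gam[k] for k in order])
        except ValueError:
            continue
        # sector between edges order[i], order[i+1] is opposite the third edge
        young = np.array([ya[(i + 2) % 3] for i in range(3)])
        diff = np.degrees(obs - young)
        out.append(JunctionReport(nid, obs, young,
                                  float(np.sqrt(np.mean(diff ** 2)))))
    return out


# ----------------------------------------------------------- trajectories

def discrepancy_percent(a: float, b: float) -> float:
    """``|a - b| / ((a + b)/2) * 100``; zero when both values vanish."""
    m = 0.5 * (a + b)
    if m == 0:
        return 0.0
    return abs(a - b) / abs(m) * 100.0


def interface_edges(tissue: Tissue, interface_class: Tuple[str, str]) -> List[int]:
    want = frozenset(interface_class)
    return [eid for eid in sorted(tissue.edges)
            if tissue.edge_class(eid) == want]


def interface_length(tissue: Tissue, interface_class: Tuple[str, str]) -> float:
    return sum(tissue.edge_length(e)
               for e in interface_edges(tissue, interface_class))


def tracked_cells_on_interface(tissue: Tissue,
                               interface_class: Tuple[str, str]) -> List[int]:
    """Cells that touch an interface of the given class (e.g. heterotypic)."""
    out = set()
    regions = tissue.edge_regions()
    for eid in interface_edges(tissue, interface_class):
        for r in regions[eid]:
            if r != tissue.medium_label:
                out.add(r)
    return sorted(out)


def mean_abs_curvature(tissue: Tissue,
                       interface_class: Tuple[str, str]) -> float:
    """Mean |kappa| over the edges of one interface class (0 if none)."""
    ks = []
    for eid in interface_edges(tissue, interface_class):
        fit = fit_circular_arc(tissue.edge_points(eid))
        ks.append(abs(fit.signed_curvature))
    return float(np.mean(ks)) if ks else 0.0


def aggregate_metrics(trajectory: Trajectory,
                      interface_class: Tuple[str, str],
                      tracked_cells: Optional[Sequence[int]] = None,
                      angle_method: Optional[str] = None,
                      horizontal: bool = False,
                      interior_only: bool = False) -> pd.DataFrame:
    """Per-snapshot comparison measures as a tidy table.

    Columns: ``step, t_star, median_rms_angle_err_deg, mean_rms_angle_err_deg,
    mean_abs_curv_norm, boundary_len_norm, displacement_norm``.

    * curvature is the mean |kappa| over edges of ``interface_class``,
      normalised by the radius of the circle with the average cell's area;
    * boundary length is the total class length over its initial value;
    * displacement is the mean centroid displacement of the tracked cells
      (all cells by default; pass ``horizontal=True`` to use only the
      x-component) normalised to the initial mean cell diameter;
    * dimensionless time is ``t* = t * gamma_ref / (mu * D)`` with
      ``gamma_ref`` the mean edge tension of the initial snapshot.
    """
    if not trajectory.snapshots:
        raise ValueError("empty trajectory")
    if angle_method is None:
        angle_method = ("nearest_segment"
                        if trajectory.config.mode == "monoline"
                        else "arc_tangent")
    t0 = trajectory.initial
    D0 = mean_cell_diameter(t0)
    mu = float(np.mean([c.viscosity for c in t0.cells.values()]))
    gamma_ref = float(np.mean([e.tension for e in t0.edges.values()]))
    L0 = interface_length(t0, interface_class)
    if tracked_cells is None:
        tracked = sorted(t0.cells)
    else:
        tracked = sorted(tracked_cells)
    c0 = {c: t0.cell_centroid(c) for c in tracked}

    rows = []
    for snap in trajectory.snapshots:
        tis = snap.tissue
        reports = junction_angle_errors(tis, method=angle_method,
                                        interior_only=interior_only)
        errs = np.array([r.rms_error for r in reports])
        areas = [tis.cell_area(c) for c in tis.cells]
        r_avg = math.sqrt(max(np.mean(areas), 0.0) / math.pi)
        curv = mean_abs_curvature(tis, interface_class) * r_avg
        length = interface_length(tis, interface_class)
        disp = []
        for c in tracked:
            if c in tis.cells:
                d = tis.cell_centroid(c) - c0[c]
                disp.append(abs(d[0]) if horizontal else float(np.hypot(*d)))
        rows.append({
            "step": snap.step,
            "t_star": snap.time * gamma_ref / (mu * D0),
            "median_rms_angle_err_deg": float(np.median(errs)) if errs.size else np.nan,
            "mean_rms_angle_err_deg": float(np.mean(errs)) if errs.size else np.nan,
            "mean_abs_curv_norm": curv,
            "boundary_len_norm": (length / L0) if L0 > 0 else np.nan,
            "displacement_norm": float(np.mean(disp)) / D0 if disp else np.nan,
        })
    return pd.DataFrame(rows)


def compare_trajectories(mono: Trajectory, poly: Trajectory,
                         interface_class: Tuple[str, str],
                         tracked_cells: Optional[Sequence[int]] = None,
                         horizontal: bool = False) -> Dict[str, float]:
    """Single per-scenario discrepancy numbers between the two models.

    Angle error, boundary length and displacement discrepancies are the
    trapezoidal time-integral of the instantaneous discrepancy percentage
    over dimensionless time (averaged over the overlapping time span);
    curvature, which a monoline model reports as exactly zero, is compared at
    the terminal configurations only.
    """
    if mono.scenario != poly.scenario:
        raise ValueError("trajectories come from different scenarios")
    if mono.seed != poly.seed:
        raise ValueError("trajectories come from different seeds")
    mm = aggregate_metrics(mono, interface_class, tracked_cells,
                           horizontal=horizontal)
    pm = aggregate_metrics(poly, interface_class, tracked_cells,
                           horizontal=horizontal)

    def integrated(col: str) -> float:
        hi = min(mm.t_star.iloc[-1], pm.t_star.iloc[-1])
        if hi <= 0:
            return 0.0
        grid = np.linspace(0.0, hi, 201)
        a = np.interp(grid, mm.t_star, mm[col])
        b = np.interp(grid, pm.t_star, pm[col])
        inst = np.array([discrepancy_percent(x, y) for x, y in zip(a, b)])
        inst = np.nan_to_num(inst)
        return float(np.trapezoid(inst, grid) / hi)

    return {
        "angle_error_pct": integrated("median_rms_angle_err_deg"),
        "boundary_length_pct": integrated("boundary_len_norm"),
        "displacement_pct": integrated("displacement_norm"),
        "curvature_terminal_pct": discrepancy_percent(
            float(mm.mean_abs_curv_norm.iloc[-1]),
            float(pm.mean_abs_curv_norm.iloc[-1])),
    }
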
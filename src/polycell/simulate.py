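"""Time stepping driver: topology events + viscous solves -> a Trajectory.

Each step applies, in order: segment coarsening, neighbour exchanges on short
junction-junction edges, segment refinement, then one constrained viscous
solve.  Topology passes are only entered when a cheap vectorised length check
flags a candidate segment, so quiescent stretches of a run cost one sparse
solve per step.  A run ends at ``n_steps`` or earlier when the largest nodal
displacement per step stays below ``stationary_tol * D`` for
``stationary_window`` consecutive steps (the terminal state, where meaningful
movement has ceased).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .mechanics import MechAssembly, SimConfig, SolverError
from .mesh import Tissue
from .tensions import TensionTable
from .topology import TopologyEvent, apply_t1_exchanges, refine_and_coarsen


@dataclass
class Snapshot:
    step: int
    time: float
    tissue: Tissue


@dataclass
class Trajectory:
    snapshots: List[Snapshot]
    events: List[TopologyEvent]
    status: str                      # "stationary" | "max_steps" | "error"
    config: SimConfig
    scenario: Optional[str] = None
    seed: Optional[int] = None

    @property
    def final(self) -> Tissue:
        return self.snapshots[-1].tissue

    @property
    def initial(self) -> Tissue:
        return self.snapshots[0].tissue

    def event_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for ev in self.events:
            out[ev.kind] = out.get(ev.kind, 0) + 1
        return out


def _mean_diameter_from_areas(areas: np.ndarray) -> float:
    return float(np.mean(2.0 * np.sqrt(np.maximum(areas, 0.0) / math.pi)))


class _TopoCheck:
    """Vectorised per-step screen for topology-event candidates."""

    def __init__(self, asm: MechAssembly, config: SimConfig):
        t = asm.tissue
        regions = t.edge_regions()
        jj_edges = set()
        refinable = set()
        expiry = {}
        for eid, e in t.edges.items():
            ra, rb = regions[eid]
            if len(e.chain) == 2 and rb is not None:
                jj_edges.add(eid)
                expiry[eid] = -1 if e.embargo_expiry is None else e.embargo_expiry
            if config.mode == "polyline":
                refinable.add(eid)
        self.seg_jj = np.array([e in jj_edges for e in asm.seg_edge])
        self.seg_expiry = np.array([expiry.get(e, -1) for e in asm.seg_edge])
        self.seg_refinable = np.array([e in refinable for e in asm.seg_edge])

    def due(self, L: np.ndarray, D: float, config: SimConfig,
            step: int) -> bool:
        lo = config.seg_min_frac * D
        hi = config.seg_max_frac * D
        delta = config.t1_threshold_frac * D
        if np.any((L < lo) & ~self.seg_jj):
            return True
        if np.any(L[self.seg_refinable] > hi):
            return True
        active = self.seg_jj & (self.seg_expiry <= step)
        return bool(np.any(L[active] < delta))


def run_simulation(tissue: Tissue, tensions: TensionTable, config: SimConfig,
                   scenario: Optional[str] = None) -> Trajectory:
    """Run one simulation on a copy of ``tissue``; the input is not modified."""
    work = tissue.copy()
    snaps: List[Snapshot] = [Snapshot(0, 0.0, work.copy())]
    events: List[TopologyEvent] = []
    status = "max_steps"
    t = 0.0
    quiet = 0
    stride = max(1, config.record_stride)

    asm = MechAssembly(work, config.damping_scale)
    check = _TopoCheck(asm, config)
    P = asm.positions()
    force_topo = True  # normalise/refine the initial mesh before stepping

    def rebuild():
        nonlocal asm, check, P
        asm = MechAssembly(work, config.damping_scale)
        check = _TopoCheck(asm, config)
        P = asm.positions()

    step = 0
    for step in range(config.n_steps):
        d, L = asm.segment_vectors(P)
        areas = asm.areas(P)
        D = _mean_diameter_from_areas(areas)
        if force_topo or check.due(L, D, config, step):
            force_topo = False
            asm.write_positions(P)
            ev = refine_and_coarsen(work, config, step, D, phase="coarsen")
            ev += apply_t1_exchanges(work, config, step, tensions, D)
            ev += refine_and_coarsen(work, config, step, D, phase="refine")
            if ev:
                events.extend(ev)
                rebuild()
                d, L = asm.segment_vectors(P)
        dt = config.dt
        if config.adaptive_dt:
            dt = min(dt, asm.stable_dt(L, config.stability_safety))
        try:
            du, lam, f = asm.solve(P, dt, (d, L))
        except SolverError:
            status = "error"
            break
        P = P + du
        t += dt
        max_du = float(np.max(np.hypot(du[:, 0], du[:, 1]))) if du.size else 0.0
        # threshold scales with dt_eff so the criterion is one on velocity
        # (stationary_tol is stated per nominal step of length config.dt)
        if max_du < config.stationary_tol * D * (dt / config.dt):
            quiet += 1
        else:
            quiet = 0
        if (step + 1) % stride == 0:
            asm.write_positions(P)
            snaps.append(Snapshot(step + 1, t, work.copy()))
        if quiet >= config.stationary_window:
            status = "stationary"
            break

    asm.write_positions(P)
    if not snaps or snaps[-1].step != step + 1 or status == "error":
        snaps.append(Snapshot(step + 1, t, work.copy()))
    return Trajectory(snaps, events, status, config, scenario, config.seed)
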
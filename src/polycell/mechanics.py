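"""Nodal force assembly, viscous dashpot matrix and the constrained time step.

The model is overdamped: interfacial tensions pull on the nodes, the cytoplasm
of each cell resists through grounded orthogonal dashpots, and each cell's area
is held at its target by a Lagrange multiplier that doubles as the cell
pressure.  One step solves the saddle-point system

    [ C/dt   G^T ] [ du  ]   [ f ]
    [ G      0   ] [ lam ] = [ r ]

where ``f`` is the tension force vector, ``C`` the (diagonal) dashpot matrix,
``G`` the per-cell area gradient (shoelace derivatives) and ``r = A0 - A``
restores each cell toward its target area.  ``C`` being diagonal, the system is
reduced exactly to its Schur complement ``S = G (dt C^-1) G^T``, a small dense
SPD matrix solved by Cholesky.  Reported cell pressures are ``p = -lam``
(medium pressure is the zero reference, so an isolated cell whose tension
squeezes it has positive internal pressure).

The dashpot coefficient of each node of cell ``c`` is

    k_c = damping_scale * mu_c * A_c / n_eff(c),
    n_eff(c) = (#junction nodes of c) + 1/2 (#intermediate nodes of c),

i.e. intermediate nodes enter the denominator with weight one-half;
contributions from cells sharing a node add.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .mesh import GeometryError, Tissue, TopologyError


class SolverError(RuntimeError):
    """Raised when the constrained viscous solve fails."""


@dataclass
class SimConfig:
    """Time stepping, threshold and mode parameters for one simulation.

    Length thresholds are fractions of the current mean cell diameter ``D``:
    ``t1_threshold_frac`` is the neighbour-change length ``delta``,
    ``seg_min_frac``/``seg_max_frac`` bound polyline segment lengths, and a
    fresh post-exchange edge is given length ``post_t1_length_frac * D``.
    """

    dt: float = 2e-3
    n_steps: int = 20000
    t1_threshold_frac: float = 0.025
    post_t1_length_frac: float = 0.0375
    seg_max_frac: float = 0.25
    seg_min_frac: float = 0.025
    embargo_steps: int = 0
    mode: str = "polyline"               # "monoline" | "polyline"
    seed: int = 0
    # numerical controls
    damping_scale: float = 1.0           # proportionality constant in k = mu*A/n_eff
    adaptive_dt: bool = True             # cap dt at the explicit stability limit
    stability_safety: float = 0.35
    stationary_tol: float = 1e-5         # max |du| per step, fraction of D
    stationary_window: int = 50          # consecutive quiet steps to stop
    record_stride: int = 50              # snapshot every this many steps

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mode not in ("monoline", "polyline"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.seg_min_frac < self.seg_max_frac:
            raise ValueError("seg_min_frac must be < seg_max_frac")
        if not self.post_t1_length_frac > self.t1_threshold_frac:
            raise ValueError("post_t1_length_frac must exceed t1_threshold_frac")
        if self.embargo_steps < 0:
            raise ValueError("embargo_steps must be >= 0")

    def replace(self, **kw) -> "SimConfig":
        d = asdict(self)
        d.update(kw)
        return SimConfig(**d)


@dataclass
class StepSolution:
    """Result of one viscous step: increments, loads and cell pressures."""

    displacements: np.ndarray            # (n_nodes, 2), ordered as node_ids
    force_vector: np.ndarray             # (n_nodes, 2)
    cell_pressures: Dict[int, float]     # cell id -> p (medium = 0 reference)
    node_ids: List[int]
    dt_eff: float


class MechAssembly:
    """Vectorised arrays for one mesh connectivity state.

    Valid until the tissue's topology changes (``tissue.version`` moves);
    node positions are gathered fresh on every use.
    """

    def __init__(self, tissue: Tissue, damping_scale: float = 1.0):
        self.tissue = tissue
        self.version = tissue.version
        self.node_ids = sorted(tissue.nodes)
        self.index = {nid: k for k, nid in enumerate(self.node_ids)}
        n = len(self.node_ids)
        self.n_nodes = n

        seg_i: List[int] = []
        seg_j: List[int] = []
        seg_gamma: List[float] = []
        seg_edge: List[int] = []
        for e in tissue.edges.values():
            ch = e.chain
            for a, b in zip(ch, ch[1:]):
                seg_i.append(self.index[a])
                seg_j.append(self.index[b])
                seg_gamma.append(e.tension)
                seg_edge.append(e.id)
        self.seg_i = np.asarray(seg_i, dtype=np.intp)
        self.seg_j = np.asarray(seg_j, dtype=np.intp)
        self.seg_gamma = np.asarray(seg_gamma)
        self.seg_edge = np.asarray(seg_edge, dtype=np.intp)

        # cell loops -> constraint pattern and dashpot diagonal
        self.cell_ids = sorted(tissue.cells)
        g_node: List[int] = []
        g_next: List[int] = []
        g_prev: List[int] = []
        g_row: List[int] = []
        cdiag = np.zeros(n)
        for row, cid in enumerate(self.cell_ids):
            loop = tissue.cell_loop(cid)
            idx = np.array([self.index[v] for v in loop], dtype=np.intp)
            m = len(idx)
            g_node.extend(idx)
            g_next.extend(np.roll(idx, -1))
            g_prev.extend(np.roll(idx, 1))
            g_row.extend([row] * m)
            cell = tissue.cells[cid]
            kinds = [tissue.nodes[v].kind for v in loop]
            n_eff = kinds.count("junction") + 0.5 * kinds.count("intermediate")
            if n_eff <= 0:
                raise TopologyError(f"cell {cid} has no nodes")
            area = tissue.cell_area(cid)
            if area <= 0:
                raise GeometryError(f"cell {cid} has non-positive area")
            k = damping_scale * cell.viscosity * area / n_eff
            cdiag[idx] += k
        self.g_node = np.asarray(g_node, dtype=np.intp)
        self.g_next = np.asarray(g_next, dtype=np.intp)
        self.g_prev = np.asarray(g_prev, dtype=np.intp)
        self.g_row = np.asarray(g_row, dtype=np.intp)
        self.cdiag = cdiag                       # per node (both dofs equal)
        self.cdof = np.repeat(cdiag, 2)          # per dof
        self.target_areas = np.array(
            [tissue.cells[c].target_area for c in self.cell_ids])
        # sub-resolution scale: segments far below seg_min can transiently
        # pin two junctions together (a blocked exchange); their tension is
        # tapered to zero there so the pair behaves as one compound junction
        # instead of freezing the stable time step
        if self.cell_ids:
            mean_d = float(np.mean(2.0 * np.sqrt(np.maximum(
                self.areas(self.positions()), 0.0) / np.pi)))
        else:
            mean_d = 0.0
        self.tiny_length = 5e-3 * mean_d

    # --------------------------------------------------------------- state
    def positions(self) -> np.ndarray:
        t = self.tissue
        return np.array([t.nodes[i].pos for i in self.node_ids])

    def write_positions(self, P: np.ndarray) -> None:
        t = self.tissue
        for k, nid in enumerate(self.node_ids):
            t.nodes[nid].pos = P[k].copy()
        # positions changed but connectivity did not; drop geometric caches only
        t._cache.pop("cell_loops", None)

    # ------------------------------------------------------------- physics
    def segment_vectors(self, P: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        d = P[self.seg_j] - P[self.seg_i]
        L = np.hypot(d[:, 0], d[:, 1])
        return d, L

    def forces(self, P: np.ndarray,
               seg: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> np.ndarray:
        """Tension force on every node: the exact negative gradient of
        ``sum(gamma * length)``."""
        d, L = seg if seg is not None else self.segment_vectors(P)
        Lsafe = np.maximum(L, 1e-300)
        t = d / Lsafe[:, None]
        # taper the tension of sub-resolution segments linearly to zero
        gam = self.seg_gamma * np.minimum(1.0, L / max(self.tiny_length, 1e-300))
        w = gam[:, None] * t
        n = self.n_nodes
        F = np.zeros((n, 2))
        F[:, 0] = (np.bincount(self.seg_i, weights=w[:, 0], minlength=n)
                   - np.bincount(self.seg_j, weights=w[:, 0], minlength=n))
        F[:, 1] = (np.bincount(self.seg_i, weights=w[:, 1], minlength=n)
                   - np.bincount(self.seg_j, weights=w[:, 1], minlength=n))
        return F

    def areas(self, P: np.ndarray) -> np.ndarray:
        x, y = P[:, 0], P[:, 1]
        cross = x[self.g_node] * y[self.g_next] - x[self.g_next] * y[self.g_node]
        return 0.5 * np.bincount(self.g_row, weights=cross,
                                 minlength=len(self.cell_ids))

    def constraint_matrix(self, P: np.ndarray) -> sp.csr_matrix:
        x, y = P[:, 0], P[:, 1]
        data_x = 0.5 * (y[self.g_next] - y[self.g_prev])
        data_y = 0.5 * (x[self.g_prev] - x[self.g_next])
        rows = np.concatenate([self.g_row, self.g_row])
        cols = np.concatenate([2 * self.g_node, 2 * self.g_node + 1])
        data = np.concatenate([data_x, data_y])
        return sp.csr_matrix((data, (rows, cols)),
                             shape=(len(self.cell_ids), 2 * self.n_nodes))

    def stable_dt(self, L: np.ndarray, safety: float) -> float:
        """Explicit stability bound: the stiffest mode is the transverse
        relaxation of the shortest, least-damped segment."""
        cmin = np.minimum(self.cdiag[self.seg_i], self.cdiag[self.seg_j])
        with np.errstate(divide="ignore"):
            lim = (cmin * np.maximum(L, self.tiny_length)
                   / np.maximum(self.seg_gamma, 1e-300))
        return safety * 0.5 * float(lim.min()) if lim.size else np.inf

    def solve(self, P: np.ndarray, dt: float,
              seg: Optional[Tuple[np.ndarray, np.ndarray]] = None
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One constrained viscous solve; returns (du, lam, f)."""
        f = self.forces(P, seg)
        if not np.all(np.isfinite(f)):
            raise SolverError("non-finite force vector")
        A = self.areas(P)
        r = self.target_areas - A
        G = self.constraint_matrix(P)
        w = dt / self.cdof                     # dt * C^-1 per dof
        fflat = f.ravel()
        GW = G.multiply(w[None, :]).tocsr()
        S = (GW @ G.T).toarray()
        b = GW @ fflat - r
        try:
            cho = sla.cho_factor(S, check_finite=False)
            lam = sla.cho_solve(cho, b, check_finite=False)
        except (sla.LinAlgError, ValueError) as exc:
            raise SolverError(f"singular constraint block: {exc}") from exc
        du = (w * (fflat - G.T @ lam)).reshape(-1, 2)
        if not np.all(np.isfinite(du)):
            raise SolverError("non-finite displacement increment")
        return du, lam, f


# ---------------------------------------------------------------- public ops

def assemble_tension_forces(tissue: Tissue) -> Dict[int, np.ndarray]:
    """Per-node vector sum of the rod tensions framing into each node."""
    asm = MechAssembly(tissue)
    F = asm.forces(asm.positions())
    return {nid: F[k] for k, nid in enumerate(asm.node_ids)}

def assemble_viscous_matrix(tissue: Tissue, damping_scale: float = 1.0
                            ) -> Tuple[sp.dia_matrix, List[int]]:
    """Global dashpot matrix ``C`` (diagonal, SPD) and its node ordering.

    Each node of each cell receives two orthogonal grounded dashpots of
    coefficient ``mu * A / n_eff`` with the half-weighted intermediate-node
    denominator; cells sharing a node add.
    """
    asm = MechAssembly(tissue, damping_scale)
    return sp.diags(asm.cdof), asm.node_ids


def advance_step(tissue: Tissue, config: SimConfig,
                 assembly: Optional[MechAssembly] = None) -> StepSolution:
    """Advance the mesh one time step (updated-Lagrangian explicit solve)."""
    asm = assembly
    if asm is None or asm.version != tissue.version or asm.tissue is not tissue:
        asm = MechAssembly(tissue, config.damping_scale)
    P = asm.positions()
    seg = asm.segment_vectors(P)
    dt = config.dt
    if config.adaptive_dt:
        dt = min(dt, asm.stable_dt(seg[1], config.stability_safety))
    du, lam, f = asm.solve(P, dt, seg)
    asm.write_positions(P + du)
    pressures = {cid: -float(lam[k]) for k, cid in enumerate(asm.cell_ids)}
    return StepSolution(du, f, pressures, asm.node_ids, dt)


def equivalent_shear(delta_p: float, length: float) -> float:
    """Transverse shear a straight pressurised edge transmits to its ends:
    ``V = 1/2 * delta_p * L``."""
    if length < 0:
        raise ValueError("length must be non-negative")
    return 0.5 * delta_p * length
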
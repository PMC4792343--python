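"""Discrete mesh events: T1 neighbour exchanges, segment refinement and
coarsening, and splitting of quad junctions / rosettes into triple junctions.

Per-step ordering (driven by :mod:`polycell.simulate`): coarsen first, so that
shrinking edges lose their intermediate nodes before being tested for
neighbour exchange; then T1 exchanges on junction-junction edges shorter than
``delta``; then refinement, so the viscous solve always runs on a compliant
mesh.

A cell-cell edge shorter than ``delta`` is eliminated and replaced by a new
edge joining the two previously separated regions, perpendicular to the old
edge through its midpoint, with length ``post_t1_length_frac * D`` so the
exchange cannot immediately reverse; an optional embargo timer additionally
locks the fresh edge for a number of steps.  A short *cell-medium* edge has no
neighbour pair to exchange, so its two junctions are merged instead (surface
smoothing); the merged node is then renormalised (split if it became
higher-order, spliced away if it became a plain degree-2 point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .mesh import Region, Tissue, TopologyError, mean_cell_diameter
from .mechanics import SimConfig
from .tensions import TensionTable


@dataclass(slots=True)
class TopologyEvent:
    step: int
    kind: str                 # "t1" | "split" | "merge" | "junction_split"
    entities: Tuple[int, ...]
    details: Dict[str, float] = field(default_factory=dict)


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _edge_dir_at(tissue: Tissue, eid: int, nid: int) -> np.ndarray:
    """Unit direction of the first chain segment of an edge leaving a node."""
    ch = tissue.edges[eid].chain
    if ch[0] == nid:
        other = ch[1]
    elif ch[-1] == nid:
        other = ch[-2]
    else:
        raise TopologyError(f"node {nid} is not an endpoint of edge {eid}")
    return _unit(tissue.nodes[other].pos - tissue.nodes[nid].pos)


def _point_in_cell(tissue: Tissue, cid: int, p: np.ndarray) -> bool:
    """Ray-casting point-in-polygon test against a cell's node loop."""
    loop = tissue.cell_loop(cid)
    pts = np.array([tissue.nodes[n].pos for n in loop])
    x, y = p
    inside = False
    j = len(pts) - 1
    for i in range(len(pts)):
        xi, yi = pts[i]
        xj, yj = pts[j]
        if (yi > y) != (yj > y) and x < (xj - xi) * (y - yi) / (yj - yi) + xi:
            inside = not inside
        j = i
    return inside


# ------------------------------------------------------------------- refine

def segments_per_edge(tissue: Tissue) -> float:
    """Mean number of straight segments per edge over the whole mesh."""
    if not tissue.edges:
        return 0.0
    return float(np.mean([len(e.chain) - 1 for e in tissue.edges.values()]))


def _refinable(tissue: Tissue, eid: int, mode: str) -> bool:
    # the monoline model never creates intermediate nodes
    return mode == "polyline"


def refine_and_coarsen(tissue: Tissue, config: SimConfig,
                       step: int = 0, D: Optional[float] = None,
                       phase: str = "both") -> List[TopologyEvent]:
    """Bisect over-long segments and collapse under-short ones.

    Over-long segments (> ``seg_max_frac * D``) are halved with a new
    intermediate node at the midpoint, repeatedly until compliant.  Under-short
    segments (< ``seg_min_frac * D``) merge their two end nodes: two
    intermediates collapse to one at the segment midpoint; an intermediate
    merges into its neighbouring junction, which keeps its position; a short
    junction-junction edge is left for the neighbour-change rule.

    ``phase`` restricts the pass to ``"coarsen"`` or ``"refine"`` so the step
    loop can interleave the neighbour-change rule between the two.
    """
    events: List[TopologyEvent] = []
    if D is None:
        D = mean_cell_diameter(tissue)
    lo = config.seg_min_frac * D
    hi = config.seg_max_frac * D

    # ---- coarsen
    for eid in sorted(tissue.edges) if phase in ("both", "coarsen") else []:
        e = tissue.edges.get(eid)
        if e is None:
            continue
        changed = True
        while changed:
            changed = False
            ch = e.chain
            for k in range(len(ch) - 1):
                a, b = ch[k], ch[k + 1]
                pa, pb = tissue.nodes[a].pos, tissue.nodes[b].pos
                L = float(np.hypot(*(pb - pa)))
                if L >= lo:
                    continue
                ka = tissue.nodes[a].kind
                kb = tissue.nodes[b].kind
                if ka == "junction" and kb == "junction":
                    continue  # whole-edge elimination is the T1 rule's job
                if len(ch) == 3 and ch[0] == ch[-1]:
                    continue  # tiny closed loop: do not degenerate to a point
                if ka == "intermediate" and kb == "intermediate":
                    mid = tissue.new_node(0.5 * (pa + pb), "intermediate")
                    e.chain = ch[:k] + [mid.id] + ch[k + 2:]
                    del tissue.nodes[a]
                    del tissue.nodes[b]
                    events.append(TopologyEvent(step, "merge", (eid, a, b),
                                                {"length": L}))
                else:  # one intermediate, one junction: drop the intermediate
                    drop = a if ka == "intermediate" else b
                    e.chain = [n for n in ch if n != drop]
                    del tissue.nodes[drop]
                    events.append(TopologyEvent(step, "merge", (eid, drop),
                                                {"length": L}))
                tissue.bump()
                changed = True
                break

    # ---- refine
    for eid in sorted(tissue.edges) if phase in ("both", "refine") else []:
        e = tissue.edges.get(eid)
        if e is None or not _refinable(tissue, eid, config.mode):
            continue
        again = True
        while again:
            again = False
            ch = e.chain
            out = [ch[0]]
            for a, b in zip(ch, ch[1:]):
                pa, pb = tissue.nodes[a].pos, tissue.nodes[b].pos
                L = float(np.hypot(*(pb - pa)))
                if L > hi:
                    mid = tissue.new_node(0.5 * (pa + pb), "intermediate")
                    out.extend([mid.id, b])
                    events.append(TopologyEvent(step, "split", (eid, mid.id),
                                                {"length": L}))
                    if L > 2 * hi:
                        again = True
                else:
                    out.append(b)
            if len(out) != len(ch):
                e.chain = out
                tissue.bump()
    return events


# ----------------------------------------------------------------------- T1

def apply_t1_exchanges(tissue: Tissue, config: SimConfig, step: int,
                       tensions: TensionTable,
                       D: Optional[float] = None) -> List[TopologyEvent]:
    """Perform all due neighbour exchanges (and short medium-edge collapses).

    Candidates are junction-junction edges shorter than
    ``t1_threshold_frac * D`` without an active embargo, processed
    shortest-first; a candidate whose local neighbourhood was already modified
    this step is skipped for determinism.
    """
    events: List[TopologyEvent] = []
    if D is None:
        D = mean_cell_diameter(tissue)
    delta = config.t1_threshold_frac * D

    cands: List[Tuple[float, int]] = []
    for eid in sorted(tissue.edges):
        e = tissue.edges[eid]
        if len(e.chain) != 2:
            continue
        if e.embargo_expiry is not None and step < e.embargo_expiry:
            continue
        L = tissue.edge_length(eid)
        if L < delta:
            cands.append((L, eid))
    cands.sort()

    modified: set = set()
    for L, eid in cands:
        if eid not in tissue.edges:
            continue
        e = tissue.edges[eid]
        n1, n2 = e.chain[0], e.chain[-1]
        if n1 in modified or n2 in modified:
            continue
        ra, rb = tissue.edge_regions()[eid]
        if rb is None:
            continue
        if tissue.medium_label in (ra, rb):
            _collapse_medium_edge(tissue, eid, config, step, tensions,
                                  events, modified)
        else:
            done = _t1_exchange(tissue, eid, config, step, tensions, D,
                                events, modified)
            if done is False and L < 0.5 * delta:
                # the exchange is structurally blocked (it would create an
                # invalid cell or interface) yet tension keeps shrinking the
                # edge: fall back on the quad-junction route -- merge the
                # junctions and re-split them into closely spaced triple
                # junctions, or pinch off a trapped lens cell as an inclusion
                _merge_cellcell_edge(tissue, eid, config, step, tensions,
                                     events, modified)
    return events


def _t1_exchange(tissue: Tissue, eid: int, config: SimConfig, step: int,
                 tensions: TensionTable, D: float,
                 events: List[TopologyEvent], modified: set) -> bool:
    e = tissue.edges[eid]
    n1, n2 = e.chain
    regions = tissue.edge_regions()
    ra, rb = regions[eid]
    ne = tissue.node_edges()
    inc1 = [x for x in ne[n1] if x != eid]
    inc2 = [x for x in ne[n2] if x != eid]
    if len(inc1) != 2 or len(set(inc1)) != 2 or len(inc2) != 2 or len(set(inc2)) != 2:
        events.append(TopologyEvent(step, "t1", (eid,),
                                    {"skipped": 1.0, "reason": 1.0}))
        return None  # anomalous valence (e.g. a pinch): no fallback either

    def classify(inc: List[int]):
        """Return (edge bordering ra, edge bordering rb, third region)."""
        s0, s1 = set(regions[inc[0]]), set(regions[inc[1]])
        shared = (s0 & s1) - {None}
        shared -= {ra, rb} if len(shared) > 1 else set()
        if len(shared) != 1:
            return None
        (c,) = shared
        if ra in s0 and rb in s1:
            return inc[0], inc[1], c
        if ra in s1 and rb in s0:
            return inc[1], inc[0], c
        return None

    side1 = classify(inc1)
    side2 = classify(inc2)
    if side1 is None or side2 is None:
        events.append(TopologyEvent(step, "t1", (eid,),
                                    {"skipped": 1.0, "reason": 2.0}))
        return False
    ep1, eq1, c = side1
    ep2, eq2, d = side2
    if c == d or c in (ra, rb) or d in (ra, rb):
        events.append(TopologyEvent(step, "t1", (eid,),
                                    {"skipped": 1.0, "reason": 3.0}))
        return False
    # a T1 must not reduce either losing cell below three edges
    if len(tissue.cells[ra].boundary) < 4 or len(tissue.cells[rb].boundary) < 4:
        events.append(TopologyEvent(step, "t1", (eid,),
                                    {"skipped": 1.0, "reason": 4.0}))
        return False

    p1 = tissue.nodes[n1].pos
    p2 = tissue.nodes[n2].pos
    mid = 0.5 * (p1 + p2)
    u = _unit(p2 - p1)
    nrm = np.array([-u[1], u[0]])
    cen_a = tissue.cell_centroid(ra)
    s = 1.0 if float(np.dot(cen_a - mid, nrm)) >= 0 else -1.0
    half = 0.5 * config.post_t1_length_frac * D
    m1 = tissue.new_node(mid + s * half * nrm, "junction")   # meets ra, c, d
    m2 = tissue.new_node(mid - s * half * nrm, "junction")   # meets rb, c, d

    def rewire(edge_id: int, old: int, new: int) -> None:
        ch = tissue.edges[edge_id].chain
        if ch[0] == old:
            ch[0] = new
        elif ch[-1] == old:
            ch[-1] = new
        else:  # pragma: no cover - guarded above
            raise TopologyError("rewire target is not an endpoint")

    rewire(ep1, n1, m1.id)
    rewire(ep2, n2, m1.id)
    rewire(eq1, n1, m2.id)
    rewire(eq2, n2, m2.id)

    gamma = tensions.get(tissue.region_type(c), tissue.region_type(d))
    expiry = step + config.embargo_steps if config.embargo_steps > 0 else None
    enew = tissue.new_edge([m1.id, m2.id], gamma, embargo_expiry=expiry)

    tissue.cells[ra].boundary.remove(eid)
    tissue.cells[rb].boundary.remove(eid)
    for r in (c, d):
        if r != tissue.medium_label:
            tissue.cells[r].boundary.append(enew.id)
    del tissue.edges[eid]
    del tissue.nodes[n1]
    del tissue.nodes[n2]
    tissue.bump()

    modified.update({m1.id, m2.id})
    for x in (ep1, eq1, ep2, eq2):
        ch = tissue.edges[x].chain
        modified.update({ch[0], ch[-1]})
    events.append(TopologyEvent(
        step, "t1", (eid, enew.id),
        {"old_length": float(np.hypot(*(p2 - p1))),
         "new_length": 2 * half,
         "cell_a": float(ra), "cell_b": float(rb)}))
    return True


def _collapse_medium_edge(tissue: Tissue, eid: int, config: SimConfig,
                          step: int, tensions: TensionTable,
                          events: List[TopologyEvent], modified: set) -> None:
    """Surface smoothing: merge the junctions of a short cell-medium edge."""
    e = tissue.edges[eid]
    n1, n2 = e.chain[0], e.chain[-1]
    if n1 == n2:
        return
    regions = tissue.edge_regions()
    ra, rb = regions[eid]
    cell = ra if rb == tissue.medium_label else rb
    ne = tissue.node_edges()
    others = [x for x in set(ne[n1]) | set(ne[n2]) if x != eid]
    spanning = [x for x in others
                if {tissue.edges[x].chain[0], tissue.edges[x].chain[-1]}
                == {n1, n2}]
    if spanning:
        # closure of a complete wrap: every other incident edge must span the
        # same junction pair, so that the merge turns them into closed loops
        # (the engulfed cell becomes an inclusion, the engulfing cell a
        # pinched annulus); mixed configurations are left to shrink further
        if len(spanning) != len(others):
            return
    elif len(tissue.cells[cell].boundary) < 4:
        return
    L = tissue.edge_length(eid)
    mpos = 0.5 * (tissue.nodes[n1].pos + tissue.nodes[n2].pos)
    m = tissue.new_node(mpos, "junction")
    for x in others:
        ch = tissue.edges[x].chain
        if ch[0] in (n1, n2):
            ch[0] = m.id
        if ch[-1] in (n1, n2):
            ch[-1] = m.id
    tissue.cells[cell].boundary.remove(eid)
    del tissue.edges[eid]
    del tissue.nodes[n1]
    del tissue.nodes[n2]
    tissue.bump()
    events.append(TopologyEvent(step, "merge", (eid, m.id),
                                {"length": L, "cell": float(cell)}))
    modified.add(m.id)
    for x in others:
        ch = tissue.edges[x].chain
        modified.update({ch[0], ch[-1]})
    if not spanning:
        normalize_junction(tissue, m.id, config, step, tensions, events,
                           modified)


def _merge_cellcell_edge(tissue: Tissue, eid: int, config: SimConfig,
                         step: int, tensions: TensionTable,
                         events: List[TopologyEvent], modified: set) -> None:
    """Quad-junction fallback for a stuck short cell-cell edge.

    Merges the edge's two junctions into one higher-order node and lets
    :func:`split_higher_order_junction` re-expand it into closely spaced
    triple junctions, picking the energetically favoured regrouping."""
    e = tissue.edges.get(eid)
    if e is None:
        return
    n1, n2 = e.chain[0], e.chain[-1]
    if n1 == n2:
        return
    regions = tissue.edge_regions()
    ra, rb = regions[eid]
    ne = tissue.node_edges()
    others = [x for x in set(ne[n1]) | set(ne[n2]) if x != eid]
    spanning = [x for x in others
                if {tissue.edges[x].chain[0], tissue.edges[x].chain[-1]}
                == {n1, n2}]
    for x in spanning:
        # a spanning edge becomes a closed loop after the merge, which is
        # only legitimate when it pinches off a trapped lens cell (boundary
        # exactly {eid, x}) as an inclusion inside its wrapping neighbour
        lens = any(set(c.boundary) == {eid, x} for c in tissue.cells.values())
        if not lens:
            events.append(TopologyEvent(step, "merge", (eid,),
                                        {"skipped": 1.0, "reason": 5.0}))
            return
    L = tissue.edge_length(eid)
    mpos = 0.5 * (tissue.nodes[n1].pos + tissue.nodes[n2].pos)
    m = tissue.new_node(mpos, "junction")
    for x in others:
        ch = tissue.edges[x].chain
        if ch[0] in (n1, n2):
            ch[0] = m.id
        if ch[-1] in (n1, n2):
            ch[-1] = m.id
    tissue.cells[ra].boundary.remove(eid)
    tissue.cells[rb].boundary.remove(eid)
    del tissue.edges[eid]
    del tissue.nodes[n1]
    del tissue.nodes[n2]
    tissue.bump()
    events.append(TopologyEvent(step, "merge", (eid, m.id),
                                {"length": L, "cell_a": float(ra),
                                 "cell_b": float(rb)}))
    modified.add(m.id)
    for x in others:
        ch = tissue.edges[x].chain
        modified.update({ch[0], ch[-1]})
    if not spanning:
        normalize_junction(tissue, m.id, config, step, tensions, events,
                           modified)


def normalize_junction(tissue: Tissue, nid: int, config: SimConfig, step: int,
                       tensions: TensionTable,
                       events: Optional[List[TopologyEvent]] = None,
                       modified: Optional[set] = None) -> None:
    """Restore the at-most-three-edges junction invariant at one node."""
    events = events if events is not None else []
    inc = tissue.node_edges().get(nid, [])
    if any(tissue.edges[e].chain[0] == tissue.edges[e].chain[-1] == nid
           for e in set(inc)):
        return  # pinch node of a closed wrap: leave untouched
    distinct = sorted(set(inc))
    if len(inc) >= 4 and len(distinct) >= 4:
        evs = split_higher_order_junction(tissue, nid, tensions, step=step,
                                          config=config)
        events.extend(evs)
        if modified is not None:
            for ev in evs:
                modified.update(ev.entities[1:3])  # the new junction node ids
    elif len(distinct) == 2 and len(inc) == 2:
        _splice_degree2(tissue, nid, config)


def _splice_degree2(tissue: Tissue, nid: int, config: SimConfig) -> None:
    inc = sorted(set(tissue.node_edges().get(nid, [])))
    if len(inc) != 2:
        return
    e1, e2 = (tissue.edges[i] for i in inc)
    regs = tissue.edge_regions()
    if set(regs[e1.id]) != set(regs[e2.id]):
        return  # should not happen for a plane partition; leave untouched
    ch1 = list(e1.chain) if e1.chain[-1] == nid else list(e1.chain[::-1])
    ch2 = list(e2.chain) if e2.chain[0] == nid else list(e2.chain[::-1])
    if ch1[-1] != nid or ch2[0] != nid:
        return
    keep = config.mode == "polyline"
    if keep:
        tissue.nodes[nid].kind = "intermediate"
        e1.chain = ch1 + ch2[1:]
    else:
        e1.chain = ch1[:-1] + ch2[1:]
        del tissue.nodes[nid]
    if e1.embargo_expiry is None:
        e1.embargo_expiry = e2.embargo_expiry
    elif e2.embargo_expiry is not None:
        e1.embargo_expiry = max(e1.embargo_expiry, e2.embargo_expiry)
    for c in tissue.cells.values():
        if e2.id in c.boundary:
            c.boundary.remove(e2.id)
    del tissue.edges[e2.id]
    tissue.bump()


# ------------------------------------------------------- higher-order split

def split_higher_order_junction(tissue: Tissue, node_id: int,
                                tensions: TensionTable,
                                epsilon: Optional[float] = None,
                                step: int = 0,
                                config: Optional[SimConfig] = None
                                ) -> List[TopologyEvent]:
    """Replace a >=4-valent node by a chain of closely spaced triple junctions.

    The cyclic order of the incident edges is preserved; connector edges take
    the tension of the interface they lie on (looked up by the types of the
    two regions they separate) and are flagged so angle scoring can exclude
    the compound junction.  A <=3-valent node is left untouched.
    """
    ne = tissue.node_edges()
    inc = sorted(set(ne.get(node_id, [])))
    if len(inc) < 4 or len(inc) != len(ne[node_id]):
        return []
    if epsilon is None:
        frac = config.seg_min_frac if config is not None else 0.025
        epsilon = frac * mean_cell_diameter(tissue)
    pos = tissue.nodes[node_id].pos
    regions = tissue.edge_regions()

    dirs = {eid: _edge_dir_at(tissue, eid, node_id) for eid in inc}
    k = len(inc)

    # Recover the cyclic order of the incident edges *topologically*: walk
    # from edge to edge through the region they share.  (Ordering by segment
    # angle is unreliable right after a junction merge, when two edges can
    # leave the node in almost the same direction.)
    def walk_order(first_region: Region):
        order_ = [inc[0]]
        sectors_ = []
        used = {inc[0]}
        cur_edge, cur_region = inc[0], first_region
        for _ in range(k):
            sectors_.append(cur_region)
            cands = [e for e in inc if e not in used
                     and cur_region in regions[e] and None not in regions[e]]
            if not cands:
                # closing the cycle: the last sector must lead back to start
                if len(used) == k and cur_region in regions[inc[0]]:
                    return order_, sectors_
                return None
            # prefer the candidate most aligned against the current edge's
            # rotation, falling back on id for determinism
            nxt = min(cands)
            used.add(nxt)
            order_.append(nxt)
            ra_, rb_ = regions[nxt]
            cur_region = rb_ if ra_ == cur_region else ra_
            cur_edge = nxt
        return None

    ra0, rb0 = regions[inc[0]]
    walked = walk_order(rb0) or walk_order(ra0)
    if walked is None:
        return []  # inconsistent local topology; leave the node untouched
    order, sectors = walked   # sectors[i] lies between order[i] and order[i+1]

    # Choose the cyclic starting edge: each rotation yields a different
    # regrouping into triple junctions (for a quad junction, one choice
    # recreates the collapsed interface while another performs the exchange).
    # Keep only rotations whose connector edges separate two distinct regions,
    # and among those prefer the lowest total connector tension (the
    # energetically favoured resolution); ties break on rotation index.
    def connector_pairs(shift: int) -> Optional[List[Tuple[Region, Region]]]:
        sec = sectors[shift:] + sectors[:shift]
        outer_r = sec[k - 1]
        pairs = []
        for j in range(k - 3):
            r_in = sec[j + 1]
            if r_in == outer_r:
                return None
            pairs.append((r_in, outer_r))
        return pairs

    best: Optional[Tuple[float, int, List[Tuple[Region, Region]]]] = None
    for shift in range(k):
        pairs = connector_pairs(shift)
        if pairs is None:
            continue
        try:
            cost = sum(tensions.get(tissue.region_type(p), tissue.region_type(q))
                       for p, q in pairs)
        except KeyError:
            continue
        if best is None or cost < best[0] - 1e-12:
            best = (cost, shift, pairs)
    if best is None:
        return []  # no valid regrouping; leave the node as is for now
    _, shift, conn_pairs = best
    order = order[shift:] + order[:shift]
    sectors = sectors[shift:] + sectors[:shift]

    n_new = k - 2
    new_nodes: List[int] = []
    assign: List[List[int]] = [[] for _ in range(n_new)]
    assign[0] = [order[0], order[1]]
    for j in range(1, n_new - 1):
        assign[j] = [order[j + 1]]
    assign[-1] = assign[-1] + [order[k - 2], order[k - 1]]

    eps2 = 0.5 * epsilon
    for j in range(n_new):
        if len(assign[j]) >= 2:
            b = dirs[assign[j][0]] + dirs[assign[j][-1]]
        else:
            b = dirs[assign[j][0]]
        if np.hypot(*b) < 1e-12:
            d0 = dirs[assign[j][0]]
            b = np.array([-d0[1], d0[0]])
        node = tissue.new_node(pos + eps2 * _unit(b), "junction")
        new_nodes.append(node.id)

    for j, eids in enumerate(assign):
        for eid in eids:
            ch = tissue.edges[eid].chain
            if ch[0] == node_id:
                ch[0] = new_nodes[j]
            elif ch[-1] == node_id:
                ch[-1] = new_nodes[j]

    events: List[TopologyEvent] = []
    outer = sectors[k - 1]          # region between the last and first edge
    # a freshly created connector is locked for a few steps so the compound
    # junction cannot churn (shrink and re-split every step)
    lockout = max(config.embargo_steps, 10) if config is not None else 10
    for j in range(n_new - 1):
        r_in = sectors[j + 1]       # region between edges e_{j+2} and e_{j+3}
        ta = tissue.region_type(r_in)
        tb = tissue.region_type(outer)
        conn = tissue.new_edge([new_nodes[j], new_nodes[j + 1]],
                               tensions.get(ta, tb), connector=True,
                               embargo_expiry=step + lockout)
        for r in (r_in, outer):
            if r != tissue.medium_label:
                tissue.cells[r].boundary.append(conn.id)
        events.append(TopologyEvent(step, "junction_split",
                                    (node_id, new_nodes[j], new_nodes[j + 1],
                                     conn.id), {"epsilon": epsilon}))
    del tissue.nodes[node_id]
    tissue.bump()
    return events
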
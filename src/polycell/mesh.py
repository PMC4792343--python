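"""Planar mesh data model for cell aggregates with polyline boundaries.

A :class:`Tissue` is a finite, simply connected patch of cells surrounded by
culture medium.  Cell boundaries are chains of straight rod segments: *junction*
nodes sit where three (or, transiently, more) interfaces meet, while
*intermediate* nodes subdivide a single cell-cell or cell-medium edge so that
it can curve.  An :class:`Edge` is the maximal chain of segments separating one
pair of regions (two cells, or a cell and the medium) and carries a single
interfacial tension along its whole length.

Coordinates are dimensionless; tissues are generated so that the initial mean
cell diameter (diameter of the equal-area circle) is close to one, and all
length thresholds elsewhere in the package are expressed as fractions of the
current mean cell diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

#: Region label used for the exterior culture medium.
MEDIUM = "medium"

#: A region bordering an edge: a cell id, or :data:`MEDIUM`.
Region = Union[int, str]


class TopologyError(ValueError):
    """Raised when a mesh operation encounters an inconsistent topology."""


class GeometryError(ValueError):
    """Raised when geometry is degenerate (zero-length segment, zero area...)."""


@dataclass(slots=True)
class Node:
    id: int
    pos: np.ndarray          # shape (2,), float64
    kind: str                # "junction" | "intermediate"

    def copy(self) -> "Node":
        return Node(self.id, self.pos.copy(), self.kind)


@dataclass(slots=True)
class Edge:
    """A polyline interface between two regions.

    ``chain`` is the ordered node-id list; first and last entries are junction
    nodes (they may coincide for a closed-loop interface around an inclusion),
    interior entries are intermediate nodes.  All segments of the chain carry
    the same ``tension``.
    """

    id: int
    chain: List[int]
    tension: float
    embargo_expiry: Optional[int] = None   # step index; None = no embargo
    connector: bool = False                # short edge from a split rosette

    def copy(self) -> "Edge":
        return Edge(self.id, list(self.chain), self.tension,
                    self.embargo_expiry, self.connector)


@dataclass(slots=True)
class Cell:
    id: int
    type_label: str
    boundary: List[int]      # edge ids; cyclic order is derived, not stored
    target_area: float
    viscosity: float = 1.0

    def copy(self) -> "Cell":
        return Cell(self.id, self.type_label, list(self.boundary),
                    self.target_area, self.viscosity)


@dataclass(slots=True)
class Violation:
    entity_kind: str
    entity_id: int
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.entity_kind} {self.entity_id}] {self.rule}: {self.message}"


def shoelace_area(points: np.ndarray) -> float:
    """Signed area of a polygon given as an (n, 2) vertex array (no repeat)."""
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


class Tissue:
    """Mutable planar cell aggregate: nodes, polyline edges and cells."""

    def __init__(self, medium_label: str = MEDIUM):
        self.nodes: Dict[int, Node] = {}
        self.edges: Dict[int, Edge] = {}
        self.cells: Dict[int, Cell] = {}
        self.medium_label = medium_label
        self._next_node = 0
        self._next_edge = 0
        self._next_cell = 0
        self._version = 0
        self._cache: Dict[str, object] = {}

    # ------------------------------------------------------------------ ids
    def new_node(self, pos, kind: str) -> Node:
        n = Node(self._next_node, np.asarray(pos, dtype=float), kind)
        self.nodes[n.id] = n
        self._next_node += 1
        self.bump()
        return n

    def new_edge(self, chain: List[int], tension: float, **kw) -> Edge:
        e = Edge(self._next_edge, list(chain), float(tension), **kw)
        self.edges[e.id] = e
        self._next_edge += 1
        self.bump()
        return e

    def new_cell(self, type_label: str, boundary: List[int],
                 target_area: float, viscosity: float = 1.0) -> Cell:
        c = Cell(self._next_cell, type_label, list(boundary),
                 float(target_area), float(viscosity))
        self.cells[c.id] = c
        self._next_cell += 1
        self.bump()
        return c

    def bump(self) -> None:
        """Invalidate derived caches after any structural modification."""
        self._version += 1
        self._cache.clear()

    @property
    def version(self) -> int:
        return self._version

    def copy(self) -> "Tissue":
        t = Tissue(self.medium_label)
        t.nodes = {i: n.copy() for i, n in self.nodes.items()}
        t.edges = {i: e.copy() for i, e in self.edges.items()}
        t.cells = {i: c.copy() for i, c in self.cells.items()}
        t._next_node = self._next_node
        t._next_edge = self._next_edge
        t._next_cell = self._next_cell
        return t

    # ------------------------------------------------- derived connectivity
    def edge_regions(self) -> Dict[int, Tuple[Region, Region]]:
        """Map edge id -> the (unordered) pair of regions it separates.

        Edges referenced by a single cell border the medium.  Edges referenced
        by zero or more than two cells are reported with a ``None`` side and
        flagged by :func:`validate_topology`.
        """
        key = "edge_regions"
        if key not in self._cache:
            owners: Dict[int, List[int]] = {eid: [] for eid in self.edges}
            for c in self.cells.values():
                for eid in c.boundary:
                    if eid in owners:
                        owners[eid].append(c.id)
            out: Dict[int, Tuple[Region, Region]] = {}
            for eid, cs in owners.items():
                if len(cs) == 1:
                    out[eid] = (cs[0], self.medium_label)
                elif len(cs) == 2:
                    out[eid] = (cs[0], cs[1])
                else:
                    out[eid] = (cs[0] if cs else None, None)  # type: ignore
            self._cache[key] = out
        return self._cache[key]  # type: ignore[return-value]

    def region_type(self, region: Region) -> str:
        if region == self.medium_label:
            return self.medium_label
        return self.cells[region].type_label

    def edge_class(self, eid: int) -> frozenset:
        """Interface class of an edge: the unordered pair of region *types*."""
        a, b = self.edge_regions()[eid]
        return frozenset({self.region_type(a), self.region_type(b)})

    def node_edges(self) -> Dict[int, List[int]]:
        """Map node id -> ids of incident edges (loop edges appear twice)."""
        key = "node_edges"
        if key not in self._cache:
            inc: Dict[int, List[int]] = {nid: [] for nid in self.nodes}
            for e in self.edges.values():
                inc[e.chain[0]].append(e.id)
                inc[e.chain[-1]].append(e.id)
                for nid in e.chain[1:-1]:
                    inc[nid].append(e.id)
            self._cache[key] = inc
        return self._cache[key]  # type: ignore[return-value]

    # ------------------------------------------------------------ geometry
    def edge_points(self, eid: int) -> np.ndarray:
        ch = self.edges[eid].chain
        return np.array([self.nodes[n].pos for n in ch])

    def edge_length(self, eid: int) -> float:
        p = self.edge_points(eid)
        return float(np.sum(np.hypot(*(p[1:] - p[:-1]).T)))

    def _boundary_rings(self, cid: int) -> List[List[int]]:
        """Decompose a cell's boundary edges into closed node rings."""
        cell = self.cells[cid]
        remaining = list(cell.boundary)
        if not remaining:
            raise TopologyError(f"cell {cid} has no boundary edges")
        rings: List[List[int]] = []
        while remaining:
            first = self.edges[remaining.pop(0)].chain
            if first[0] == first[-1]:
                rings.append(list(first[:-1]))
                continue
            ring = list(first[:-1])
            start, cur = first[0], first[-1]
            while cur != start:
                for k, eid in enumerate(remaining):
                    ch = self.edges[eid].chain
                    if ch[0] == cur:
                        seg = ch
                        break
                    if ch[-1] == cur:
                        seg = ch[::-1]
                        break
                else:
                    raise TopologyError(
                        f"cell {cid}: boundary does not continue at node {cur}")
                remaining.pop(k)
                ring.extend(seg[:-1])
                cur = seg[-1]
            rings.append(ring)
        return rings

    def cell_loop(self, cid: int) -> List[int]:
        """Ordered CCW node traversal of a cell (first node not repeated).

        The boundary edge list is unordered; the traversal is recovered by
        walking shared junction endpoints.  A cell whose wrap has closed on
        itself (an engulfing cell pinched at the closure point) decomposes
        into several rings sharing a pinch node; the hole rings are then
        threaded clockwise through the pinch so the shoelace sum over the
        whole traversal equals the enclosed area.
        """
        key = "cell_loops"
        loops = self._cache.setdefault(key, {})
        if cid in loops:  # type: ignore[operator]
            return loops[cid]  # type: ignore[index]
        rings = self._boundary_rings(cid)

        def area_of(ring: List[int]) -> float:
            return shoelace_area(np.array([self.nodes[n].pos for n in ring]))

        if len(rings) == 1:
            loop = rings[0]
            if area_of(loop) < 0:
                loop.reverse()
        else:
            rings.sort(key=lambda r: -abs(area_of(r)))
            loop = rings[0]
            if area_of(loop) < 0:
                loop.reverse()
            for hole in rings[1:]:
                if area_of(hole) > 0:
                    hole.reverse()        # holes run clockwise
                pinch = next((n for n in hole if n in loop), None)
                if pinch is None:
                    raise TopologyError(
                        f"cell {cid}: detached interior ring is not supported")
                r = hole.index(pinch)
                hole = hole[r:] + hole[:r]          # start hole at the pinch
                i = loop.index(pinch)
                loop = loop[:i + 1] + hole[1:] + [pinch] + loop[i + 1:]
        loops[cid] = loop  # type: ignore[index]
        return loop

    def cell_area(self, cid: int) -> float:
        loop = self.cell_loop(cid)
        pts = np.array([self.nodes[n].pos for n in loop])
        return shoelace_area(pts)

    def cell_centroid(self, cid: int) -> np.ndarray:
        loop = self.cell_loop(cid)
        pts = np.array([self.nodes[n].pos for n in loop])
        x, y = pts[:, 0], pts[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * cross.sum()
        if abs(a) < 1e-300:
            return pts.mean(axis=0)
        cx = np.sum((x + xn) * cross) / (6 * a)
        cy = np.sum((y + yn) * cross) / (6 * a)
        return np.array([cx, cy])


# ----------------------------------------------------------------- operations

def polygon_area(tissue: Tissue, cell_id: int) -> float:
    """Signed shoelace area of a cell's node loop (positive: CCW boundary)."""
    return tissue.cell_area(cell_id)


def mean_cell_diameter(tissue: Tissue) -> float:
    """Mean over cells of the equal-area-circle diameter ``2*sqrt(A/pi)``."""
    if not tissue.cells:
        raise TopologyError("tissue has no cells")
    return float(np.mean([2.0 * math.sqrt(max(tissue.cell_area(c), 0.0) / math.pi)
                          for c in tissue.cells]))


def total_interface_energy(tissue: Tissue) -> float:
    """Boundary energy ``sum over edges of tension * polyline length``."""
    return sum(e.tension * tissue.edge_length(e.id) for e in tissue.edges.values())


def validate_topology(tissue: Tissue) -> List[Violation]:
    """Check every structural invariant; empty list means the mesh is sound."""
    out: List[Violation] = []
    regions = tissue.edge_regions()
    incidence = tissue.node_edges()

    for e in tissue.edges.values():
        ch = e.chain
        if len(ch) < 2:
            out.append(Violation("edge", e.id, "chain", "fewer than two nodes"))
            continue
        for a, b in zip(ch, ch[1:]):
            if a == b:
                out.append(Violation("edge", e.id, "chain",
                                     f"repeated consecutive node {a}"))
            else:
                d = tissue.nodes[a].pos - tissue.nodes[b].pos
                if float(np.hypot(*d)) <= 0.0:
                    out.append(Violation("edge", e.id, "segment",
                                         f"zero-length segment {a}-{b}"))
        for nid in ch[1:-1]:
            if tissue.nodes[nid].kind != "intermediate":
                out.append(Violation("edge", e.id, "chain",
                                     f"interior node {nid} is not intermediate"))
        for nid in (ch[0], ch[-1]):
            if tissue.nodes[nid].kind != "junction":
                out.append(Violation("edge", e.id, "chain",
                                     f"end node {nid} is not a junction"))
        ra, rb = regions[e.id]
        if rb is None:
            out.append(Violation("edge", e.id, "two_regions",
                                 "edge is referenced by != 1 or 2 cells"))
        elif ra == rb:
            out.append(Violation("edge", e.id, "two_regions",
                                 f"both sides reference region {ra}"))

    for n in tissue.nodes.values():
        inc = incidence.get(n.id, [])
        if n.kind == "intermediate":
            interior_of_one = (
                len(inc) == 1
                and tissue.edges[inc[0]].chain[0] != n.id
                and tissue.edges[inc[0]].chain[-1] != n.id)
            if not interior_of_one:
                out.append(Violation(
                    "node", n.id, "intermediate_degree",
                    "intermediate node must carry exactly two segments of one edge"))
        else:
            distinct = set(inc)
            loop_edge = any(tissue.edges[e].chain[0] == tissue.edges[e].chain[-1] == n.id
                            for e in distinct)
            if len(distinct) < 2 and not loop_edge:
                out.append(Violation("node", n.id, "junction_degree",
                                     "junction is endpoint of fewer than 2 edges"))
            # pinch nodes of closed engulfment wraps carry two loop passes
            # and are exempt from the quad-junction normalisation rule
            if len(inc) > 3 and not loop_edge:
                out.append(Violation("node", n.id, "max_valence",
                                     f"junction has {len(inc)} incident edges (>3)"))

    for c in tissue.cells.values():
        try:
            area = tissue.cell_area(c.id)
        except TopologyError as exc:
            out.append(Violation("cell", c.id, "closed_loop", str(exc)))
            continue
        if area <= 0:
            out.append(Violation("cell", c.id, "positive_area",
                                 f"area {area:.3g} is not positive"))

    # connectivity (union-find over nodes through edge chains)
    if tissue.nodes:
        parent = {nid: nid for nid in tissue.nodes}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for e in tissue.edges.values():
            for a, b in zip(e.chain, e.chain[1:]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        roots = {find(n) for n in tissue.nodes}
        if len(roots) > 1:
            out.append(Violation("tissue", 0, "connected",
                                 f"mesh has {len(roots)} components"))
    return out
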
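"""Seeded Voronoi initial conditions.

Generator points are sampled uniformly at unit density, optionally regularised
by a few Lloyd iterations, then jittered to create intentional cell-size
variation (so that pressure differences exist between neighbours).  The
tessellation is clipped to a rounded hull, producing a finite isolated
aggregate surrounded by medium, and rescaled so the mean cell diameter is
exactly one.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient

from .mesh import MEDIUM, Tissue, shoelace_area, validate_topology
from .tensions import TensionTable


def _finite_regions(points: np.ndarray) -> List[Polygon]:
    """Bounded Voronoi region polygons via a distant ghost-point ring."""
    center = points.mean(axis=0)
    span = float(np.ptp(points, axis=0).max()) + 1.0
    radius = 4.0 * span
    theta = np.linspace(0, 2 * math.pi, 64, endpoint=False)
    ghosts = center + radius * np.column_stack([np.cos(theta), np.sin(theta)])
    vor = Voronoi(np.vstack([points, ghosts]))
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise ValueError(f"unbounded Voronoi region for point {i}")
        polys.append(Polygon(vor.vertices[region]))
    return polys


def _lloyd(points: np.ndarray, iters: int) -> np.ndarray:
    pts = points.copy()
    for _ in range(iters):
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull.buffer(0.5)
        regs = _finite_regions(pts)
        pts = np.array([reg.intersection(hull).centroid.coords[0]
                        if not reg.intersection(hull).is_empty
                        else pts[i]
                        for i, reg in enumerate(regs)])
    return pts


def voronoi_tissue(n_cells: int, seed: int, size_variation: float = 0.5,
                   lloyd_iters: int = 3, hull_margin: float = 0.4,
                   type_label: str = "cell", viscosity: float = 1.0,
                   tensions: Optional[TensionTable] = None,
                   _attempt: int = 0) -> Tissue:
    """Build a polyline tissue from a seeded Voronoi tessellation.

    ``size_variation`` is the standard deviation of the post-Lloyd point
    jitter in units of the mean point spacing; 0 gives a regular honeycomb-like
    aggregate, 0.5 an irregular one with an area coefficient of variation
    above ~0.2.  All cells get ``type_label`` and unit target pressure scale;
    tensions default to 1 on every interface.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _attempt]))
    side = math.sqrt(n_cells)
    pts = rng.uniform(0, side, size=(n_cells, 2))
    if n_cells >= 2 and lloyd_iters > 0:
        pts = _lloyd(pts, lloyd_iters)
    if size_variation > 0 and n_cells >= 2:
        pts = pts + rng.normal(0.0, size_variation, size=pts.shape)

    try:
        if n_cells == 1:
            clip = MultiPoint([tuple(pts[0])]).buffer(0.55, quad_segs=6)
            polys = [clip]
        else:
            hull = MultiPoint([tuple(p) for p in pts]).convex_hull
            clip = hull.buffer(hull_margin, quad_segs=3)
            cells = []
            for reg in _finite_regions(pts):
                c = reg.intersection(clip)
                if c.geom_type == "MultiPolygon":
                    c = max(c.geoms, key=lambda g: g.area)
                if c.is_empty or c.area <= 0:
                    raise ValueError("empty clipped cell")
                cells.append(orient(Polygon(c.exterior.coords)))
            polys = cells
        tissue = tissue_from_polygons(
            polys, [type_label] * len(polys),
            tensions=tensions or TensionTable.uniform(1.0, [type_label]),
            viscosity=viscosity)
        bad = validate_topology(tissue)
        if bad:
            raise ValueError(f"invalid generated mesh: {bad[0]}")
    except ValueError as exc:
        if _attempt >= 5:
            raise
        warnings.warn(f"degenerate tessellation (seed={seed}): {exc}; "
                      f"regenerating with perturbation")
        return voronoi_tissue(n_cells, seed, size_variation, lloyd_iters,
                              hull_margin, type_label, viscosity, tensions,
                              _attempt=_attempt + 1)
    return tissue


def tissue_from_polygons(polys: Sequence[Polygon], types: Sequence[str],
                         tensions: TensionTable, viscosity: float = 1.0,
                         medium_label: str = MEDIUM,
                         snap_tol: float = 1e-7) -> Tissue:
    """Assemble a mesh from a gap-free set of CCW cell polygons.

    Vertices closer than ``snap_tol`` (after rescaling to unit mean diameter)
    are fused; maximal vertex chains separating one region pair become edges,
    vertices where the region pair changes become junction nodes, the rest
    intermediate nodes.  A boundary ring with no junction at all (single cell,
    or an isolated inclusion) is split into three edges by pseudo-junctions.
    """
    # rescale so the mean equal-area-circle diameter is 1
    areas = np.array([abs(p.area) for p in polys])
    dmean = float(np.mean(2.0 * np.sqrt(areas / math.pi)))
    scale = 1.0 / dmean
    rings = []
    for p in polys:
        xy = np.asarray(p.exterior.coords)[:-1] * scale
        if shoelace_area(xy) < 0:
            xy = xy[::-1]
        rings.append(xy)

    # ---- snap vertices
    allpts = np.vstack(rings)
    tree = cKDTree(allpts)
    pairs = tree.query_pairs(snap_tol)
    parent = list(range(len(allpts)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    clusters: Dict[int, List[int]] = {}
    for i in range(len(allpts)):
        clusters.setdefault(find(i), []).append(i)
    vert_of = np.empty(len(allpts), dtype=np.intp)
    vert_pos: List[np.ndarray] = []
    for vid, (_, members) in enumerate(sorted(clusters.items())):
        for m in members:
            vert_of[m] = vid
        vert_pos.append(allpts[members].mean(axis=0))

    # ---- per-cell vertex rings, segment -> owning cells
    offs = 0
    cell_rings: List[List[int]] = []
    for xy in rings:
        ring = [int(vert_of[offs + k]) for k in range(len(xy))]
        dedup = [v for k, v in enumerate(ring) if v != ring[k - 1]]
        if len(dedup) < 3:
            raise ValueError("degenerate cell ring after snapping")
        cell_rings.append(dedup)
        offs += len(xy)

    seg_owners: Dict[Tuple[int, int], List[int]] = {}
    for ci, ring in enumerate(cell_rings):
        for a, b in zip(ring, ring[1:] + ring[:1]):
            seg_owners.setdefault((min(a, b), max(a, b)), []).append(ci)

    seg_pair: Dict[Tuple[int, int], Tuple[object, object]] = {}
    for seg, owners in seg_owners.items():
        if len(owners) == 1:
            seg_pair[seg] = (owners[0], medium_label)
        elif len(owners) == 2:
            seg_pair[seg] = (owners[0], owners[1])
        else:
            raise ValueError(f"segment shared by {len(owners)} cells")

    vert_segs: Dict[int, List[Tuple[int, int]]] = {}
    for seg in seg_pair:
        vert_segs.setdefault(seg[0], []).append(seg)
        vert_segs.setdefault(seg[1], []).append(seg)

    def pairset(seg: Tuple[int, int]) -> frozenset:
        return frozenset(seg_pair[seg])

    is_junction = {v: (len(segs) >= 3 or len({pairset(s) for s in segs}) > 1)
                   for v, segs in vert_segs.items()}

    # ---- walk maximal chains
    tissue = Tissue(medium_label)
    node_of: Dict[int, int] = {}

    def node_id(v: int, kind: str) -> int:
        if v not in node_of:
            node_of[v] = tissue.new_node(vert_pos[v], kind).id
        return node_of[v]

    visited: set = set()
    chains: List[Tuple[List[int], frozenset]] = []
    for v in sorted(vert_segs):
        if not is_junction[v]:
            continue
        for seg in sorted(vert_segs[v]):
            if seg in visited:
                continue
            # walk away from the junction through degree-2 same-pair vertices
            pair = pairset(seg)
            chain = [v]
            cur, prev = (seg[0] if seg[1] == v else seg[1]), v
            visited.add(seg)
            while not is_junction[cur]:
                chain.append(cur)
                nxt_seg = next(s for s in vert_segs[cur]
                               if s != (min(cur, prev), max(cur, prev)))
                visited.add(nxt_seg)
                prev, cur = cur, (nxt_seg[0] if nxt_seg[1] == cur
                                  else nxt_seg[1])
            chain.append(cur)
            chains.append((chain, pair))
    # pure cycles with no junction (single cell / inclusion): split into 3
    for v in sorted(vert_segs):
        if is_junction[v] or any(s in visited for s in vert_segs[v]):
            continue
        cyc = [v]
        seg = sorted(vert_segs[v])[0]
        visited.add(seg)
        prev, cur = v, (seg[0] if seg[1] == v else seg[1])
        while cur != v:
            cyc.append(cur)
            nxt_seg = next(s for s in vert_segs[cur]
                           if s != (min(cur, prev), max(cur, prev)))
            visited.add(nxt_seg)
            prev, cur = cur, (nxt_seg[0] if nxt_seg[1] == cur else nxt_seg[1])
        pair = pairset(seg)
        m = len(cyc)
        cuts = sorted({0, m // 3, (2 * m) // 3})
        if len(cuts) < 3:
            raise ValueError("ring too short to split into three edges")
        for a, b in zip(cuts, cuts[1:] + [m]):
            piece = cyc[a:b + 1] if b < m else cyc[a:] + [cyc[0]]
            chains.append((piece, pair))
            for w in cuts:
                is_junction[cyc[w]] = True

    for chain, pair in chains:
        nids = [node_id(v, "junction" if is_junction[v] else "intermediate")
                for v in chain]
        tissue.new_edge(nids, 0.0)  # tension stamped once cells exist

    # map chains back to cells
    for ci, _ring in enumerate(cell_rings):
        tissue.new_cell(types[ci], [], 0.0, viscosity)
    edge_ids = sorted(tissue.edges)
    for eid, (chain, pair) in zip(edge_ids, chains):
        for r in pair:
            if isinstance(r, int):
                tissue.cells[r].boundary.append(eid)
    for cid in tissue.cells:
        tissue.cells[cid].target_area = tissue.cell_area(cid)
    tensions.assign(tissue)
    tissue.bump()
    return tissue


def to_monoline(tissue: Tissue) -> Tissue:
    """Return a copy with edges reduced to single straight rods (monoline).

    Nodes then exist only at the junctions.  One guard keeps the geometry
    non-degenerate: a cell-medium chain is left segmented when its cell has
    fewer than three boundary edges, since straightening it would flatten the
    cell onto a chord (the two-cell aggregate is the canonical case).  Target
    areas are refreshed from the straightened geometry.
    """
    t = tissue.copy()
    for e in list(t.edges.values()):
        if len(e.chain) == 2:
            continue
        a, b = t.edge_regions()[e.id]
        if t.medium_label in (a, b):
            cell = a if b == t.medium_label else b
            if len(t.cells[cell].boundary) < 3:
                continue
        for nid in e.chain[1:-1]:
            del t.nodes[nid]
        e.chain = [e.chain[0], e.chain[-1]]
    t.bump()
    for cid in t.cells:
        t.cells[cid].target_area = t.cell_area(cid)
    return t
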
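"""Persistence: snapshot records, trajectory directories, SVG frames.

Snapshots are line-delimited text with full-precision floats (``repr``), so a
write/read round trip reproduces the tissue exactly and runs with the same
seed and configuration produce byte-identical output.  Schema (0-based ids,
CCW cell loops)::

    # polycell snapshot v1
    medium <label>
    node <id> <x> <y> <kind>
    edge <id> <tension> <embargo_expiry|-> <connector 0|1> <n0,n1,...>
    cell <id> <type> <target_area> <viscosity> <e0,e1,...>
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__ as _pkg_version
from .mechanics import SimConfig
from .mesh import Cell, Edge, Node, Tissue
from .simulate import Snapshot, Trajectory

SNAPSHOT_HEADER = "# polycell snapshot v1"


def write_snapshot(tissue: Tissue, path) -> None:
    lines = [SNAPSHOT_HEADER, f"medium {tissue.medium_label}"]
    for nid in sorted(tissue.nodes):
        n = tissue.nodes[nid]
        lines.append(f"node {nid} {float(n.pos[0])!r} {float(n.pos[1])!r} {n.kind}")
    for eid in sorted(tissue.edges):
        e = tissue.edges[eid]
        emb = "-" if e.embargo_expiry is None else str(e.embargo_expiry)
        chain = ",".join(map(str, e.chain))
        lines.append(f"edge {eid} {float(e.tension)!r} {emb} {int(e.connector)} {chain}")
    for cid in sorted(tissue.cells):
        c = tissue.cells[cid]
        loop = ",".join(map(str, sorted(c.boundary)))
        lines.append(f"cell {cid} {c.type_label} {float(c.target_area)!r} "
                     f"{float(c.viscosity)!r} {loop}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path) -> Tissue:
    text = Path(path).read_text().splitlines()
    if not text or text[0] != SNAPSHOT_HEADER:
        raise ValueError(f"{path}: not a polycell snapshot")
    tissue = Tissue()
    for line in text[1:]:
        if not line.strip():
            continue
        parts = line.split()
        tag = parts[0]
        if tag == "medium":
            tissue.medium_label = parts[1]
        elif tag == "node":
            nid = int(parts[1])
            tissue.nodes[nid] = Node(nid, np.array([float(parts[2]),
                                                    float(parts[3])]), parts[4])
        elif tag == "edge":
            eid = int(parts[1])
            emb = None if parts[3] == "-" else int(parts[3])
            chain = [int(x) for x in parts[5].split(",")]
            tissue.edges[eid] = Edge(eid, chain, float(parts[2]), emb,
                                     bool(int(parts[4])))
        elif tag == "cell":
            cid = int(parts[1])
            boundary = [int(x) for x in parts[5].split(",")]
            tissue.cells[cid] = Cell(cid, parts[2], boundary,
                                     float(parts[3]), float(parts[4]))
        else:
            raise ValueError(f"{path}: unknown record {tag!r}")
    tissue._next_node = max(tissue.nodes, default=-1) + 1
    tissue._next_edge = max(tissue.edges, default=-1) + 1
    tissue._next_cell = max(tissue.cells, default=-1) + 1
    tissue.bump()
    return tissue


# ------------------------------------------------------------- trajectories

def write_trajectory(traj: Trajectory, outdir) -> None:
    out = Path(outdir)
    (out / "snapshots").mkdir(parents=True, exist_ok=True)
    for snap in traj.snapshots:
        write_snapshot(snap.tissue,
                       out / "snapshots" / f"step_{snap.step:07d}.txt")
    with open(out / "events.tsv", "w") as fh:
        fh.write("step\tkind\tentities\tdetails\n")
        for ev in traj.events:
            det = ";".join(f"{k}={v!r}" for k, v in sorted(ev.details.items()))
            ents = ",".join(map(str, ev.entities))
            fh.write(f"{ev.step}\t{ev.kind}\t{ents}\t{det}\n")
    times = {snap.step: snap.time for snap in traj.snapshots}
    manifest = {
        "polycell_version": _pkg_version,
        "scenario": traj.scenario,
        "seed": traj.seed,
        "status": traj.status,
        "config": dataclasses.asdict(traj.config),
        "snapshot_steps": [s.step for s in traj.snapshots],
        "snapshot_times": times,
        "event_counts": traj.event_counts(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_trajectory(path) -> Trajectory:
    src = Path(path)
    manifest = json.loads((src / "manifest.json").read_text())
    config = SimConfig(**manifest["config"])
    snaps = []
    times = {int(k): v for k, v in manifest["snapshot_times"].items()}
    for step in manifest["snapshot_steps"]:
        tissue = read_snapshot(src / "snapshots" / f"step_{step:07d}.txt")
        snaps.append(Snapshot(step, times[step], tissue))
    return Trajectory(snaps, [], manifest["status"], config,
                      manifest.get("scenario"), manifest.get("seed"))


# --------------------------------------------------------------- rendering

_DEFAULT_STYLE = {
    "cell": "#d9d9d9", "green": "#7fbf7f", "yellow": "#f2e394",
    "edge": "#333333", "background": "#ffffff",
    "stroke_width": 0.01, "pad": 0.3, "size": 640,
}


def render_svg(tissue: Tissue, path, style: Optional[Dict] = None) -> None:
    """One scalable frame: cells filled by type colour, edges as polylines."""
    st = dict(_DEFAULT_STYLE)
    if style:
        st.update(style)
    pts = np.array([n.pos for n in tissue.nodes.values()])
    lo = pts.min(axis=0) - st["pad"]
    hi = pts.max(axis=0) + st["pad"]
    span = hi - lo
    size = st["size"]

    def sx(p):
        return (p[0] - lo[0]) / span[0] * size

    def sy(p):
        return (hi[1] - p[1]) / span[1] * size   # flip y for SVG

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" '
        f'height="{size}" viewBox="0 0 {size} {size}">',
        f'<rect width="{size}" height="{size}" fill="{st["background"]}"/>',
    ]
    for cid in sorted(tissue.cells):
        loop = tissue.cell_loop(cid)
        coords = " ".join(f"{sx(tissue.nodes[n].pos):.2f},"
                          f"{sy(tissue.nodes[n].pos):.2f}" for n in loop)
        fill = st.get(tissue.cells[cid].type_label, "#cccccc")
        parts.append(f'<polygon points="{coords}" fill="{fill}" '
                     f'stroke="none"/>')
    w = st["stroke_width"] * size
    for eid in sorted(tissue.edges):
        p = tissue.edge_points(eid)
        coords = " ".join(f"{sx(q):.2f},{sy(q):.2f}" for q in p)
        parts.append(f'<polyline points="{coords}" fill="none" '
                     f'stroke="{st["edge"]}" stroke-width="{w:.2f}" '
                     f'stroke-linecap="round"/>')
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")


def render_frames(trajectory: Trajectory, outdir,
                  style: Optional[Dict] = None) -> List[Path]:
    """One SVG per saved snapshot; returns the written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for snap in trajectory.snapshots:
        p = out / f"frame_{snap.step:07d}.svg"
        render_svg(snap.tissue, p, style)
        paths.append(p)
    return paths
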
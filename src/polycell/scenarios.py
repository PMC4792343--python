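"""The six canonical cell-interaction scenarios and matched model pairs.

Each scenario couples a seeded Voronoi initial condition with a tension table
whose entries satisfy the inequality that defines the behaviour:

==================  =============================================================
annealing           one cell type, every interface (including the medium) carries
                    the same tension; size variation supplies pressure differences
cell_engulfment     two cells; spreading condition gamma_gm + gamma_gy < gamma_ym
                    makes the green cell wrap over (engulf) the yellow one
tissue_engulfment   two multicellular masses; green cells peel off their mass and
                    flow over the yellow tissue (embargo timer enabled)
sorting             200 cells of two randomly assigned types; heterotypic tension
                    above the homotypic mean drives sorting plus engulfment
invasion            a small block of low-tension yellow cells is drawn in between
                    high-tension green cells (2 gamma_gy < gamma_gg)
checkerboard        heterotypic contact strongly favoured over both homotypic
                    tensions, driving maximal mixing
==================  =============================================================

Tension magnitudes are free parameters of the model; the defaults below sit
comfortably inside each scenario's inequality and are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .mechanics import SimConfig
from .mesh import MEDIUM, Tissue
from .simulate import Trajectory, run_simulation
from .tensions import TensionTable
from .voronoi import to_monoline, voronoi_tissue

SCENARIO_NAMES = ("annealing", "cell_engulfment", "tissue_engulfment",
                  "sorting", "invasion", "checkerboard")


class ScenarioError(ValueError):
    """Raised when parameters violate a scenario's defining inequality."""


@dataclass
class Scenario:
    name: str
    tissue: Tissue               # master polyline tissue (pre-refinement)
    tensions: TensionTable
    config: SimConfig

    def monoline_tissue(self) -> Tissue:
        return to_monoline(self.tissue)


_DEFAULT_N = {
    "annealing": 50,
    "cell_engulfment": 2,
    "tissue_engulfment": 30,
    "sorting": 200,
    "invasion": 46,
    "checkerboard": 60,
}

_DEFAULT_TENSIONS: Dict[str, Dict[Tuple[str, str], float]] = {
    "annealing": {("cell", "cell"): 1.0, ("cell", MEDIUM): 1.0},
    "cell_engulfment": {
        ("green", "green"): 1.0, ("yellow", "yellow"): 1.0,
        ("green", "yellow"): 1.0,
        ("green", MEDIUM): 1.0, ("yellow", MEDIUM): 3.0,
    },
    "tissue_engulfment": {
        ("green", "green"): 1.6, ("yellow", "yellow"): 1.0,
        ("green", "yellow"): 1.0,
        ("green", MEDIUM): 1.0, ("yellow", MEDIUM): 3.0,
    },
    "sorting": {
        ("green", "green"): 1.0, ("yellow", "yellow"): 1.0,
        ("green", "yellow"): 1.6,
        ("green", MEDIUM): 2.0, ("yellow", MEDIUM): 1.2,
    },
    "invasion": {
        ("green", "green"): 2.4, ("yellow", "yellow"): 0.8,
        ("green", "yellow"): 1.0,
        ("green", MEDIUM): 1.5, ("yellow", MEDIUM): 0.8,
    },
    "checkerboard": {
        ("green", "green"): 1.0, ("yellow", "yellow"): 1.0,
        ("green", "yellow"): 0.2,
        ("green", MEDIUM): 1.0, ("yellow", MEDIUM): 1.0,
    },
}


def _check_inequalities(name: str, g: TensionTable) -> None:
    if name == "annealing":
        vals = {gamma for _, gamma in g.items()}
        if len(vals) != 1:
            raise ScenarioError("annealing requires one uniform tension on "
                                "every interface class")
    elif name in ("cell_engulfment", "tissue_engulfment"):
        lhs = g.get("green", MEDIUM) + g.get("green", "yellow")
        rhs = g.get("yellow", MEDIUM)
        if not lhs < rhs:
            raise ScenarioError(
                f"engulfment requires gamma_gm + gamma_gy < gamma_ym "
                f"(got {lhs:.3g} >= {rhs:.3g})")
    elif name == "sorting":
        het = g.get("green", "yellow")
        hom = 0.5 * (g.get("green", "green") + g.get("yellow", "yellow"))
        if not het > hom:
            raise ScenarioError(
                f"sorting requires gamma_gy > (gamma_gg + gamma_yy)/2 "
                f"(got {het:.3g} <= {hom:.3g})")
    elif name == "invasion":
        if not 2 * g.get("green", "yellow") < g.get("green", "green"):
            raise ScenarioError(
                "invasion requires 2 gamma_gy < gamma_gg so heterotypic "
                "contact is energetically preferred")
    elif name == "checkerboard":
        het = g.get("green", "yellow")
        if not (het < g.get("green", "green") and het < g.get("yellow", "yellow")):
            raise ScenarioError(
                "checkerboard requires gamma_gy far below both homotypic "
                "tensions")
    else:
        raise ScenarioError(f"unknown scenario {name!r}; "
                            f"choose from {SCENARIO_NAMES}")


def build_scenario(name: str, n_cells: Optional[int] = None, seed: int = 0,
                   size_variation: Optional[float] = None,
                   tensions: Optional[TensionTable] = None,
                   config: Optional[SimConfig] = None) -> Scenario:
    """Construct tissue + tension table + config for one named scenario."""
    if name not in SCENARIO_NAMES:
        raise ScenarioError(f"unknown scenario {name!r}; "
                            f"choose from {SCENARIO_NAMES}")
    n = n_cells if n_cells is not None else _DEFAULT_N[name]
    sv = size_variation if size_variation is not None else (
        0.5 if name == "annealing" else 0.3)
    gam = tensions if tensions is not None else TensionTable(
        _DEFAULT_TENSIONS[name])
    _check_inequalities(name, gam)

    if name == "annealing":
        tissue = voronoi_tissue(n, seed, sv, type_label="cell")
    else:
        tissue = voronoi_tissue(n, seed, sv, type_label="green")
        _assign_types(name, tissue, seed)
    gam.assign(tissue)

    cfg = config if config is not None else SimConfig(seed=seed)
    if config is None and name in ("tissue_engulfment", "invasion",
                                   "checkerboard"):
        # scenarios whose tension tables frustrate junction balance churn
        # through rapid reverse exchanges without a lockout
        cfg = cfg.replace(embargo_steps=20)
    return Scenario(name, tissue, gam, cfg)


def _assign_types(name: str, tissue: Tissue, seed: int) -> None:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cids = sorted(tissue.cells)
    cx = {c: tissue.cell_centroid(c)[0] for c in cids}
    if name == "cell_engulfment":
        # the cell with the higher medium tension (yellow) is the engulfed one
        left = min(cids, key=lambda c: cx[c])
        for c in cids:
            tissue.cells[c].type_label = "yellow" if c == left else "green"
    elif name == "tissue_engulfment":
        order = sorted(cids, key=lambda c: cx[c])
        half = len(order) // 2
        for c in order[:half]:
            tissue.cells[c].type_label = "green"
        for c in order[half:]:
            tissue.cells[c].type_label = "yellow"
    elif name == "invasion":
        order = sorted(cids, key=lambda c: cx[c])
        n_inv = max(1, round(len(order) * 6 / 46))
        for c in order[:n_inv]:
            tissue.cells[c].type_label = "yellow"
        for c in order[n_inv:]:
            tissue.cells[c].type_label = "green"
    elif name in ("sorting", "checkerboard"):
        for c in cids:
            tissue.cells[c].type_label = (
                "yellow" if rng.random() < 0.5 else "green")
        labels = {tissue.cells[c].type_label for c in cids}
        if len(labels) < 2:  # pathological tiny tissues
            tissue.cells[cids[0]].type_label = (
                "green" if "yellow" in labels else "yellow")
    tissue.bump()


def run_pair(scenario: Scenario) -> Tuple[Trajectory, Trajectory]:
    """Run the monoline and polyline models from the identical initial mesh.

    Both runs start from the same seeded tessellation and differ only in
    mode (cell-cell edges straight vs segmented).
    """
    mono_cfg = scenario.config.replace(mode="monoline")
    poly_cfg = scenario.config.replace(mode="polyline")
    mono = run_simulation(scenario.monoline_tissue(), scenario.tensions,
                          mono_cfg, scenario=scenario.name)
    poly = run_simulation(scenario.tissue, scenario.tensions, poly_cfg,
                          scenario=scenario.name)
    return mono, poly
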
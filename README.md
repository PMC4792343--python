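# polycell

Finite-element mechanics of 2D cell aggregates with **polyline** (segmented,
curvable) cell edges, alongside the classical **monoline** (straight-edge)
vertex model as its exact special case.

## The scientific problem

In aggregates of embryonic cells, mechanics is dominated by net interfacial
tensions γ along the cell boundaries and by the effective viscosity μ of the
cytoplasm.  Nearly all cell-level models approximate cell-cell edges as
straight rods between triple junctions.  That approximation is not
innocent: a straight edge acts like a beam, transmitting an equivalent
transverse shear

    V = ½ · Δp · L

(Δp the intracellular pressure difference across the edge, L its length) to
its end junctions.  These virtual shear forces distort junction angles away
from the Young force-balance angles

    cos θ_ij = (γ_k² − γ_i² − γ_j²) / (2 γ_i γ_j),

corrupt any method that infers tensions from observed contact angles, and
can physically arrest motions — engulfment and invasion foremost — that real
cells perform easily.  `polycell` implements the remedy: each edge is a
polyline of short segments joined by intermediate nodes (created and removed
on the fly), so edges can bow under pressure like a discretised membrane
while carrying one tension per interface.  The package provides

* the overdamped mechanics: tension force assembly, per-cell grounded
  dashpots with the half-weighted intermediate-node denominator, and
  Lagrange area constraints solved per step as a saddle-point system
  (pressures fall out as the multipliers);
* discrete events: T1 neighbour exchanges with a minimum-length trigger,
  reverse-exchange embargo, segment refinement/coarsening, and the
  approximation of quad junctions and rosettes by closely spaced triple
  junctions;
* seeded Voronoi initial conditions and six canonical cell-interaction
  scenarios (annealing, cell and tissue engulfment, sorting, invasion,
  checkerboard), each defined by an inequality on its tension table;
* the comparison metrics: least-squares circular-arc fits, Young angles and
  per-junction RMS errors, curvature / boundary-length / displacement time
  series, and monoline-vs-polyline discrepancy percentages;
* text snapshot persistence, SVG frame rendering, and a thin CLI
  (`polycell run / compare / render`).

It is intended for modellers studying interfacial-tension-driven cell
rearrangement and for generating synthetic ground-truth data (shapes with
known tensions) to validate force-inference methods.

## Worked example

A single cell with uniform boundary tension must round up into a circle
whose internal pressure is γ/R (the 2D pressure-vessel / Young-Laplace
limit):

```bash
$ python examples/01_laplace_relaxation.py
terminated: stationary after 68 steps
isoperimetric ratio 4*pi*A/P^2 = 0.99964  (1 = circle)
cell pressure = 2.0004,  gamma/R = 2.0000
The two numbers agree because at equilibrium the tension of the
curved boundary is balanced by the pressure jump across it.
```

The isoperimetric ratio says the terminal polygon is a circle to within the
segment discretisation; the Lagrange multiplier of the area constraint
(the cell pressure, 2.0004) matches the analytic γ/R = 2 to 0.02 %.

The other examples follow the same pattern, one capability each:
`02_annealing_angle_errors.py` (junction-angle fidelity of the two models),
`03_engulfment_dichotomy.py` (complete vs arrested engulfment),
`04_invasion_displacement.py` (invasion depth), `05_cli_trajectory.py`
(persistence, metrics tables and SVG frames).

## Layout

```
src/polycell/      mesh, mechanics, topology, voronoi, scenarios,
                   metrics, tensions, simulate, io, cli
examples/          one short narrative script per capability
tests/             unit + property tests and end-to-end acceptance checks
scripts/           acceptance.py (see above)
docs/methods.md    model assumptions, parameters, numerics, limitations
```
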
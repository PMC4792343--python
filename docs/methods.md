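# Methods

## Model

`polycell` simulates a finite, planar aggregate of cells surrounded by
culture medium.  The mechanical ingredients are deliberately few:

* **Interfacial tension.**  Every interface (cell-cell or cell-medium)
  carries a constant tension γ, set by the unordered pair of region types it
  separates.  An interface is a chain of straight rod segments; all segments
  of one edge carry the same tension.  The nodal force is the vector sum of
  the rod tensions framing into each node, which is exactly the negative
  gradient of the boundary energy E = Σ γ·length (a unit test holds the
  assembly to this identity at 10⁻⁶ relative error).
* **Viscous cytoplasm.**  Each cell contributes to every one of its nodes a
  pair of orthogonal grounded dashpots with coefficient
  k = `damping_scale`·μ·A / n_eff, where n_eff counts the cell's junction
  nodes plus *one half* of its intermediate nodes.  The half weighting keeps
  the cell's total drag approximately independent of how finely its edges
  are segmented.  Grounding the dashpots (to the lab frame rather than
  pairwise) makes the damping matrix C diagonal and positive definite, so
  rigid modes are damped and every step is solvable without extra anchoring.
  The proportionality constant only rescales time; it defaults to 1.
* **Area constraints.**  Cells are incompressible in 2D: each cell's area is
  held at its target by a Lagrange multiplier.  One step solves

      [ C/Δt  Gᵀ ] [Δu]   [f]
      [ G     0  ] [λ ] = [r]

  with G the shoelace area gradients evaluated at the step's start and
  r = A₀ − A a drift-restoring right-hand side.  Because C is diagonal the
  saddle system is reduced exactly to its Schur complement
  S = G(ΔtC⁻¹)Gᵀ — a dense SPD matrix with one row per cell — and solved by
  Cholesky factorisation; this is algebraically identical to factorising the
  full saddle matrix and considerably faster at these sizes (≤ a few hundred
  cells).  Cell pressures are reported as p = −λ with the medium at zero, so
  a lone tense cell has positive internal pressure and the Young-Laplace
  relation κ = Δp/γ can be checked without sign gymnastics.

Geometry is updated-Lagrangian: positions, forces, C and G are rebuilt on
the deformed configuration every step.

**Monoline vs polyline.**  The polyline model lets edges curve by carrying
intermediate nodes, maintained by refinement rules (below).  The monoline
model is the classical straight-edge special case: nodes exist only at the
junctions and no intermediate node is ever created.  One degeneracy guard
applies at initialisation: a cell-medium chain is kept segmented when its
cell has fewer than three boundary edges, because straightening it would
flatten the cell onto a chord — the two-cell engulfment aggregate is the
canonical case (its two junctions would otherwise pin all three interfaces
onto the same line, giving zero-area cells).  With the segment cap raised
above the longest edge, the polyline engine reproduces a monoline run
bit-for-bit; a test asserts this.

The mechanical difference between the two models is the transverse
(equivalent) shear V = ½·Δp·L that a straight pressurised edge of length L
transmits to its end junctions.  In the monoline model L is the whole edge
and the shear is large enough to distort junction angles and arrest motions
such as engulfment and invasion; in the polyline model L is one short
segment and the shear nearly vanishes, the intermediate nodes instead
bowing until tension components balance the pressure like a discretised
membrane.  `equivalent_shear` exposes the diagnostic.

## Discrete events

Each step applies, in order: segment coarsening, neighbour exchanges,
segment refinement, then the viscous solve.  All length thresholds are
fractions of the current mean cell diameter D (mean of equal-area-circle
diameters):

* **Refinement** (polyline only): any segment longer than `seg_max_frac`·D
  (default 0.25) is divided into two equal segments with a new intermediate
  node; repeated to compliance.  At this default, near-isotropic interior
  edges settle at roughly 2–4 intermediate nodes, with longer curved
  perimeter edges carrying proportionally more.
* **Coarsening**: any segment shorter than `seg_min_frac`·D (default 0.025)
  merges its end nodes — two intermediates collapse to the segment midpoint;
  an intermediate merges into its junction, which keeps its position; a
  short junction-junction edge is passed to the neighbour-change rule.
* **T1 neighbour exchange**: a cell-cell edge between two junctions shorter
  than δ = `t1_threshold_frac`·D (default 0.025) is eliminated; the two
  previously separated regions gain a new edge through the old midpoint,
  perpendicular to the old edge, with length `post_t1_length_frac`·D
  (default 0.0375, deliberately above δ so the exchange cannot immediately
  reverse).  The new edge's tension is looked up from the tension table by
  its new interface class.  An optional embargo timer additionally locks
  fresh edges for `embargo_steps` steps; it is enabled (20 steps) for the
  tissue-engulfment, invasion and checkerboard scenarios, whose frustrated
  tension tables otherwise churn through rapid reverse exchanges.  When
  several edges qualify in one step they are processed shortest-first, and
  any candidate whose neighbourhood was already modified that step waits —
  this makes runs deterministic.
* **Short cell-medium edges** have no neighbour pair to exchange; their two
  junctions are merged instead (surface smoothing), and the merged node is
  renormalised.  When every other edge at the merged pair spans the same two
  junctions, the merge *closes a wrap*: the spanning edges become closed
  loops, the engulfed cell becomes an inclusion and the engulfing cell a
  pinched annulus.  Cell boundaries may therefore decompose into several
  rings sharing a pinch node; the area and its gradient are computed on a
  single traversal that threads hole rings clockwise through the pinch.
* **Quad junctions and rosettes** are approximated by closely spaced triple
  junctions: a node with four or more incident edges is replaced by a chain
  of 3-valent nodes joined by connector edges of length ≈ `seg_min_frac`·D.
  The cyclic order of the incident edges is recovered topologically (by
  walking edge→shared region→edge around the node), each connector takes
  the tension of the interface it lies on, and among the possible
  regroupings the one with the lowest total connector tension is chosen —
  for a quad junction this selects between re-creating the collapsed
  interface and performing the exchange.  Connectors are flagged so angle
  scoring can exclude compound junctions, and are embargoed briefly so a
  frustrated junction cannot re-split every step.  The same machinery
  doubles as a fallback for a shrinking edge whose plain T1 is blocked
  (e.g. it would reduce a triangle cell to two edges): once it falls below
  δ/2 its junctions are merged and re-split, or — when it is the last
  cell-cell contact of a trapped lens cell — pinched off as an inclusion.

## Time stepping and numerical choices

* The explicit step is stability-limited by the transverse relaxation of
  the shortest, least-damped segment; with `adaptive_dt` (default) the step
  is capped at `stability_safety`·½·min(c·L/γ) over segments (safety 0.35).
  The nominal `dt` (default 2·10⁻³ in model units of μD/γ) is an upper
  bound.
* Segments below 0.5 % of a cell diameter — far under the coarsening
  threshold, so only transiently present or structurally stuck — have their
  tension tapered linearly to zero.  A stuck pair of junctions then behaves
  as one compound junction instead of pinning the stable time step at zero.
  This affects no segment of a well-formed mesh.
* A run ends early as *stationary* when the largest per-step displacement,
  rescaled to the nominal dt (i.e. a velocity criterion), stays below
  `stationary_tol`·D (default 10⁻⁵) for `stationary_window` (50)
  consecutive steps; otherwise it ends at `n_steps` as *max_steps*.
  Scenarios whose tension tables violate the junction triangle inequality
  (invasion, checkerboard) have no true equilibrium and typically end at
  the step cap while their summary metrics have long saturated.
* Degenerate inputs: zero-length segments, non-positive cell areas and
  singular constraint blocks raise typed errors (`GeometryError`,
  `SolverError`); a mid-run solver failure truncates the trajectory with
  status *error* rather than corrupting it.

## Initial conditions

`voronoi_tissue` samples generator points at unit density, applies three
Lloyd iterations (regularising shape, not size), jitters the points by
`size_variation` × the mean spacing, and clips the tessellation to the
convex hull buffered by 0.4 spacing, yielding a finite aggregate with a
rounded outline.  Coordinates are rescaled so the mean cell diameter is
exactly 1; target areas are the as-built polygon areas, so the intentional
size variation produces permanent pressure differences between neighbours.
With the default `size_variation` = 0.5 the cell-area coefficient of
variation is ≈ 0.45–0.5, similar to a Poisson-Voronoi tessellation.  The
annealing scenario uses exactly this default; it is the one free parameter
of that study that the model does not pin down internally, and the terminal
monoline angle-error level scales with it (more size variation → larger
pressure differences → larger straight-edge shear).

The six scenario builders assign cell types (by position for the engulfment
and invasion layouts, randomly 50/50 for sorting and checkerboard) and
supply tension tables that provably satisfy each scenario's defining
inequality — uniform tension for annealing; γ_gm + γ_gy < γ_ym for
engulfment (spreading condition; defaults 1 + 1 < 3); heterotypic above the
homotypic mean for sorting (1.6 > 1); 2γ_gy < γ_gg for invasion
(2 < 2.4); γ_gy far below both homotypic tensions for checkerboard
(0.2 ≪ 1).  Construction fails loudly, naming the inequality, if an
override violates it.  The magnitudes themselves are free parameters chosen
once with comfortable margin; only the inequalities are meaningful.

## Measurements

* **Arc fits**: least-squares circles (Taubin's algebraic fit) through an
  edge's chain points; chains whose deviation from the chord is below
  10⁻⁹ of scale report infinite radius.  Curvature sign is a chord-side
  convention (positive bulging left of the first→last direction).
* **Young angles**: the force-balance angles at a triple junction,
  cos θ_ij = (γ_k² − γ_i² − γ_j²)/(2γ_iγ_j); a junction whose tensions
  violate the triangle inequality has no equilibrium and is skipped.
* **Junction scoring**: every 3-valent junction is scored (junctions
  touching connector edges of split rosettes are excluded; `interior_only`
  restricts to junctions whose three interfaces are all cell-cell).
  Observed angles come from arc tangents (`arc_tangent`) or from the first
  chain segment (`nearest_segment`, the only choice for monoline edges);
  observed and Young angles are paired by interface identity, not by
  sorting.  Each junction reports the RMS of its three angle deviations in
  degrees.  Edges with a single segment are measured by their chord either
  way; on a curved interface this contributes ≈ κL/2 of tangent error and
  is the source of the occasional outlier junction.
* **Time series** (`aggregate_metrics`): per saved snapshot — median and
  mean junction RMS angle error; mean |κ| over a chosen interface class
  normalised by the equal-area-circle radius of the average cell; total
  class boundary length over its initial value; mean centroid displacement
  of tracked cells (those initially on the heterotypic interface for
  engulfment/invasion analyses; horizontal component for invasion) per
  initial mean cell diameter; and dimensionless time t* = t·γ_ref/(μ·D)
  with γ_ref the initial mean edge tension — the prefactor is a convention
  and only scales the abscissa.
* **Model comparison** (`compare_trajectories`): discrepancy
  |a−b|/((a+b)/2)·100 between matched monoline/polyline runs, averaged by
  trapezoidal integration over the overlapping dimensionless-time span —
  except curvature, which a monoline model reports as exactly zero and
  which is therefore compared at the terminal configurations only.

## What the generator does and does not emulate

The synthetic tissues capture the geometry and mechanics the model needs:
polygonal cells of realistic size dispersion, a rounded free surface, and
interfacial-tension-dominated dynamics.  They do not emulate active
protrusion or crawling, elastic (storage) response of the cytoplasm, cell
division, apoptosis or extrusion, chemotaxis, or three-dimensional effects;
passing tests therefore speak to the interfacial-tension mechanism in
isolation, not to any of those processes.  Invading cells here arrest after
roughly one cell diameter precisely because no motile machinery exists in
the model.

## Problem sizes used in the shipped analyses

The acceptance script and the slower end-to-end tests use 50-cell annealing
aggregates over three seeds (the scale at which the angle-error statistics
are stable to well under a degree between seeds), the two-cell engulfment
doublet, a 46-cell invasion field with six invaders, and a 50-cell sorting
run for the conservation check.  Runs go to stationarity with a step cap of
4–8·10⁴; the segment-count study caps at 4·10⁴ steps, by which point the
nearest-segment error statistic has long converged even when slow creep
continues.

## Known limitations

* Monoline annealing reproduces the reported *mean* junction error but its
  error distribution is right-skewed (quiet interior junctions, large
  surface-junction errors), so its *median* sits a few degrees below the
  reported one; the level scales with the unquantified initial size
  variation (see above).
* Rosettes are never stable objects; the compound-triple-junction
  approximation churns in frustrated regions (checkerboard, deep invasion)
  and is rate-limited by the connector embargo rather than by mechanics.
* A pinched annulus keeps its pinch node forever; a fully engulfed cell
  does not detach and drift.
* No rosette-aware angle scoring: compound junctions are simply excluded.
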
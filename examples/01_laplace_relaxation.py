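"""A lone tense cell rounds up: the 2D pressure-vessel (Young-Laplace) limit.

Builds a single polygonal cell, lets its uniform boundary tension relax it to
stationarity under the area constraint, and checks that the terminal shape is
a circle whose internal pressure equals gamma / R.
"""

import math

import polycell as pc
from polycell.mechanics import MechAssembly

tissue = pc.voronoi_tissue(1, seed=0)
config = pc.SimConfig(seg_max_frac=0.04, seg_min_frac=0.01, n_steps=20000)
tensions = pc.TensionTable.uniform(1.0, ["cell"])

traj = pc.run_simulation(tissue, tensions, config)
final = traj.final

area = final.cell_area(0)
perimeter = sum(final.edge_length(e) for e in final.edges)
isoperimetric = 4 * math.pi * area / perimeter ** 2

asm = MechAssembly(final)
_, lam, _ = asm.solve(asm.positions(), config.dt)
pressure = -lam[0]
radius = math.sqrt(area / math.pi)

print(f"terminated: {traj.status} after {traj.snapshots[-1].step} steps")
print(f"isoperimetric ratio 4*pi*A/P^2 = {isoperimetric:.5f}  (1 = circle)")
print(f"cell pressure = {pressure:.4f},  gamma/R = {1 / radius:.4f}")
print("The two numbers agree because at equilibrium the tension of the")
print("curved boundary is balanced by the pressure jump across it.")
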
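# Example scenario configuration for `polycell run`.
#
#   polycell run --config examples/annealing.yaml --out out/poly
#   polycell run --config examples/annealing.yaml --out out/mono --mode monoline
#   polycell compare --mono out/mono --poly out/poly
#   polycell render --traj out/poly --out out/frames
#
# Any SimConfig field (dt, seg_max_frac, embargo_steps, ...) may be set here;
# tensions may be overridden with a mapping like
#   tensions: {"cell,cell": 1.0, "cell,medium": 1.0}

scenario: annealing
n_cells: 30
seed: 1
size_variation: 0.5
n_steps: 10000
record_stride: 500
mode: polyline
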
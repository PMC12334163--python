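# regentrack

Tools for studying how acquisition settings shape automated nucleus
tracking in long-term 3D time-lapse microscopy — built around a fully
synthetic benchmark of a regenerating epithelium with known ground
truth.

Long-term live imaging of regenerating tissue must ration light: finer
sampling in z, xy or time improves the ability to detect and follow
nuclei in a crowded epithelium, but every extra voxel costs exposure
and photodamage. `regentrack` reproduces this trade-off end to end at
desk scale. It simulates a calibrated 4D recording (anisotropic
0.31 × 0.31 × 1.24 µm voxels, 10-min frames, four imaging replicates
per slice) of nuclei that migrate toward a wound, divide in a
quiescence–burst–decline schedule, and die as bright pyknotic bodies,
under depth attenuation, photobleaching with heat-shock recovery, and
Poisson + Gaussian noise. From one master recording it derives five
reduced acquisitions that all correspond to *exactly the same* total
light exposure (¼ of the master), trading z-sampling, frame rate,
lateral sampling and frame averaging against each other. A classical
pipeline — multi-scale blob detection with probability threshold 0.7
and radius bounds [1 µm, 5 µm], flow-assisted nearest-neighbour linking
with a 5 µm gate and at most two daughters per parent, and backward
tracing of selected cells with flow interpolation — is then scored
against the known lineage forest.

Scoring follows the acyclic-oriented-graph-matching (AOGM) family of
tracking metrics: the prediction is edited into the reference with
weighted vertex operations (splits NS, missing FN, spurious FP) and
edge operations (spurious ED, missing EA, wrong division semantics EC),
and

```
TRA = 1 − min(AOGM, AOGM₀) / AOGM₀,   AOGM₀ = w_FN·|V_gt| + w_EA·|E_gt|
```

with DET the vertex-only analogue. Detection and linking
precision/recall, the raw AOGM cost as a proofreading-effort estimate,
and depth-stratified recall tables (5 µm z-bins) complete the report.
A lineage forest obeys `n_tracks = n_spots − n_links` by construction;
the package enforces it everywhere.

## Worked example

```python
import regentrack as rt

config = rt.li_synth_mini()                 # small test-sized recording
movie, forest, events = rt.simulate_recording(config)
print(f"tracks={rt.count_trees(forest)}  spots={forest.n_spots} "
      f"links={forest.n_links}  divisions={events.n_divisions}")

spots = rt.detect_volume(movie.averaged(0), movie.grid, rt.DetectionParams(), t=0)
print(f"frame 0: {len(spots)} nuclei detected of {len(forest.spots_at(0))} present")

flow = rt.ground_truth_flow_field(forest, movie.grid)

detected, next_id = [], 1
for t in range(movie.n_timepoints):
    frame_spots = rt.detect_volume(movie.averaged(t), movie.grid, t=t, id_start=next_id)
    detected.extend(frame_spots)
    next_id += len(frame_spots)
pred = rt.link_forward(detected, flow)
report = rt.evaluate_forests(forest, pred, depth_bin=5.0)
print(f"DET={report.det:.3f}  TRA={report.tra:.3f}  effort={report.effort:.1f}")
```

prints

```
tracks=12  spots=314  links=302  divisions=9
frame 0: 12 nuclei detected of 12 present
DET=1.000  TRA=1.000  effort=0.000
```

The mini recording is shallow (13.6 µm), so every nucleus sits far
above the detection limit and the pipeline reconstructs the forest
perfectly — `tracks = spots − links` (314 − 302 = 12), `DET = TRA = 1`,
zero edits needed. The full benchmark (`rt.li_synth()`, 60 frames,
20 z-slices spanning 23.5 µm under a 15 µm attenuation length) is
detection-limited at depth; running the trade-off experiment on it,

```sh
regentrack experiment --out results/
```

produces a five-row table (one per equal-exposure condition) in which
detection recall falls monotonically with depth, the full-z condition
clearly beats the standard half-z acquisition in the deepest layers,
and the doubled-frame-rate conditions score comparable accuracy but
roughly twice the proofreading effort, because twice as many time
points need correcting.

Beyond the experiment driver, the library answers lineage questions
directly: `backtrack` traces any selected cell backward through missing
detections by flow interpolation, `register_clouds`/`transfer_labels`
map post-fixation stained nuclei onto the last live frame, and
`progenitor_analysis` groups labelled terminal cells into clones and
counts the divisions separating them from their progenitors.

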
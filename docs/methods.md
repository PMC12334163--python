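# Methods

`regentrack` builds a fully synthetic but statistically realistic 4D
recording of nuclei in a regenerating epithelium, derives equal-exposure
acquisition variants from it, runs a classical detection-and-linking
pipeline, and scores the results against the known ground truth with
graph-edit (AOGM) tracking metrics. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark can and cannot say about real recordings.

## The lineage-forest data model

A *spot* is one nucleus at one time point: position `(z, y, x)` in µm,
radius, intensity, optional categorical label, and an `interpolated`
flag. A *link* joins a parent spot at time `t` to a child at `t+1`.
The forest invariants — at most one parent, at most two children, links
advance time by exactly one — make every connected component a rooted
tree (one cell's clonal descent, branching at divisions), so

```
n_tracks = n_spots − n_links
```

holds identically; the package checks it on every mutation.
Coordinates are physical microns with `z = 0` at the coverslip-proximal
slice and voxel index `i` at position `i × voxel_size` (centre-of-voxel,
0-based), so every distance threshold in the pipeline (5 µm linking
gate, 3 µm suppression, 5 µm depth bins) is calibration-independent.

Time decimation (`reduce_time`) keeps every k-th frame, re-indexes time
to consecutive integers, and relinks each kept spot to its nearest kept
descendants; a division falling on a removed frame therefore reappears
as two links from the retained ancestor. With `k = 2` a retained spot
can acquire at most two such descendants; for larger `k` a surplus
(two divisions inside one removed gap) is resolved by keeping the two
earliest descendants and promoting the rest to new roots. A halved
55-frame annotation keeps 28 frames.

## The synthetic recording

The generator emulates long-term confocal imaging of H2B-labelled
nuclei in a regenerating crustacean leg: anisotropic voxels
(0.31 × 0.31 × 1.24 µm), 10-minute frames, four imaging replicates per
slice. The packaged benchmark configuration (`li_synth`, seed 42) uses
60 frames, 20 z-slices and a 160 × 160 px lateral field with 40
founder cells; a faster `li_synth_mini` (20 frames, 12 slices) serves
the unit tests. Field size was set so the recording fits comfortably
in desk-scale memory while preserving the nucleus density (about
1.5 × 10³ µm³ per cell) of the full-scale configuration.

**Cell behaviour.** Cells perform a damped random walk
(`motility_sd` 0.5 µm/frame) with a wound-directed drift
(0.4 µm/frame) that is active only during an early migration phase
(first quarter of the recording) — in the recordings this emulates,
epithelial migration precedes the proliferation burst and nuclear
positions stabilise later. Short-range repulsion pushes neighbours
apart to `min_separation` (5.5 µm), giving epithelial packing instead
of a pile-up at the wound plane; the 5 µm nearest-neighbour linking
gate of point-based trackers presupposes neighbour spacing above the
gate, so this is the regime the method is designed for. The division
schedule is a quiescence → burst → decline probability profile
(0 / 0.04 / 0.01 per cell per frame for the benchmark); daughters are
placed one radius apart along a random axis and sit out a 5-frame
refractory period before they may divide again. Apoptosis
(probability 0.002/frame) renders one final bright pyknotic spot
(3× intensity) before the nucleus disappears. Every birth, division
and apoptosis is recorded in an event log kept consistent with the
emitted forest — it is the independent oracle for division counts and
clone depths.

**Imaging model.** Nuclei are rendered as anisotropic Gaussians whose
width combines the nucleus extent (`σ = r/√2`, radius ~2 µm) with the
PSF (0.15 µm lateral, 0.6 µm axial) in quadrature — adequate for
point-detection tracking, deliberately not a textured-chromatin model.
Intensity is scaled by depth attenuation `exp(−z/ℓ)` (ℓ = 15 µm),
photobleaching `exp(−k·exposures)` (k = 0.002 per exposure, four
exposures per frame) with a ×1.3 step recovery at frame 30 (heat-shock
re-expression), and pyknotic brightening. Each replicate draws
independent Poisson shot noise (variance = 20 × signal) plus Gaussian
read noise (sd 1000 counts) on a 200-count background. The photon
budget puts the brightest nuclei at a per-voxel peak SNR of ≈ 8 per
replicate, which leaves the bottom half of the stack genuinely
detection-limited under the 15 µm attenuation length — the regime the
depth-stratified analysis is about. Everything is deterministic given
the configuration seed, and `simulate_recording(..., return_clean=True)`
exposes the noiseless scene so fresh noise realisations can be drawn
for repeat experiments.

Two idealised auxiliaries stand in for a trained detection and flow
model: `render_probability_map` (value 1 at each nucleus centre,
Gaussian falloff with the nucleus radius, maximum-combined) and
`ground_truth_flow` (each voxel carries the frame-to-frame displacement
of the nearest tracked cell, optionally noised).

## Equal-exposure acquisition conditions

Five subsampling recipes derive reduced acquisitions from the master
recording: #1 half z + half t with 4-replicate averaging, #2 full z /
half t / 2 replicates, #3 half z / full t / 2 replicates, #4 half xy
sampling on both lateral axes with 4 replicates, #5 single replicate.
Relative exposure is `z_keep · t_keep · xy_keep² · n_average/4`, which
is exactly 1/4 for all five — the design constraint that makes the
comparison fair. Decimation keeps even indices (so 55 frames keep 28),
averaging takes the arithmetic mean of the *first* n replicates
(replicates accumulate sequentially during a scan) rounded half-up, and
pixel dropping rather than binning is used laterally so the exposure
ledger is unchanged. Spatial decimation does not move physical
coordinates, so ground-truth annotations only need time reduction.

## Detection

A multi-scale Laplacian-of-Gaussian detector stands in for the learned
probability map. Numerical choices that matter:

- **Physical units.** Per-axis second derivatives are divided by
  `voxel_size²`, so the response is true physical curvature on any
  anisotropic grid (a naive index-space Laplacian mis-weights the z
  axis by `dz²`).
- **Band limiting.** Per-axis smoothing is clamped to ≥ 0.6 voxel.
  Below that, a discrete Gaussian derivative degenerates into a raw
  finite difference whose noise *falls* as the grid coarsens,
  spuriously rewarding undersampled axes; the clamp makes an
  undersampled axis pay its physical price (over-smoothing). 0.6 was
  chosen as the value at which the discrete filter's noise-gain ratio
  between a 1.24 µm and a 2.48 µm z-grid best matches the continuous
  filter at the nucleus-matched scale.
- **Noise-referenced normalisation.** The voxel noise sd is estimated
  from the raw image (wavelet-detail estimator — robust to smooth
  structure, so it works in crowded fields and small windows where a
  median-based floor on the response map fails) and propagated into
  response units through the measured white-noise gain of the
  mid-ladder, nucleus-matched filter. The max-over-scales response
  excess over a 5σ floor is mapped through the saturating transform
  `p = r'/(r' + 15σ)`. One *global* noise level is essential: scoring
  each voxel against its own selected scale's noise would rank a
  barely-positive shoulder of a coarse, heavily-averaging filter above
  a genuine nucleus peak, and would break the monotonicity between
  confidence and response on which local-maximum extraction relies.
  The output reads like a calibrated detector's probability — near 1
  for blobs far above the noise, falling smoothly toward the detection
  limit. Noiseless volumes (σ below 10⁻⁴ of the dynamic range) fall
  back to a min-max rescale.
- **Cluster rejection.** A nucleus's scale profile must peak within the
  radius range: voxels whose response is still growing at a sentinel
  scale of twice the ladder top (clusters of nuclei, background
  plateaus) are zeroed.

Centre extraction applies the 0.7 probability threshold, takes
26-connected local maxima, estimates the radius from the best-responding
scale clamped to [1 µm, 5 µm], and suppresses candidates closer than
3 µm centre-to-centre greedily by descending value (ties broken by
smaller index — deterministic). A division-detector variant
(`metaphase_response`, intensity × blob response, threshold 0.8) flags
metaphase-like bright compact nuclei.

## Linking and backtracking

Forward linking predicts each spot's origin by subtracting the flow
sampled at its position (nearest-voxel sampling at the child — the
backward-warp convention) and assigns candidate pairs within the 5 µm
gate greedily in ascending distance order, at most two daughters per
parent, one parent per child; unmatched spots start new tracks. Greedy
nearest-neighbour (not global assignment) matches the semantics of the
emulated platform and is O(n log n); the test suite keeps an exhaustive
minimum-distance assignment oracle to quantify the gap (at most one
link on small random instances). With exact flow and complete
detections the predicted origin coincides with the true parent, so
relinking ground-truth spots reproduces the reference forest exactly
regardless of crowding.

Backtracking iterates from a selected cell toward `t = 0`: predict the
previous position from the flow, search detections in a local window
(either a provided spot table or the centre detector run on a windowed
volume), link to the closest detection within the vicinity radius
(default 5 µm), and otherwise interpolate a spot at the prediction.
The budget counts *consecutive* interpolations; exceeding it returns a
truncated path (a status, not an exception). A division needs no
special casing: the parent is simply the nearest detection one frame
earlier.

The classical flow estimator tiles the frame into blocks of 5 µm
half-size, locates each block in the previous frame by maximising
normalised cross-correlation over integer-voxel shifts within a 5 µm
search radius, zeroes zero-variance blocks, and interpolates block
displacements linearly to voxels. The experiment driver defaults to
the simulator's ground-truth flow instead — mirroring the emulated
platform, whose flow model is trained on the target recording itself —
which also keeps the full experiment within desk-scale runtime; block
matching remains available via `flow_source="block_matching"`.

## Evaluation

Vertex matching is per time point: predicted spots within a
ground-truth spot's radius are candidates, resolved one-to-one by
minimum-total-distance assignment (maximum cardinality first). This
replaces the mask-overlap rule of segmentation-based benchmarks because
annotations here are point + radius. Unmatched ground truth covered by
an already-matched prediction counts as a vertex split (NS); remaining
unmatched ground truth as FN; unmatched predictions as FP. Edge
operations compare links through the matched-vertex map: a predicted
link is redundant (ED) unless both endpoint images form a reference
link; missing reference links count EA; corresponding links whose
division semantics differ (source divides in one forest only) count EC.
Division-ness is derived from out-degree, since the CSV model has no
separate edge type. Weights default to (NS, FN, FP, ED, EA, EC) =
(5, 10, 1, 1, 1.5, 1), the weighting of the community benchmark this
follows; they are exposed in `AOGMWeights`.

Scores: `TRA = 1 − min(AOGM, AOGM₀)/AOGM₀` with
`AOGM₀ = w_FN·|V_gt| + w_EA·|E_gt|` (the cost of building the reference
from nothing); DET is the same with vertex-only cost over
`w_FN·|V_gt|`. Detection precision/recall come from the matching
(TP/(TP+FP), TP/(TP+FN); NS spots count as unrecalled; 0/0 ≡ 1);
linking precision/recall count a predicted link as correct iff its
endpoint images form a reference link. The linking-only mode re-links
the ground-truth spots (perfect detection) before scoring. The raw,
un-normalised AOGM cost doubles as the proofreading-effort estimate: it
is additive over disjoint unions, so it grows with recording length at
fixed per-frame quality. Depth-stratified tables bin matched and
missed ground truth by true z (5 µm bins), false positives by predicted
z, omitting bins without ground truth.

The trade-off driver subsamples the master under each condition,
reduces the ground truth, detects, links, scores everything including
the linking-only mode, and averages three repeats that draw fresh
replicate noise on the shared noiseless scene (the emulated study
averaged three independently trained model iterations; without learned
models, noise realisations are the analogous source of run-to-run
variation).

## Annotation transfer and progenitor analysis

Post-fixation stained nuclei are registered onto the final live frame
by iterative closest point with a rigid (Kabsch) or affine
(least-squares) model, initialised by centroid alignment plus
principal-axes rotation; all four proper-rotation sign choices and a
plain centroid-only start are tried and the best final residual wins,
deterministically. Optional trimming drops the worst correspondences
from each fit, absorbing outlier points; fixation distortion is handled
by the affine mode plus an acceptance-radius gate rather than non-rigid
warping. Label transfer matches transformed fixed points to live spots
one-to-one in ascending distance within the acceptance radius (default
5 µm, the linking gate). Progenitor analysis walks each labelled
terminal spot to its root, groups labelled cells by shared root into
clones, and reports per clone the progenitor position, the division
count along each labelled path, and the labelled/unlabelled split of
terminal descendants.

## What the benchmark does and does not show

The generator reproduces the statistical structure that stresses a
point-detection tracker — anisotropic sampling, depth attenuation,
bleaching with recovery, replicate noise, crowding, divisions,
apoptosis — so it can test the *machinery*: metric correctness,
equal-exposure accounting, exact recovery under ideal inputs, the
depth dependence of detection, and the directions of the acquisition
trade-offs (full z-sampling wins deep-layer detection; doubled frame
rate wins linking but multiplies the proofreading workload). These
directions emerge from the pipeline's physics — under equal exposure
the photon budget per physical volume is identical across conditions,
so what separates them is how much spatial information survives
sampling and how a band-limited detector can exploit it. The benchmark
does not reproduce textured chromatin, autofluorescent cuticle,
scattering, stage drift, or the behaviour of a trained detector on such
structure, so absolute scores are not comparable to scores on real
recordings — only the orderings and mechanisms are. An optional
sinusoidal tissue oscillation (period ~6.5 h) is provided but off by
default, since the mechanism of the pulsation it mimics is unknown.

## Problem sizes and determinism

The packaged benchmark (60 frames, 20 × 160 × 160 voxels, 4 replicates,
~3,600 spots) was sized so that the complete test suite and the
acceptance script each run in minutes on a single CPU. All randomness
flows from explicit seeds: the benchmark configuration carries seed 42;
experiment drivers and scripts split their seed into per-stage child
seeds via `SeedSequence`, so any stage can be re-run in isolation and
byte-identical outputs are reproducible end-to-end.
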
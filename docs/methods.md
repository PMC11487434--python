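# Methods

## Problem and pipeline

A vertebra reconstructed from CT as a surface point cloud is measured for
its axial rotation: the rotation of its anatomical frame about the
cranio-caudal axis relative to the scanner frame. The pipeline is
sampling → segmentation → landmark geometry → angle, with rater-agreement
statistics to compare automated against manual measurements.

All coordinates are treated as millimetres and are never rescaled on read;
units only matter for distance-valued outputs (pedicle center offsets,
noise magnitudes). Mesh faces in PLY/OBJ input are discarded — every stage
operates on point sets.

## Entropy-augmented farthest-point sampling

Plain FPS greedily selects the point with the largest minimum distance to
the already-selected set, giving uniform geometric coverage. The
entropy-augmented variant multiplies that max–min distance by a local
information weight:

    score(c) = d_min(c, S) · (1 + λ · Ĥ(c))

`Ĥ(c)` is the Shannon entropy (natural log) of the histogram of c's
`k_local` nearest-neighbour distances, min–max rescaled to [0, 1] over the
cloud. Defaults: `k_local = 16`, `B = 32` histogram bins, `ε = 1e-12`
inside the logarithm, `λ = 1`, start index 0. Ties in the greedy argmax
break to the lowest index; `λ = 0` reduces bit-for-bit to plain FPS, so the
variant inherits FPS's coverage behaviour as a limiting case.

Two numerical choices deserve note:

* Per-point neighbourhood histograms are binned on a **common range**
  (0 to the largest k-NN distance in the cloud). Auto-ranged histograms
  would normalise scale away and make the entropy blind to local density,
  which is the very signal the weight exists to capture: a point in a
  dense clump concentrates mass in few bins (low entropy), a point in a
  sparse region spreads over many (high entropy).
* A numerically degenerate distance multiset (range below float
  resolution at the requested bin count) is treated as a single occupied
  bin, giving H ≈ 0.

Fixed-size resampling draws one or more FPS/entropy-FPS subsets of 3072
points (the network's stock input size) from each labelled cloud, with
draw start indices derived from the seed; repeated draws of the same
vertebra expand a small labelled dataset.

## Segmentation network

Architecture (per cloud, coordinates normalised to the unit sphere):

* input embedding: Linear–BatchNorm–ReLU (LBR) from xyz to `base_width`
  (64 at full size);
* four encoder stages: FPS subset (ratio 1/4 per stage, so 3072 → 768 →
  192 → 48 → 12), local max-pooling over each sampled point's 16-NN patch
  in the finer level, LBR to the stage width (64/128/256/512), per-stage
  position encoding, then relation attention within 16-NN patches of the
  stage;
* position encoding: δ = φ(xyz) with φ a two-layer MLP with one ReLU;
  the stage input is ψ(concat(f, δ)) with ψ linear. Encoding is
  recomputed at every stage from that stage's coordinates;
* relation attention: `F_SA = softmax(QKᵀ/d_a)·V` with `d_a = width/4`,
  `F_RA = F_in − F_SA`, `F_out = LBR(F_RA) + F_in`. The attention scale
  divides by `d_a` itself; the conventional `√d_a` is available via
  `attention_scale="sqrt"`. Zeroing the LBR recovers the identity map —
  the block is strictly residual;
* four decoder stages: features interpolated to the finer resolution by
  inverse-distance weighting over the 3 nearest coarse points (weights
  1/(d+1e-10), normalised — the point-set realisation of trilinear
  upsampling), concatenated with the same-resolution encoder features
  (skip connection), fused by LBR;
* head: LBR + linear to per-point class scores.

The geometry (FPS levels, k-NN patches, interpolation weights) depends
only on coordinates and is built once per cloud and cached; only features
flow through the autodiff graph during training. The encoder FPS starts
from the point farthest from the centroid — a geometric, order-independent
choice that makes outputs permutation-equivariant for generic clouds.

**Normalisation statistics.** The network processes one whole cloud per
forward pass, so the "batch" for BatchNorm is the cloud itself: statistics
are computed over the current cloud's points at training *and* inference
time (instance-normalisation behaviour). Running estimates are tracked but
not used for prediction: with every cloud in a different pose, running
averages mix pose-dependent statistics and generalise poorly, while
per-cloud statistics keep inference deterministic per cloud.

**Training.** Adam, learning rate 0.003 halved every 20 epochs (the decay
factor 0.5 and batch size 4 are the pipeline's stock values; the step
interval is this implementation's choice), gradients averaged over the
batch, mean cross-entropy loss. The checkpoint with the best validation
mIoU is returned together with the per-epoch loss/mIoU log. All
initialisation and shuffling derives from one integer seed; two runs with
the same seed are bit-identical.

**Metric.** mIoU = mean over classes of TP/(TP+FP+FN), ×100. A class
absent from both prediction and truth (0/0) counts as IoU 1, so a
perfectly predicted cloud scores 100 even when a class does not occur.

The autodiff core is a ~200-line reverse-mode engine over NumPy arrays
(broadcast-aware arithmetic, matmul, relu/exp/log/sqrt, axis reductions,
gather, concat); its gradients are verified against central finite
differences in the test suite.

## Landmarks, frame, and angle

* **Endplate split**: k-means, k = 2, 10 seeded restarts. "Upper" is the
  cluster whose center projects further along the inter-center axis
  oriented toward +Z (tie-break +Y, then +X). Cluster means are the
  endplate centers.
* **Pedicle centers**: k-means, k = 2; "left" is the center with the
  smaller global-X projection (tie-break Y, then Z).
* **Frame**: origin = midpoint of the endplate centers; z = normalised
  endplate axis; y = normalised vector from the pedicle midpoint to the
  origin (anterior); x = ŷ × ẑ. y and z are *not* orthogonalised — the
  angle uses only in-plane projections, so small non-orthogonality from
  asymmetric segmentations is harmless.
* **Angle**: both the local y-axis and the global reference axis (default
  (0, 1, 0), configurable) are projected onto the transverse plane; the
  unsigned angle in [0°, 180°] is computed via atan2(‖p_g × p_l‖, p_g·p_l)
  (well-conditioned near 0°, where arccos is not). A signed variant takes
  its sign from (p_g × p_l)·n̂, i.e. right-handed rotation about the
  endplate axis. The unsigned angle is the headline output.
* **Degeneracy**: axis lengths or projections below 1e-6 × cloud diameter
  raise a `DegenerateGeometryError` instead of returning junk.

The full measurement returns an audit record: both centers, plane, frame
axes, point counts, and both angle variants.

## Agreement statistics

Two-way ANOVA without replication on the S×R table (rows = subjects,
columns = raters) gives MSR, MSC, MSE. The absolute-agreement ICC defaults
to the **single-measures** form ICC(A,1); the average-measures form
ICC(A,k) is selectable. The packaged reference table's published
coefficients are reproduced (to 3 decimals) by the single-measures form
applied to the 10×2 column pairs — not by the average-measures form — so
`single` is the default despite the average-measures formula being the one
usually quoted alongside such tables; both are exposed. Confidence
intervals use the McGraw–Wong F-based construction (cross-checked against
`pingouin` in the tests). Bland–Altman limits of agreement are
mean ± 1.96·SD of the paired differences.

Two of the published mean differences for the reference table
(Observer1−Observer2, and the sign of Observer1−Observer3) are not
consistent with the table's own columns; the package reports what the
columns give.

## Phantom generator

The phantom emulates a single reconstructed vertebra surface:

| parameter | default | meaning |
|---|---|---|
| body_radius_x / _y | 22 / 16 mm | elliptical body semi-axes |
| body_height | 28 mm | endplate separation |
| endplate_thickness | 2 mm | rim band labelled as endplate |
| pedicle_lateral / _posterior | ±15 / −20 mm | pedicle centers |
| pedicle_radius | 4 mm | pedicle blob size |
| n_body / n_endplate / n_pedicle | 2400 / 700 / 400 | points per region |
| density_skew | 2.0 | arch/pedicle densification factor |
| noise_sd | 0 mm | isotropic Gaussian surface noise |
| theta_deg / tilt_deg | 0 / 0 ° | applied axial rotation / tilt |

Geometry defaults approximate a mid-thoracic/lumbar vertebral body; the
density skew reproduces the arch-denser-than-body pattern of real
reconstructions that motivates entropy-weighted sampling. Surfaces (not
volumes) are sampled, mimicking surface meshes.

Every structure is generated mirror-symmetrically (caps and rims across
the sagittal plane, right pedicle as the mirror of the left, lower cap as
the z-mirror of the upper), so the exact group means of the generated
structure points satisfy the frame construction identically and a
noiseless phantom's measured angle equals the applied axial rotation to
machine precision — the generator inverts the measurement, and its
recorded `theta_true` is computed *through* the landmark construction
(equal to the applied angle when tilt = 0). Noise is added after
labelling, so labels stay exact.

What the phantom does **not** model: cortical/trabecular texture, the
posterior arch between the pedicles, spinous/transverse processes,
endplate concavity, pathology (wedging, fusion), and segmentation-induced
holes. Passing tests therefore demonstrate correctness of the algorithms
under clean, well-separated anatomy — not clinical performance on real
scans, which depends on segmentation quality for structures the phantom
idealises.

## Problem sizes used in the checks

The reduced training sanity check uses 512-point clouds (FPS-resampled
from ~5400-point phantoms), network widths 32/64/128/256, 20 training and
10 held-out phantoms with axial angles uniform in [0°, 25°], 30 epochs,
batch 4, lr 0.003. This configuration reaches held-out endplate mIoU ≈ 98%
(floor asserted: 80%) in well under a minute on one CPU. Angle-recovery
checks use 50 phantoms per condition. These sizes are the package's
standard desk-scale configuration; the full-size network (3072 points,
widths 64/128/256/512, 200 epochs) uses the same code path.

## Known limitations

* The network is CPU-bound NumPy; full-scale training (3072 points, 200
  epochs, large datasets) is feasible but slow compared to a GPU
  implementation.
* Attention is restricted to k-NN patches; very coarse bottleneck stages
  (≤ k points) degenerate to global attention over the stage.
* The angle is undefined (and raises) when the vertebra's y-axis is
  parallel to the endplate axis or when either projection onto the
  transverse plane vanishes — configurations far outside anatomical range.
* k-means endplate splitting assumes the two caps are the dominant
  separation in the predicted endplate cloud; a grossly incomplete
  segmentation (one cap missing) will split a single cap instead and
  produce a wrong axis. The measurement record's point counts and centers
  allow such cases to be audited.
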
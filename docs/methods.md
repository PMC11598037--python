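# Methods

## Scope and model

phenonet estimates five phenotypic traits (fresh weight fw, dry weight dw,
height h, canopy diameter d, leaf area la) of a single lettuce plant per
top-down RGB-D frame, alongside detection and instance segmentation into
four varieties.  The model is a two-stream, two-stage detector: dual
RepVGG backbones (RGB and depth), per-stage cross-modal feature
rectification (FRM), per-stage squeeze-and-excitation fusion (SEF), a
feature pyramid with transposed-convolution upsampling, and Mask
R-CNN-style heads plus a residual trait head.  All neural components run
on a small numpy autodiff engine written for this package (`phenonet.nn`);
its operator set (broadcasted arithmetic, conv2d with stride/padding/
groups, transposed conv, ROI align with bilinear sampling, batch/group
norm, SiLU/sigmoid/softplus, Adam) is exactly what the model needs, and
every operator's gradient is finite-difference-tested.

Key wiring invariant: after each backbone stage the FRM-corrected feature
pair is simultaneously (a) the input to the next backbone stage of each
stream and (b) the input to that stage's SEF.  A traced forward asserts
this in the tests.

### Equations implemented

- FRM channel path: concat the C-channel pair → 2C; GAP and GMP → two 2C
  vectors; concat → 4C; FC 4C→C, SiLU, FC C→2C, sigmoid, split.  Spatial
  path: concat → 2C; 1×1 conv to C/2, SiLU, 1×1 conv to 2, sigmoid,
  split.  Rectification adds the *other* modality's feature scaled by the
  other modality's weights, with factor 0.5 on both the channel and the
  spatial term.  This cross assignment is implemented exactly as printed
  in the source equations even though the module it derives from differs
  in that detail.
- SEF: per-modality SE weights (GAP → FC C→C/4 → SiLU → FC → sigmoid),
  cross-multiplied: `W_mid = F_rgb⊙W_d + F_d⊙W_rgb`; output
  `SiLU(BN(Conv1×1(SCConv(W_mid)))) + BN(W_mid)` with independent BNs.
- SCConv is treated as a pluggable operator following its published
  outline: an SRU that gates group-normalised activations by the
  normalised GN scale (hard threshold 0.5, halves cross-reconstructed)
  and a CRU that splits channels 1/2, transforms one part by group-wise
  3×3 + pointwise 1×1 and the other by pointwise 1×1 + identity, fused by
  softmax attention over pooled branch statistics.  Thresholds and split
  ratio are configurable; exact fidelity to the original operator's
  internals is out of scope.
- RepVGG: train form act(BN(conv3×3) + BN(conv1×1) + BN(identity)); the
  deploy form folds each BN into its branch kernel (1×1 zero-padded into
  the 3×3 centre, identity as a Dirac kernel) and sums.  Equivalence is
  asserted to 1e-4 at block and whole-stream level; reparameterisation is
  idempotent.  Activations are SiLU network-wide, matching the activation
  choice in the fusion modules.

## Depth completion

Classical and training-free.  Depth is in meters with 100.0 as the
working maximum; 0 marks missing pixels; valid input is clamped to
[1e-3, 100−1e-3] so a saturated reading cannot collide with the missing
sentinel.  The pipeline inverts (v → 100−v), fill-dilates with a 5×5
diamond kernel, bridges residual small holes by a grey-closing applied
fill-only, fill-dilates with a 7×7 kernel, extends the topmost valid
value to the frame top per column, iterates a 17×17 fill-dilation until
dense, median-blurs (5), Gaussian-blurs (5-tap, σ = 1.1 via the common
0.3·((k−1)/2−1)+0.8 rule), and inverts back.  Only the 5×5 diamond is
prescribed by the method; the other sizes are conventional
fast-completion defaults, all exposed in `CompletionOptions`.

Guarantees (tested): any input with ≥1 valid pixel completes to full
density; with blurs off, every originally valid pixel is preserved
exactly (all morphological steps are fill-only — a full grey closing
would corrupt border pixels, so closing fills but never overwrites);
fills are foreground-biased (nearest-depth) because they take the
inverted-space maximum; completion is idempotent on dense input with
blurs off.

## Synthetic data

The generator emulates the structure of the greenhouse benchmark: one
centred rosette per frame, four variety labels, RGB + depth pairs, VIA
2.x polygon annotations, a trait CSV.  A plant is a union of elliptical
leaf polygons around a core disc (shapely), rasterised with a
centre-in-polygon rule so polygon and mask are exactly consistent; leaf
colour follows a radial gradient with a per-variety tint (giving the
classifier a learnable signal); depth is camera height minus a spherical
dome profile.  Corruption adds Bernoulli speckle at `hole_fraction` plus
missing pixels in a band around the leaf boundary — the two failure modes
of consumer structured-light sensors.  Traits are computed from rendered
geometry: la = mask area / px_per_cm²; d = max caliper extent of the mask
(exhaustive over convex-hull vertices); h = 100·dome_height;
fw = 0.05·(la·h)^0.8 with lognormal noise (σ = 0.05); dw = r·fw with
r ~ N(0.05, 0.005) clipped to [0.03, 0.07].  The allometry is
synthetic-only plumbing that ties the regression target to visible
geometry; it does not model real lettuce growth, so passing tests show
the pipeline can learn geometry-linked traits, not that it reproduces
field accuracy.  `generate_dataset` draws per-sample radius, leaf count
and dome height around the base config (otherwise height would be a
constant and R² undefined) and cycles the four varieties.

Defaults mirror the acquisition rig: 1920×1080, camera 0.9 m above the
crop, ≈16 px/cm on the ground plane, 12 leaves, 26 cm canopy radius.
Tests run the same generator at 96–160 px scale.

## Data handling

Centre crop 1024² then resize to 800² (bilinear RGB, nearest depth;
vertices map by v′ = (v−offset)·800/1024).  Augmentation is exactly 4×:
original, horizontal flip, vertical flip, +10 % multiplicative brightness
(RGB only, clamped; depth is a distance, not a radiance).  5-fold
cross-validation partitions *base* image ids; every augmented variant
inherits its base image's fold role, so no augmented copy of a test image
can leak into training; 10 % of each fold's training portion is held out
for validation (100 ids → 20 test / 8 val / 72 train per fold).

## Training

Four sessions with Adam, initial lr 0.0012, divided by ten per session,
batch 6, 140 epochs split 80/20/20/20 by default (the split across
sessions is not dictated by the method and is configurable).  Session
freeze masks: (1) everything; (2) backbone streams only; (3) RPN +
box/mask/trait heads only; (4) backbone stages 1–2 plus their FRM/SEF.
The optimiser is re-initialised at each session boundary.  Losses: RPN
objectness as class-balanced BCE over all non-ignored anchors (dense
supervision calibrates the proposal ranking far better than random
sampling at small dataset sizes), smooth-L1 RPN box deltas, ROI softmax
cross-entropy (foreground at IoU ≥ 0.45 — proposals hover near 0.5 IoU
early on and the box head must learn refinement on realistic
candidates), smooth-L1 class-agnostic box refinement, per-pixel mask BCE
at 28², and smooth-L1 trait regression on z-scores; all weights 1.0.
Trait z-statistics are fitted on the training split only.  ROI training
batches are proposals + GT boxes + jittered GT copies at four noise
levels (5–20 % of box size) so refinement generalises beyond
near-perfect boxes.

BatchNorm uses batch statistics at inference as well (free-running BN):
every stage trains on single-image batches (backbone) or the image's ROI
batch (heads), and with such batch shapes the running averages are a poor
normaliser — switching to them collapses detection quality.  Running
stats are still tracked and are what reparameterisation folds.

## Inference

Proposals (top-256 by objectness, NMS 0.7, keep 16) are delta-refined
once, snapped to the bounding box of their predicted mask (the mask head
is trained across jittered boxes and localises the outline more reliably
than delta regression), and re-scored by the classifier on the snapped
box.  The final score is class confidence × (0.5 + 0.5·objectness):
objectness breaks ties between saturated class scores without sinking a
weak-objectness true positive below sensible thresholds.  The trait head
is evaluated on the kept boxes plus jittered copies so its BN batch
resembles the training ROI batches, and its z-space output is
de-normalised with the train-split statistics (dw clamped to ≤ fw).
Scenes in this application contain one plant, so evaluation defaults to
the top-1 detection per image (AR is then recall at 1).

## Evaluation metrics

R² = 1 − SSres/SStot (error on constant truth); MAPE reported as a
fraction, matching the benchmark tables (error on zero truth); NRMSE =
RMSE/(max−min) (scale-invariant; error on constant truth); F1 =
2PR/(P+R), defined 0 with a warning when P = R = 0.  COCO protocol:
greedy score-ordered matching per category and IoU threshold
(0.50:0.05:0.95), 101-point interpolated AP, AR as mean recall at the
detection cap; cross-checked against an exhaustive re-walk on toy
scenes.  Fold aggregation reports the arithmetic mean and the sample
(n−1) standard deviation rounded to 4 decimals — the n−1 convention is
what reproduces the published tables' std rows (population std does
not).  Of the 50 published mean/std cells, 49 reproduce exactly; the
detection AP50 std cell prints 0.0044 while its fold column (identical
to segmentation's, printed 0.0045) aggregates to 0.0045 — treated as an
erratum in the source tables.

## Reduced-scale problem sizes

The test suite and acceptance script exercise the full pipeline at desk
scale, chosen as the package's own default test conditions: 96² images,
backbone widths 8/16/32/64 (one block per stage), 32-channel FPN, square
anchors at scales 6/8/10 per level (rosette plants are round — skewed
anchor ratios rarely exceed 0.5 IoU with a square box), 8 training
images, 200 full-batch Adam iterations at lr 0.002.  Under these
conditions the model reaches train-set mask AP50 ≥ 0.9 and mean trait
R² ≥ 0.9 (the learnability bar is the mean over the five traits).  The
5-fold cross-validation smoke test runs 10 images at 64² with one step
per session.

## Known limitations

- The synthetic world has one centred plant per frame, no occlusion, no
  illumination variation and an invented trait allometry; results on it
  say nothing quantitative about greenhouse data.
- The detector's candidate set is small (16 proposals) and the mask-snap
  assumes a single compact object; multi-plant scenes would need the
  plain NMS path with larger budgets.
- The residual trait head's topology is constrained by parameter parity
  with the 8-conv baseline (verified programmatically), not by a published
  blueprint.
- Checkpoints store raw named arrays (npz) with a train/deploy flag; no
  cross-version migration is attempted.
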
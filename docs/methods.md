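# Methods

This package implements a complete dynamic-counting pipeline for livestock
passing under a fixed overhead camera: single-shot head detection (SH-SSD),
tracking-by-detection (DeepSort-style), and line-crossing counting (the
Streak rule), plus a synthetic corridor-scene generator that makes every
stage testable without farm footage.

## Detector architecture

SH-SSD is an SSD-lineage single-shot detector with three parts.

**Backbone.** A stride-2 CBR stem (conv + batch norm + ReLU6) followed by
six TAneck modules — MobileNetV3-style inverted bottlenecks in which the
squeeze-excitation gate is replaced by a Triple Attention (TA) block.  Three
taps after rows 2, 4 and 6 produce `output1/2/3` at strides 8/16/32.

The TA block pools the input along the channel, height and width axes
respectively (max and mean, giving 2 maps per branch), compresses each pair
with a bias-free 7x7 convolution, batch norm and sigmoid, gates the input
with the resulting mask, and averages the three gated tensors.  Each branch
costs 98 conv weights + 2 BN scalars, so a TA block adds exactly 300
trainable parameters regardless of width.  The attention convolutions pad
by edge replication so a constant input produces an exactly uniform 0.5
gate (zero-padding would break this at the borders).

**Neck.** Three *independent* feature branches (no cross-scale fusion):
Branch1 (stride 8) is DW-CBR x2, SPP, CBR x2 and five TAnecks; Branch2
(stride 16) the same with four TAnecks; Branch3 (stride 32) drops the SPP.
SPP concatenates the input with stride-1 max-pooled copies at kernels
5/9/13 (4x channels); the following 1x1 CBR reduces back to the shared
width.  Branch independence is a tested invariant: perturbing one backbone
output leaves the other branches' outputs bit-identical.

**Head.** One decoupled head (DCHead) per branch: a shared 1x1 CBR stem,
then disjoint classification and regression stacks of (DW-CBR -> CBR) x 2
ending in 1x1 prediction convolutions.  Anchors are square, three per cell,
sizes `{32, 64, 128} x {1, 2^(1/3), 2^(2/3)}` on strides 8/16/32.  Box
coding is the SSD convention without variance scaling.  Inference applies a
sigmoid score threshold and greedy class-wise NMS (IoU 0.5; ties broken by
lower index for determinism).

### Channel widths and the parameter audit

The published architecture fixes the module sequence and three trainable
parameter totals — TA backbone 2.97 M, plain-SE backbone 2.98 M, full
detector 6.44 M — but not the per-layer channel widths.  The widths in
`shssd/config.py` follow the MobileNetV3-Large doubling ladder
(stem 24; expansions 112..1992; outputs 56..432; neck width 176 with
branch expansions 368/360/360) and were fixed once so that all three
totals land on the published values; `shssd.model.parameter_audit()`
recomputes them from the live network.  The SE variant used for the
2.98 M comparison applies a SENet-style gate (reduction 16, hidden width
a multiple of 8) on the block output of the same two rows that carry TA;
with squeeze-excitation on the expanded channels the printed 0.01 M gap
between the two backbones would be impossible, so the output-side form is
the one consistent with the published totals.

## Label assignment and loss

Training uses dynamic sample matching: label assignment adapts to the
current predictions instead of fixed IoU rules.  The implemented rule is
the SimOTA formulation: candidate anchors have their center inside a
ground-truth box or within 2.5 cells of its center; the cost of pairing
anchor m with ground truth g is `-log p_m + 3 * (-log IoU(pred_m, g))`;
each ground truth takes its k cheapest candidates with
`k = clamp(floor(sum of its top-10 candidate IoUs), 1, 10)`; an anchor
claimed twice goes to the cheaper ground truth, and any ground truth left
empty reclaims its cheapest candidate.  Unassigned anchors whose own box
overlaps a ground truth at IoU >= 0.4 are *ignored* rather than treated
as background: without this band, hard-negative mining keeps selecting
the anchors adjacent to each positive — which share its features — and
the classifier settles into a uniform-score equilibrium instead of
separating (observed directly during development: positive scores
plateaued near the mining ratio).  The loss is hard-negative-mined binary
cross-entropy (negatives at 3:1 against positives) plus smooth-L1 on
encoded offsets, both normalized by the positive count.  The
classification bias initializes to a 0.01 foreground prior so early
optimization is not dominated by the several thousand background anchors.

The full-scale schedule (Adam, lr 5e-4, x0.1 decay every 100 epochs,
batch 32, 300 epochs) is implemented but exercised only at toy scale: the
training-sanity check overfits the full 6.44 M-parameter detector on 20
synthetic 320x320 images for at most 300 Adam steps (lr 6e-3 with x0.1
step decays at 60% and 85% of the run, batch 2) and requires train-set
AP0.5 >= 90; in practice it early-stops above that bar around step 125.
These sizes keep one optimizer step around 3 s on a single CPU core with
the numpy backend.  Train-set AP is evaluated at score threshold 0.05
after re-estimating batch-norm running statistics under the current
weights (they lag at batch size 2).

## Numerical backend

All network layers (convolution with grouped/depthwise paths, batch norm,
ReLU6, sigmoid, max pooling, the attention blocks) are implemented on
numpy with explicit forward/backward pairs and an Adam optimizer;
pointwise and general convolutions lower onto BLAS matmuls (1x1 as a pure
matmul, k > 1 via im2col), while the depthwise convolutions — memory-
bound, no BLAS mapping — use numba-jitted kernels with a pure-numpy
fallback.  Every layer's backward
pass is verified against central finite differences in the unit suite;
composite blocks are checked at a looser tolerance because ReLU6/BN kinks
dominate the finite-difference error there.  Batch norm uses eps 1e-5 and
momentum 0.1; weights are He-normal; all randomness flows through seeded
`numpy.random.Generator` handles, making training and inference bit-
reproducible per seed.

## Tracking

A constant-velocity Kalman filter runs on (cx, cy, aspect, height) with
DeepSort's height-scaled noise (position std h/20, velocity std h/160).
Confirmed tracks are matched first, freshest first (matching cascade), on
a cost blending the chi-square-gated Mahalanobis distance (99% quantile,
4 dof) with an appearance distance at weight 0.2, solved by the Hungarian
algorithm; leftovers fall back to IoU matching at threshold 0.3.  Track
lifecycle: confirmed after 3 consecutive hits, deleted after 30 missed
frames; ids are never reused.

One deliberate extension over the vanilla algorithm: **duplicate-track
suppression**.  When detection noise briefly splits one target into two
confirmed tracks, the pair alternates in stealing the target's single
detection — each stays inside `max_age`, and the stale one eventually
re-crosses the counting line for a double count.  A confirmed track that
coasts three consecutive frames while overlapping a freshly updated
confirmed track at IoU > 0.45 is therefore retired.  Appearance cannot
break this cycle (both tracks hold the same animal), and genuinely
distinct overlapping animals are unaffected in practice because their own
detections keep both tracks fresh.  The original appearance term is a trained
re-identification CNN; the default embedding here is an 8x8x8 RGB
histogram of the box crop under cosine distance — deterministic,
dependency-free, and discriminative for the color-textured synthetic
heads — with `embed_fn` as the plug-in point for a learned model.
Without frames the tracker runs motion-only.

## Counting

The head-box center is the positional reference.  Each track's signed side
of the counting line is tracked frame to frame; a strict negative-to-
positive flip (downward, for a left-to-right horizontal line) increments
the tally once per track id.  A center exactly on the line keeps its
previous side, so boundary jitter cannot double-count; tracks first seen
beyond the line are not counted.  The total is monotone non-decreasing.
A lost-and-recovered animal receives a new id and would be recounted if it
crossed again — inherent to id-based counting and worth knowing when
reading the robustness numbers.

## Synthetic scenes

The generator emulates the acquisition setting: a fixed overhead camera on
a 2 m corridor passed by up to four animals abreast.  Heads are filled
ellipses (major axis 36-64 px in a 640x640 frame) with a per-track hue and
speckle texture, entering above the frame on staggered frames and moving
downward at 3-6 px/frame with sinusoidal lateral drift; lanes may overlap
(occlusion probability 0.2, z-order fixed by track id).  Ground truth
records a head only once at least 50% of its box is visible, matching
annotation practice for heavily truncated objects and keeping the
aspect-height Kalman state well-posed during frame entry.  Per-track
crossing flags are derived from the center trajectory against the line at
half frame height.  Detector noise is modeled as independent misses
(per-box), uniform false positives (per-frame), and Gaussian corner
jitter, all seeded.

What the synthetic scenes do *not* model: photorealistic appearance, body
occlusion of heads, motion blur, lighting changes, or correlated detector
failures.  Passing the counting checks therefore demonstrates the
correctness of the tracking/counting machinery under the stated noise
model, not field performance on real farms.

## Evaluation

P = TP/(TP+FP) x 100 and R = TP/(TP+FN) x 100 with greedy score-ranked
one-to-one matching; precision at zero detections is defined as 0.  AP is
the area under the interpolated PR curve: on explicit PR points the
interpolated curve is integrated exactly; the dataset evaluator samples it
on the 101-point recall grid (COCO convention) and averages IoU thresholds
0.50:0.05:0.95.  The two integrators agree within the grid quantization
(< 0.25 of a percentage point), and the exact one is the oracle-tested
path.  Small-target AP restricts ground truths to area < 32x32 px before
evaluation.  An FPS utility (M images / S seconds) is provided for
completeness; throughput is hardware-dependent and not part of any check.

## Known limitations

- Parameter totals pin the architecture only up to the published rounding;
  the width table is a consistent reconstruction, not a transcription.
- The numpy backend targets correctness and CPU-scale experiments, not
  GPU training throughput.
- Counting accuracy under noise is measured on the synthetic noise model;
  real-world severe occlusion (the published failure mode) is only
  approximated by overlapping lanes.
- Video ingestion is an image-sequence/MOT-CSV contract; camera streams
  are out of scope.
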
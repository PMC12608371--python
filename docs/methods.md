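# Methods

This note documents the models, rules and numerical choices behind
`embryostage`, including the places where the design was genuinely open
and what the synthetic-data tests do and do not demonstrate.

## Acquisition model

Frames are single-channel 256 × 256 images on a fixed grid: time zero at
the first cleavage, acquisition from 150 min onward at 5-min intervals
(`TimeGrid(150, 5)`, both configurable).  All durations are therefore
multiples of the frame interval; the decoder never interpolates within
a frame.

## Segmentation network

A U-Net whose encoder and decoder stages are pairs of residual blocks.
Each block is conv3×3 → BN → ReLU → conv3×3 → BN (→ dropout) plus an
additive shortcut, with a final ReLU; the shortcut is the identity when
channel counts match and a 1×1 convolution + BN otherwise.  Dropout
(rate 0.2 by default) sits after each block's second convolution —
the published description fixes only the rate, not the placement.
Downsampling is 2×2 max pooling, upsampling 2×2 transposed convolution;
encoder features are concatenated into the matching decoder stage.
Widths double per level from `base_features` (default 64, the classical
U-Net convention; the first-stage width is not printed anywhere, so the
convention stands in).  Inputs must be divisible by `2**depth`.

Training: Adam, learning rate 0.002, batch 20, 80 epochs, seeded 80:20
train/validation split, no augmentation.  The loss is the fused
sigmoid + binary cross-entropy on logits, computed as
`max(x,0) − x·y + log(1+exp(−|x|))`, finite for any finite logits.
Masks are obtained by thresholding logits at 0, i.e. σ(x) at 0.5, with
the boundary mapping to 1 (`x ≥ 0 ⇒ ŷ = 1`).  Model selection keeps the
epoch with the highest validation IoU.  Two IoU conventions needed
fixing: the empty∩empty case is defined as 1.0 (both masks agree there
is no embryo), and training-curve IoU is micro-averaged over the
epoch's concatenated pixels (macro vs micro is unspecified; micro is
stabler for near-empty masks).

## Stage classifier

The standard 18-layer residual plan — 7×7/2 stem, 3×3/2 max pool, four
groups of two basic blocks at widths (w, 2w, 4w, 8w), global average
pooling, linear head — adapted to one input channel (the frames are
grayscale; no channel triplication) and six outputs, always trained
from scratch.  `base_width` w defaults to 64 (feature length 512); the
desk-scale experiments use w = 8 at 64 px input.

Training: cross-entropy, Adam at 0.001 (the published protocol does not
print the classifier learning rate; 0.001 is the Adam convention),
halved every 10 epochs, 80 epochs, seeded stratified 70:30 split for
the holdout protocol and 80:20 per fold for five-fold cross-validation
(both protocols appear in the source descriptions and both are
implemented).  Weight decay and augmentation are unspecified upstream;
this package uses decoupled weight decay 1e−4 on weight tensors and
random horizontal/vertical flips during classifier training only —
embryo orientation is unconstrained at acquisition, so mirrored views
are valid members of each stage.  The segmenter uses no augmentation.
Validation precision/recall/F1 are macro-averaged (classes are balanced
by construction, so micro ≈ macro; macro is reported).

Grad-CAM targets the last convolutional block.  Because the network
ends in global average pooling followed by one linear layer, the
gradient of a class score with respect to those feature maps is
spatially constant and equals the head-weight row over the map area, so
the heat map is computed in closed form as `ReLU(Σ_k W[c,k] A_k)`,
min-max normalised and bilinearly upsampled.  Note the map is coarse:
its native resolution is the last feature-map grid (8 × 8 at 256 px
input), so localisation claims are only meaningful at that granularity.
UMAP embeds the average-pool features with the Euclidean metric and a
fixed `random_state`.

## Timeline decoding rules

The stage call is the argmax of the softmax probabilities; ties break
toward the earlier stage (development is monotone, and the earlier
stage is the conservative claim).  The call rule itself is a design
decision — probability traces, not calls, are what the upstream
description plots.

**Misclassifications.**  A frame whose call interrupts a continuous
single-stage run is a misclassification: *isolated* when a single frame
is flanked on both sides by one common different stage (corrected to
that stage), *consecutive* when a run of ≥ 2 identical wrong calls is
so flanked (never auto-corrected; the interrupted stage is excluded
from that embryo's comparative statistics).  First and last frames have
no two-sided context and are never flagged.  An uncorrected mode keeps
the flags and tallies but computes durations from the raw calls, for
sensitivity analysis.

**Transitions.**  At each boundary between a stage s and its successor
s′, two patterns are recognised.  *Oscillation*: the maximal stretch of
frames around the boundary whose original argmax alternates strictly
between s and s′; it must contain a reversal (an s after an s′),
otherwise a plain one-step switch would qualify.  *Mixed*: contiguous
frames at the boundary where no stage reaches θ = 0.6 and the top two
stages are exactly {s, s′}; θ derives from the observed 40–60 %
mixed-probability pattern and is configurable.  A jump to a
non-successor stage is tagged anomalous and claims no frames.
Oscillation frames look, frame by frame, exactly like strings of
isolated misclassifications, so transition detection runs on the
original calls and *revokes* any misclassification flags inside a
recognised window; when a flagged run straddles a window edge its
remainder keeps its flag but stays uncorrected, which leaves durations
intact.  Correction is idempotent on series whose misclassifications
are mutually separated (the synthetic generator enforces ≥ 2 clean
frames of margin); adjacent alternating errors are inherently ambiguous
with oscillation transitions and are resolved in the transition
detector's favour.

**Durations.**  A stage's duration is the frame interval times its
non-transition frame count (corrected stage where set); each boundary's
transition span is counted separately, so no frame is double-counted,
and the conservation identity Σ stage spans + Σ transition spans =
interval × frame count is asserted on every table.  Whether published
stage durations include their transition frames is not stated upstream;
exclusion is this package's convention, applied uniformly to all
groups, so group *comparisons* are unaffected by the choice.

## Group statistics

Per stage: mean ± SEM (sample SD over √n), two-tailed Student's t-test
with pooled variance (a Welch option exists but is off by default — the
upstream analyses say only "unpaired Student's t-test"), percent delay
from the group means, and stars at strict thresholds 0.05/0.01/0.001/
0.0001.  No multiple-testing correction is applied, matching the
raw stage-wise reporting convention.  Embryos whose table excludes a
stage (consecutive misclassification) are dropped from that stage's
sample only.  Degenerate inputs are handled explicitly: zero pooled
variance yields p = 1 (equal means) or p = 0 with infinite t (unequal);
groups with n < 2 are marked not-testable rather than erroring.

## Synthetic data

The generator emulates the *structure* of the study data, not its
optics.  Images: an elliptical eggshell (bright rim, dim interior) with
one deterministic motif per stage — granular texture, dorsal stripes, a
ventral arc, a curled comma, two parallel tube segments, three tube
segments across the short axis — plus up to one of four background
noise categories (neighbouring embryo, defocus blur, bubbles, debris)
and seeded pose jitter (centre, axes, rotation within ±25°; real
mounting is roughly but not perfectly consistent, and full 0–180°
orientations are not part of the emulated conditions).  Noise
categories attach to segmentation datasets, where noise robustness is
the claim being exercised; classifier datasets are clean
background-zeroed extractions, matching the pipeline's operating point.
Probability series: stable frames put κ = 0.95 on the true stage; mixed
transitions split 98 % of the mass across the boundary pair with the
argmax handed over monotonically; oscillation transitions alternate a
high-confidence argmax (even length ≥ 4, ending on the later stage, the
shortest shape containing a reversal that hands over cleanly); injected
errors replace a stable frame's argmax with a wrong high-confidence
stage, with ≥ 2 clean frames of margin to segment ends and other
injections.  Every row is mixed with a symmetric Dirichlet draw
(weight 0.02) and renormalised, giving non-degenerate softmax rows
whose argmax and mixed/stable character are preserved by construction.
Everything is byte-reproducible from (spec, seed).

What passing tests show: that the architectures train, that the decoder
inverts the generator exactly, that the statistics are calibrated, and
that the pipeline composes end to end.  What they do not show: DIC
contrast realism, muscle-twitching dynamics, real inter-embryo
variability, or the published real-data accuracies — those require the
original archive and are out of scope here.

## Desk-scale experiment sizes

The test suite and the acceptance script train reduced models sized for
a single CPU: the segmenter on 60 synthetic 64 px images (depth 2,
width 8, 10 epochs, batch 20) reaching held-out IoU ≥ 0.90 across
seeds, and the classifier on 60 images per stage at 64 px (width 8,
40 epochs, batch 20) reaching held-out accuracy ≥ 0.90 across seeds,
with a five-fold CV at the same size.  The statistical power check
simulates per-embryo durations as 5-min-rounded normals at the scale of
the first comparative stage (mean 53.75 min, SD 7.4 min ≙ SEM 1.85 at
n = 16) with a +50 % treated mean at n = 10; at that scale the
noncentral-t power at p < 0.01 exceeds 0.999, and the type-I rate of
the same pipeline is checked against its nominal 5 %.

## Known limitations

- Frames are classified independently; no temporal smoothing or HMM
  decoding of the probability series (deliberately out of scope).
- The transition-delimitation rules (θ = 0.6, reversal requirement) are
  this package's formalisation of informally described patterns; other
  reasonable delimitations would shift stage/transition frame
  attribution by about one frame at boundaries.
- Grad-CAM's closed form is exact only for GAP + linear heads, which is
  the architecture used here.
- The NumPy engine is single-threaded apart from BLAS matmuls; it is
  sized for desk-scale experiments, not for 256 px training at the full
  published protocol.
- No embryo-orientation (angle) correction is applied to durations.
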
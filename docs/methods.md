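# Methods

## Problem and model

`echoseg` segments the left ventricle (LV) in apical four-chamber
echocardiogram frames and derives the ejection fraction
EF = (EDV − ESV)/EDV from the per-frame masks.  The network is a nested
UNet (UNet++) grid `X^{i,j}` truncated at a prune level L ∈ {1..4}:

* `X^{0,0}` is a VGG-style conv pair (two 3×3 convolutions, each followed
  by batch normalisation and ReLU; convolutions carry no bias because BN
  absorbs it).
* Backbone rows `X^{i,0}` (i ≥ 1) use a *nested* feature-extraction block:
  a 1×1 convolution preserves the incoming information on a skip path,
  the main path max-pools to half resolution, applies a conv pair,
  upsamples with a 2×2/stride-2 transposed convolution, concatenates with
  the skip and applies a second conv pair.  The block therefore sees one
  resolution level deeper than its row.  A plain conv pair can be
  substituted via `nested_encoder: false`.
* Decoder nodes `X^{i,j}` (j ≥ 1) concatenate all same-row predecessors
  with a transposed-conv upsample of `X^{i+1,j-1}` and apply a conv pair
  (standard UNet++ dense connectivity).
* Every node output passes through the fused attention block (below);
  `attention_mode: none` disables it for ablations.
* Deep supervision: a 1×1 convolution + sigmoid head on every `X^{0,j}`.
  Pruning to level l keeps exactly the nodes feeding head l and shares
  parameter and BN-buffer storage with the parent, so the pruned forward
  equals the parent's level-l output bit for bit in eval mode.

Inputs must be divisible by `2^(L+1)` when nested encoder blocks are on
(the deepest row pools once more); there is no implicit padding.

## Fused attention

Channel attention, then SimAM, then spatial attention:

1. **Channel**: global average- and max-pooled channel descriptors pass
   through one shared two-layer MLP (hidden width C/r, ReLU, biases
   included in both layers); the sigmoid of the summed outputs rescales
   channels.  Default r = 8 in the shipped configurations.
2. **SimAM** (parameter-free): each activation is rescaled by
   `σ(d_i/(4(v+λ)) + 0.5)` with `d_i = (x_i − μ)²` per position, μ the
   channel mean and `v = Σ d_i/(HW−1)` the channel variance over spatial
   positions.  `d` is per-element; a scalar (summed) reading would make
   the weight spatially constant and the attention vacuous.  λ defaults
   to 1e-4; HW = 1 is treated as the zero-variance case (v = 0).
3. **Spatial**: channel-wise mean and max maps are concatenated and
   convolved (odd kernel k, zero padding, default k = 7) to one sigmoid
   map that rescales all channels identically.

A note on symmetry: the channel MLP is a channel-mixing bottleneck, so
channel attention is *not* equivariant to input-channel permutation on its
own; the symmetry that does hold (and is tested) permutes the MLP weights
consistently with the channels.

## Loss and metrics

Training loss: `α · DiceLoss + (1−α) · BCE`, α = 0.8, on raw sigmoid
probabilities (soft Dice); with deep supervision the per-head losses are
averaged uniformly and only the pruned head is used at test time.
Probabilities are clipped to [1e-6, 1−1e-6] before logarithms, which keeps
every gradient finite.  Metrics binarise at 0.5 (hard Dice/IoU) with a
1e-6 smoothing epsilon in numerator and denominator, so two empty masks
score 1.  Reported set-level metrics are macro averages over frames;
confidence intervals are percentile bootstrap (frames resampled, 1000
replicates by default, seeded).  Note the algebraic identity
IoU = DSC/(2−DSC) for any binary pair, used as a cross-check in tests.

## Numerical stack

No deep-learning framework is part of the dependency set; `echoseg.nn` is
a compact reverse-mode autodiff engine over float32 numpy arrays.
Convolutions are lowered to BLAS matrix products via im2col/col2im
(stride 1, 'same' zero padding); the 2×2/stride-2 transposed convolution
exploits that kernel = stride partitions output pixels; max-pooling
scatters gradients to per-window argmaxes (earliest index on ties).
Batch normalisation is composed from differentiable primitives (batch
statistics in train mode, running estimates — momentum 0.1, unbiased
variance — in eval mode).  Weight init is He-uniform from an explicit
seeded generator, zero biases; Adam uses standard bias-corrected moments.
Every primitive's gradient is verified against central finite differences
in the test suite.  On one CPU core the engine sustains roughly
tens of GFLOP/s, which makes the desk-scale experiments below practical.

## Parameter and FLOP accounting

Pinned convention: one multiply-accumulate of a convolution, transposed
convolution or linear layer counts as 2 FLOPs (bias adds counted once per
output element); batch-norm costs 2 FLOPs per output element; pooling,
activations, attention poolings and elementwise rescalings are not
counted.  Parameter counts sum trainable scalars only (BN running
statistics excluded).

The published totals for the reference operating point — 5.96 M
parameters and 25.74 GFLOPs at 112×112, prune level L3 — do not come with
printed channel widths.  `scripts/match_reference.py` enumerates width
families (multiples of 8, monotone, together with the nested mid-width
factor and reduction ratio) under the analytic counters, cross-checks
candidates against the real builder, and freezes the closest family:
widths (80, 80, 128, 256), r = 8, mid-factor 1, giving 5.9576 M
parameters and 25.724 GFLOPs — both equal to the published values at
their printed precision.

## Synthetic echocardiograms

The generator emulates only what the downstream code consumes: a sector
field of view (apex at top centre, 75° opening), a dark elliptical blood
pool (intensity 0.12) inside a bright myocardial rim (0.85, rim width 30%
of the semi-axes) over mid-grey tissue (0.45), multiplicative Rayleigh
speckle normalised to unit mean (mixing weight 0.5) and a Gaussian blur
(σ = 1 px).  The pool area follows
`area(t) = ES + (ED−ES)(1+cos 2πt/T)/2`, so frame 0 is ED and frame T/2
ES, and both axes scale by √(area ratio) (fixed aspect ratio 1.7).
Defaults: 112×112 frames, 20 frames per cycle, ED pool area 10% of the
frame.  Cohorts draw EF uniformly from (0.45, 0.75) and jitter centre
(±3%), aspect (±12%), tilt (±8°) and ED area (±20%) per sequence, with
70/15/15 train/val/test splits assigned per sequence by exact
largest-remainder counts.

Masks are the noise-free ellipse interiors, and the *pixel area* of the
mask is the volume proxy throughout — a single-plane stand-in, not a
clinical volume (no area–length or Simpson reconstruction).  Ground-truth
EF is therefore exactly the quantity the clinical module computes, which
is what makes the EF round-trip tests meaningful.  What the generator
does **not** model: probe/beamforming physics, anatomical neighbours
(atria, right heart), valve motion, out-of-plane motion, shadowing and
dropout, inter-observer tracing variability.  Passing tests demonstrate
the pipeline's correctness and trainability on high-contrast,
geometrically clean data; they do not certify clinical accuracy on real
echocardiograms.

## Desk-scale experiment sizes

The shipped `desk.yaml` runs the reference recipe (Adam, lr 1e-4,
batch 2, α = 0.8, L3, fused attention, 5 epochs) on a 200-frame cohort
(10 sequences × 20 frames) at 64×64 with widths (24, 48, 96, 192) —
sizes chosen as the smallest configuration that trains to a validation
Dice ≥ 0.9 in a few minutes on one CPU core.  With the packaged seeds the
run reaches validation Dice ≈ 0.94 and held-out EF error ≈ 0.01–0.03.
ED/ES frames are selected as the area argmax/argmin per video (no ECG
gating; ties break to the earliest frame).

## Known limitations

* Pixel-area EF ignores through-plane geometry; absolute EF on real data
  would need a volume model.
* The engine is CPU/float32 only; batch sizes and resolutions are bounded
  by memory copies in im2col.
* Checkpoints store raw arrays keyed by dotted module paths; they are not
  interchangeable with other frameworks.
* BN statistics are shared (by storage) between a parent and its pruned
  sub-models; training a pruned copy mutates the parent's buffers.
  Pruning is intended for inference.
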
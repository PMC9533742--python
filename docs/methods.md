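# Methods

## Problem

Photon-counting area detectors used at SAXS/WAXS beamlines are tiled from
rectangular modules with dead stripes between them.  On a PILATUS3 2M
(3 columns x 8 rows of 487 x 195 modules, 1475 x 1679 pixels, 172 um
pitch) the tiling leaves 7 full-width horizontal gaps 17 px tall and 2
full-height vertical gaps 7 px wide.  The recorded intensity is therefore
missing along a fixed grid of bands, which disrupts downstream automation
(sample-type classification, orientation determination) even though
conventional reduction does not need the missing pixels.  This package
implements and compares ways to fill the gap grid: four trainable
convolutional inpainting networks and a non-learned biharmonic baseline,
together with the data pipeline, the gap-restricted evaluation protocol
and a latent-space analysis of what inpainting buys downstream.

A note on the vertical-gap width: the detector description gives both
"7 pixels wide" and a 1475 x 5 extent for the vertical gaps.  Only 7
makes the module widths integral (3 * 487 + 2 * 7 = 1475), so 7 is the
default; the width is an explicit `DetectorGeometry` parameter.

## Working resolution and pre-processing

Frames are resized to 512 x 512 with bicubic interpolation (negative
overshoot clipped at zero), then mapped to [0, 1] by `v -> log(1 + v)`
followed by a per-frame min-max normalization.  `log1p` rather than a bare
logarithm keeps zero-valued (masked, beamstop) pixels finite; per-frame
rather than global normalization makes every input commensurate with the
networks' output range.  The gap mask is rescaled by scaling each band
rectangle's edges and rounding to the nearest integer with a minimum
extent of 1 px, which preserves the gap topology (at 512 x 512 the 17 px
horizontal bands become 5-6 px, the 7 px vertical bands 2 px).

## Gap-grid augmentation

Horizontal gaps have ground truth (acquired in the real experiment by
translating the detector); vertical gaps never do.  Training data is
therefore built from column strips:

1. each 512 x 512 frame is cropped into seven 512 x 128 strips at offsets
   {0, 64, ..., 384} (64 px overlap);
2. the four strips that intersect a vertical gap (offsets 64, 128, 256,
   320) are discarded;
3. each survivor receives an artificial vertical gap drawn uniformly from
   start columns {-1, 21, 41, 85, 105} (-1 = none) with width 2 - exactly
   the local positions and width the true vertical gaps occupy inside the
   discarded strips - giving an (input, target) pair in which the gap
   pixels have known truth.

This yields 3 pairs per frame (13 923 from a 4641-frame training split).
The candidate list is a reconstruction from the rescaled gap geometry (the
original coordinate list is not legible in the source material); it is
exposed as configuration.  Each strip is augmented once per pass rather
than re-randomized per epoch.  At inference all seven strips are predicted
and recombined by arithmetic averaging of overlapped columns, which is an
exact left inverse of cropping for unmodified strips and suppresses
patch-edge artifacts otherwise.

## Architectures

All four networks map a 1-channel strip to a 1-channel strip, all
convolutions are zero-padded to preserve shape, there are no normalization
layers, and the output is linear (clamped to [0, 1] only at evaluation).

* **Convolutional autoencoder** (depth 2, base 32): conv/ReLU/max-pool
  encoder stages doubling channels, transposed-conv + conv decoder, 1x1
  head; the latent is a spatial feature map, and there are no skip
  connections.
* **TUNet** (tunable U-Net): `depth` resolution levels with channel
  schedule `round(base * growth^level)` (rounding half away from zero, so
  fractional growth rates like 1.5 and 2.5 are stable), two 3x3 conv+ReLU
  per block, 2x2 max-pool down, 2x2 stride-2 up-convolutions, channel
  concatenation skips, 1x1 head.
* **Partial-convolution U-Net** (depth 5, base 32): the same topology with
  every convolution replaced by a mask-renormalized partial convolution.
  The valid-pixel mask rides along: max-pooled in the encoder,
  nearest-upsampled in the decoder, merged with the skip mask by maximum.
  A window with `s > 0` valid cells computes
  `y = (W * (x . m)) * (|W|/s) + b`; a pixel becomes valid once any truly
  valid pixel enters its receptive field, so holes shrink monotonically.
  Out-of-frame padding cells count as valid in the renormalization sum
  (making a fully valid input reproduce the ordinary zero-padded
  convolution exactly, borders included) but not in the mask update.
  This model takes the mask as input - it is not a blind inpainter.
* **MSDNet** (mixed-scale dense network): layer `i` convolves the
  concatenation of the input and all previous layer outputs (width 1) with
  a 3x3 kernel of dilation `((i-1) mod max_dilation) + 1`; the output is a
  1x1 convolution over the input plus all layer channels.  The parameter
  count is `4.5 d^2 + 6.5 d + 2` for `d` layers - 0.012 M at 50 layers,
  0.181 M at 200 - two to three orders of magnitude below the U-Nets.
  The head is initialized as a near-pass-through of the input channel
  (unit weight on the input, small random weights on the layer channels),
  so optimization starts from the identity map and learns gap
  corrections while gradient reaches every layer from the first step.

The U-Net-family internals (convolutions per block, up-conv kernel) are
stated here as this package's choices; parameter counts of the tunable
U-Net therefore depend on those choices and are not treated as reference
values.

## Numerical engine

No deep-learning framework is part of the dependency set; the networks run
on a small reverse-mode autodiff engine over numpy arrays
(`scattergap.nn`).  Convolutions are evaluated per kernel tap as BLAS
matrix products over shifted views, with numba-compiled streaming kernels
taking over when the in-by-out channel product is at most 64 (profiled
crossover on 512 x 128 strips; the MSDNet's many-channels-to-one layers
are copy-bound under BLAS).  Gradients accumulate in the forward dtype, so
float64 finite-difference gradient checks run alongside float32 training.
Weights use He-normal initialization; biases start at zero.

## Training recipe

L1 loss (no adversarial terms or extra regularization), Adam with default
moments, initial learning rate 1e-3 dropping by 10x every `lr_step` epochs
(100 of 300 at full scale; 60 of 180 for the 200-layer MSDNet variant).
The validation split (10%) is taken by parent frame so sibling strips of
one image never straddle the split; the best-validation weights are
retained.  The loss is computed over all pixels of the target strip by
default; a `loss_on_gaps_only` switch restricts the support to gap pixels
(at desk scale this concentrates the training signal on the ~4% of pixels
that are actually scored and converges much faster; compositing removes
non-gap predictions at evaluation time either way).

## Evaluation protocol

Two tracks.  Horizontal gaps: full frames are inpainted by strip-wise
inference plus overlap-averaged stitching, predictions outside the gaps
are replaced by the input pixels, and pooled L1 / Pearson are computed
over horizontal-gap pixels that carry ground truth (the intersections
with vertical gaps do not and are excluded).  Vertical gaps: the
evaluation split undergoes the same augmentation, and the metrics pool
the artificial-gap pixels of each strip.  Pearson on a zero-variance
pooled series is reported as NaN, never silently 0.

## Biharmonic baseline

Masked pixels solve the discrete biharmonic equation (13-point stencil)
clamped to the known surrounding values.  Where the stencil reaches past
the frame border - the vertical gaps span the full frame height - the
out-of-frame value is closed by linear extrapolation from the two nearest
in-frame lines per axis, which keeps constants and affine images exact
solutions everywhere (a widely used reflective closure would not be).
The sparse system is split into decoupled diagonal blocks and each block
is LU-factorized once per mask, so frame stacks sharing the detector mask
solve in milliseconds each.  The solver is direct; no iteration tolerance
is involved.

## Synthetic data

The real beamline library is not public, so the generator emulates its
features at working resolution: a radially decaying diffuse background,
2-6 rings (width 1.5-6 px, optionally azimuthally modulated with order
2/4/6), 0-4 Gaussian peaks (sigma 1.5-4 px), a square beamstop shadow
(half-width 6-14 px) and Gaussian read noise.  Intensities are drawn on a
photon-count scale spanning several decades (backgrounds 50-500, rings up
to 2000, peaks up to 5000 counts) so the log transform matters as it does
for measured data; under these defaults the mean preprocessed intensity
over the gap bands is about 0.25, matching the range reported for the
real testing data.  Stress cases appear with probability 0.15 each: a
peak buried wholly inside a horizontal gap band, three peaks tangent to
the beamstop, and a fourfold-symmetric peak quadruplet.  Scenes are
deterministic given their seed; Gaussian rather than Poisson noise is
used, as the evaluation metrics are insensitive to the choice at these
noise levels.

What the generator does not emulate: photon-counting statistics, detector
flat-field/gain structure, q-space calibration, diffuse scattering from
real materials, and the long-tailed variety of a decade of user data.
Passing desk-scale tests therefore demonstrates that the pipeline,
losses, architectures and protocol are implemented correctly and behave
as reported directionally - not that the trained weights transfer to real
beamline frames.

## Desk-scale benchmark sizes

The seeded end-to-end benchmark uses 200 synthetic frames (60 training,
40 evaluation; the full set feeds the latent analysis), a 12-layer
width-2 max-dilation-6 MSDNet (2642 parameters, batch 2) and a depth-3
base-4 growth-2 TUNet (batch 4) trained for at most 30 epochs with the
gap-restricted loss; the biharmonic baseline is evaluated on the same
split.  Width 2 is the benchmark's "small MSDNet": width-1 networks up
to 16 layers do not reach baseline quality within the 30-epoch budget.  The latent-space analysis embeds the 200 masked / truth /
TUNet-inpainted frames (average-pooled to 128 x 128 before embedding;
the encoder is size-agnostic and the pooling keeps the three spaces
strictly comparable) with identically seeded autoencoders and uses
k = 100 nearest neighbors.  These sizes are the package's benchmark
conditions, chosen so the whole suite runs on a single CPU.

## Degenerate inputs and tie-breaks

Constant frames preprocess to all zeros (min = max convention).  Latent
neighbor ordering breaks distance ties by ascending image id; the self
neighbor is excluded, so rank 1 is the nearest distinct image.  Max-pool
gradient routes to the first maximum in each window.  An all-true gap
mask is rejected by the biharmonic solver (no boundary data) but is a
legal mask elsewhere.  `count_modules` of an all-gap mask is 0.

## Known limitations

* The vertical-gap track never sees true vertical-gap truth (none exists);
  artificial gaps are a proxy whose fidelity rests on the "consistent in
  location" construction.
* A feature wholly inside a gap band with no trace outside it cannot be
  recovered by any method here; the benchmark asserts this as a property
  rather than treating it as a defect.
* Parameter counts for the tunable U-Net depend on unspecified block
  internals and are intentionally not pinned to reference values.
* Desk-scale training budgets are orders of magnitude below the full
  recipe; reported desk-scale metrics characterize the implementation,
  not achievable reconstruction quality.
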
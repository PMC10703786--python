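# Methods

## Problem and model

Breast-ultrasound lesion segmentation is hard because lesion boundaries
are blurred by low contrast, shapes are irregular, and the image is
corrupted by speckle noise and posterior acoustic shadowing. The package
implements a three-path U-structure network (TPUNet) for this task:

- **Three-path encoder.** Three independent encoding paths of depths
  2, 3 and 4 process the same single-channel image. Each path is a chain
  of UNet-style blocks (two 3×3 conv → batch-norm → ReLU units) with 2×2
  max-pooling between blocks, so path *p* produces feature maps at
  levels 1..depth(*p*) with channel widths `base·2^(ℓ−1)`. The shallow
  (inner) path preserves texture and small-target detail; the deep
  (outer) path extracts abstract semantics.
- **Attention-based feature fusion (AFF).** Wherever two or three paths
  provide same-resolution skip features, they are fused competitively.
  The channel sub-module global-average-pools each input to a C-vector,
  reduces the concatenated 2C descriptor with a learned linear map, and
  applies a sigmoid, giving a per-channel gate α∈(0,1); the two-input
  channel fusion is `α·A + (1−α)·B`. The spatial sub-module reduces each
  input to a 1-channel map (channel-mean ‖ channel-max → 1×1 conv, one
  independent conv per input) and softmaxes across inputs, giving
  per-pixel weights that sum to one. The AFF output applies both at
  once: `α·α′·A + (1−α)·β′·B`, and for three inputs
  `α(1−β)α′·A + β(1−γ)β′·B + γ(1−α)γ′·C`, where the three channel gates
  come from the cyclic pairs (A,B), (B,C), (C,A).
- **Decoder and deep supervision.** Decoding starts from the outer
  path's level-4 features; each stage bilinearly upsamples 2×,
  concatenates the AFF-fused skip, and applies a conv block. At the
  bottleneck and each of the three decoder stages, a 3×3 convolution to
  one channel, bilinear upsampling to input size, and a sigmoid produce
  an auxiliary probability map; the final prediction uses a separate
  1×1 convolution head on the level-1 decoder features.

## Loss

`L_total = L_deepsup + λ·L_seg` with λ = 0.6.

- `L_deepsup = Σᵢ λᵢ·BCE(pᵢ, g)`, λᵢ = 0.1 over the four auxiliary heads.
- `L_seg = (L_focal + L_focal_tversky) + α(epoch)·L_HD`.
- Focal loss: `mean(−α_t(1−p)^γ g log p − (1−α_t)p^γ(1−g)log(1−p))`,
  α_t = 0.8, γ = 2.
- Focal Tversky: `(1−T)^γ` with `T = TP/(TP + 0.3·FP + 0.7·FN)` on soft
  pixel counts and γ = 2; the FN-heavy β shrinks missed-lesion regions.
- Boundary (Hausdorff-distance) loss:
  `mean((g−p)²·(d(p)² + d(g)²))`, where d(·) is the unsigned Euclidean
  distance-to-boundary map of the 0.5-thresholded mask. Both distance
  maps are constants with respect to the gradient; gradients flow only
  through the squared error, following the HD-loss literature. The
  weight α ramps 0 → 1 by 0.005 per epoch (epoch counter starts at 0),
  so training attends to regions first and boundaries later.

Numerical choices: probabilities are clamped to [ε, 1−ε], ε = 1e-6,
before logs; ε is also added to the Tversky numerator and denominator so
the index is defined for empty masks; all-zero/all-one masks have no
boundary and get all-zero distance maps, degrading the boundary term to
zero rather than NaN. `L_seg` is applied to the final head only — the
total separates the deep-supervision and segmentation terms, and the
two heads are deliberately distinct parameters.

## Implementation substrate

The runtime environment provides no deep-learning framework, so the
package carries a small tape-based reverse-mode autodiff engine on
NumPy (`tpunet.nn`). Convolutions are lowered to k² shifted
channel-last GEMMs (BLAS `sgemm`); the input gradient of a stride-1
convolution is computed by the transposed form of the same loop.
Bilinear resizing is expressed as two precomputed interpolation-matrix
products, which makes its adjoint exact. Batch normalization is built
from differentiable primitives (batch statistics in training, running
statistics with momentum 0.1 in evaluation). All gradients are verified
against central differences in the test suite. Parameters are float32;
the engine preserves float64 when given float64 inputs, which the
numerical-equivalence tests exploit.

## Training recipe

Adam, starting learning rate 0.003; the validation mean IoU is
monitored every epoch, parameters are checkpointed whenever it strictly
improves, and the learning rate is halved after 30 epochs without
improvement (the patience counter resets on halving). Validation uses
the same post-processing as test-time scoring, since checkpoint
selection monitors mIoU. Training batches are augmented with random
horizontal flips and random rotations (±15°; the magnitude is not
specified in the source recipe) applied identically to image and mask;
rotation fills with black. Batch size defaults to 8. Everything —
initialization, shuffling, augmentation — derives from the config seed,
and the training loop pins BLAS to a single thread (floating-point
reduction order then no longer depends on the host's core count), so
loss trajectories are bit-reproducible.

## Evaluation

- IoU = |A∩B|/|A∪B|; two empty masks score 1 (perfect agreement).
- HD95: boundaries are foreground pixels 4-adjacent to background; the
  directed nearest-boundary distances of both directions are pooled and
  the 95th percentile (linear interpolation) is reported. The printed
  definition 0.95·max(h(∂A,∂B), h(∂B,∂A)) is also implemented
  (`mode="scaled_max"`); the percentile reading is the default because
  it is the convention of the metric's literature. When exactly one
  mask is empty (or has no boundary), the image diagonal is scored as a
  penalty and the pair is counted in `n_skipped_hd95`; two empty masks
  score 0.
- Post-processing keeps the largest 8-connected component of the
  thresholded (strictly > 0.5) prediction; ties break by label scan
  order (top-left first).

## Synthetic phantoms

The generator emulates the failure modes of breast ultrasound at the
texture level: a speckle-textured background (multiplicative Gaussian
noise times a low-frequency inhomogeneity, both scaled by the speckle
strength) containing one darker lesion whose boundary is an ellipse
modulated by random harmonics of orders 2–5, rescaled so the enclosed
polygon area matches the sampled area fraction, optionally softened by
Gaussian blur, plus (with probability 0.3) a posterior shadow band with
linear falloff. Defaults: area fraction 0.02–0.25 of the image,
contrast 0.15–0.5, edge blur σ 1–4 px, speckle strength 0.2–0.5,
boundary irregularity 0–0.3. With zero speckle and blur, the
construction is exact: lesion mean = background mean − contrast.

The phantoms contain no acoustic physics (no beamforming, RF, or
depth-dependent attenuation), so passing tests demonstrate that the
architecture, loss, and pipeline function and learn — not clinical
performance. At the small smoke-test resolution (64 px), the harder
corner of the parameter space (≈3%-area lesions with contrast ≈0.2 and
blur σ ≈ 4 px) is close to invisible, which bounds the attainable mean
IoU; such cases appear at full resolution too but proportionally less
blurred.

## Problem sizes used in tests and the acceptance script

The packaged experiments use a reduced network (base width 8, 64×64
inputs, ≈150k parameters) trained on 64 phantoms with 16-phantom
validation and held-out splits for at most 30 epochs — sizes chosen so
the full pipeline, including three independent seeds, runs comfortably
on a single CPU. Training may stop early once validation mIoU reaches
0.85, since the checkpoint of interest is already saved. The full-size
configuration (base 32, 224×224) is the package default for real use.

## Known limitations

- The channel sub-module's printed reduction ("1D convolution with
  stride C+1") is not implementable as written for a 2C descriptor; the
  default realizes its intent as a learned linear map 2C→C (the
  paired kernel-2 reading is available via `channel_reduce="paired"`).
- BUSI provides no patient identifiers, so splits are image-level.
- Multi-annotation cases are excluded, not merged.
- Tumor-free ("normal") images are excluded from training by default
  (`include_normal=True` to change).
- CPU-only: full-size training on the real dataset is out of scope for
  the bundled experiments.
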
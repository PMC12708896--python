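# Methods

`leafensemble` implements a two-stage ensemble pipeline for diagnosing
plant disease from leaf photographs, at a scale where every stage can be
trained and verified on one CPU core in minutes.  The pipeline is:
synthetic data generation → lesion segmentation (U-Net + shifted-window
transformer, combined per pixel) → region-of-interest (ROI) extraction →
classification (CoAtNet and Enhanced CoAtNet) → decision fusion with
weights found by a Levy-Flight Honey Badger Algorithm (LFHBA) →
evaluation (one-vs-rest metric suite, ROC/AUC, Grad-CAM heatmaps).

## Numerical substrate

No deep-learning framework is used.  The networks run on a small
reverse-mode automatic-differentiation core over numpy arrays
(`_autograd.py`): a `Tensor` records, per operation, a closure that
propagates gradients to its parents; `backward` replays the tape in
reverse topological order.  Convolutions are im2col + matmul; transposed
convolution is implemented as zero-dilation followed by convolution with
the spatially flipped kernel (verified against a direct scatter oracle);
layer/batch normalization and softmax are fused ops with hand-derived
backward passes.  Every op is checked against central differences in the
test suite.  All arithmetic is float32; all randomness flows through
seeded `numpy.random.Generator` instances, so runs are bit-reproducible
on one platform.

## Synthetic data

Real corpora of this kind are directory-per-class folders of RGB leaf
photos with no segmentation ground truth.  The generator emulates that
structure: a superellipse "leaf" with vein lines on a dark backdrop,
with elliptical lesions painted inside the leaf.  Because the generator
paints the lesions, an exact binary mask is available for free — that is
what makes the segmentation stage supervisable and Dice-scorable, which
real data of this kind would not support.

Per-class lesion styles control count, radius, color and noise.  The
default styles place lesion hues on the color-wheel band [0.5, 1.25) mod
1 — cyans through blues, magentas, reds to yellow — deliberately
skipping leaf greens so every class is visible against the canvas and
the default classes are pairwise separable by color.  Texture noise
(sd 0.02), Gaussian blur (0.8 px) and multiplicative lighting jitter
([0.9, 1.1]) roughen the signal.  Defaults are 38 classes of 224 px
images, mirroring the structure of the public corpus the pipeline
targets; the tested desk profile uses 5 classes at 64 px.

What the generator does **not** emulate: real lesion texture, occlusion,
field backgrounds, specular lighting, inter-class similarity of real
diseases, or label noise.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and can learn a separable signal — they
say nothing about accuracy on real leaves.

A second simulator fabricates per-classifier probability matrices with
exact Bernoulli-controlled argmax accuracy (rows drawn from a Dirichlet
peaked at the chosen mode, concentration 8 by default, with a swap
enforcing the argmax contract).  It exercises the fusion stage without
any trained network.

## Segmentation

*U-Net*: encoder levels of 3x3 conv + ReLU + 2x2 max pooling (channels
double per level), a bottleneck conv, and decoder levels of stride-2
transposed convolution, concatenation with the matching encoder map, and
conv + ReLU; a 1x1 conv + sigmoid head emits per-pixel foreground
probabilities.

*Windowed-attention segmenter*: 4x4 patches are flattened and linearly
projected (learned absolute position embeddings added — the standard
minimal choice), then processed by stages of transformer blocks that
alternate plain windowed attention and cyclically-shifted windows
(shift = window/2) with the standard region-id boundary mask, so shifted
blocks mix information across window borders without attending across
the cyclic wrap seam.  Blocks are post-norm, matching the equations this
architecture is usually written with at this level of description:
`y = LN(x + Attn(x))`, `z = LN(y + MLP(y))`, MLP = linear → ReLU →
linear.  Patch merging (2x2 concat → linear 4C→2C) halves resolution
between stages.  The upsampling head (1x1 conv per stage output,
bilinear upsample to full resolution, summed, 1x1 conv + sigmoid) is a
deliberately light decoder: segmentation quality at desk scale is
carried mostly by the U-Net, and the transformer member contributes
complementary errors for the ensemble.

The ensemble combines member probability maps per pixel (mean by
default; max and simplex-weighted rules available) and thresholds at 0.5,
with score == threshold counting as foreground.  ROI extraction zeroes
background pixels, crops to the mask bounding box padded by 10%, and
resizes back to the classifier input size; an empty mask passes the full
image through with a logged warning.

Training minimizes pixelwise binary cross-entropy plus Dice loss — BCE
alone is dominated by the ~97% background pixels, while the Dice term
directly rewards overlap — with minibatch Adam.

## Classification

*CoAtNet*: a stride-2 stem then stages of either convolutional blocks
(3x3 conv + batch norm + ReLU with residual; batch norm after the
stem/downsample convs follows the architecture's standard convolutional
practice and is required for stable desk-scale optimization) or
transformer blocks (global multi-head scaled dot-product attention over
the flattened grid + FFN, post-norm).  At least one conv stage precedes
the first transformer stage.  Global average pooling, linear head,
softmax.

*Enhanced CoAtNet* adds, on top of the same trunk: multiscale feature
aggregation — the last `n_scales` stage maps are 1x1-projected to a
common width, bilinearly resized to the coarsest scale and summed with
convex weights α = softmax(learnable logits) — an adaptive attention
module `λ1·Conv(x) + λ2·SelfAttn(x)` with free (unconstrained) scalars
λ initialized at 0.5, dropout (rate 0.1, inverted, inside the
transformer path and after the adaptive module), and batch normalization
(eps 1e-5, momentum 0.1).  α is constrained to the simplex because the
scales' "contributions" are meant to be convex weights; λ is left free
because nothing in its definition imposes a constraint.

The adaptive module *supplements* the trunk (post-aggregation
refinement) rather than replacing its transformer stages; the
alternative reading (replacement) would discard the trunk's global
context and was not taken.

## Decision fusion

Fusion is the rowwise convex combination `F = Σ w_i C_i(X)` of the
classifiers' probability matrices.  The weights are found by LFHBA, a
population metaheuristic with two moves per candidate per iteration:

* attraction toward the incumbent best `P`:
  `X' = X + r (P - X) e^{-t/T}`, `r ~ Uniform(0, 1)` drawn fresh per
  candidate per iteration;
* with probability 0.5, instead a Levy move `X' = X + S ∘ (P - X)`
  where `S` is drawn per dimension by Mantegna's construction
  (`S = scale · u / |v|^{1/β}`, `u ~ N(0, σ_u²)`, `v ~ N(0,1)`, σ_u the
  Gamma-function ratio, β = 1.5), giving occasional heavy-tailed jumps
  past the best.

Candidates keep a move only on improvement (greedy selection); the
global best is elitist, so the best-fitness trace is nonincreasing by
construction.  The Levy step multiplier defaults to 1.0: because the
step multiplies the attraction vector `(P - X)`, a unit multiplier makes
typical Levy moves comparable to attraction moves while the heavy tail
still overshoots; sub-unit scales (e.g. the 0.01 conventional for
*absolute* cuckoo-style steps) strangle the jumps and the search stalls
on the incumbent best.  The sphere benchmark in the acceptance script
measures the convergence this default achieves.

Weight search runs in an unconstrained box [-5, 5]^N and maps each
candidate to the simplex by softmax before evaluation — this guarantees
valid convex fusion and keeps the search space smooth.  Fitness is the
negative argmax accuracy on a validation split (ties toward the lowest
class index); mean cross-entropy is available behind a switch for
calibration-sensitive uses.

## Evaluation

Per-class one-vs-rest metrics from the confusion matrix: accuracy
(TP+TN)/(TP+TN+FP+FN), recall TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP), F1 = 2PR/(P+R); zero-denominator cells are defined
as 0; the default average is macro (unweighted over classes), micro
available.  ROC AUC is one-vs-rest per class (trapezoidal, via
scikit-learn), macro-averaged over classes present in the truth.

Grad-CAM: channel weights are the spatial mean of the gradient of the
target-class *logit* with respect to a chosen feature map; the heatmap
is the rectified weighted channel sum, bilinearly upsampled to the input
and max-normalized (an all-zero map stays zero).  The default layer is
the last convolutional stage (CoAtNet) or the aggregated multiscale map
(Enhanced).  The localization check uses a detection-style probe —
lesion-bearing vs lesion-free leaves with every lesion confined to the
top-left quadrant — because only there is the positive evidence strictly
localized; with several lesion-bearing classes, class-common leaf
structure legitimately attracts diffuse saliency and the argmax is not a
meaningful localization statistic.

## Desk profile and problem sizes

The tested configuration ("desk" profile) is chosen so every stage
trains in minutes on one core while leaving headroom above the quality
bars: 5 classes × 100 images at 64 px (60/20/20 train/val/test);
U-Net depth 3 / base 8 (lr 3e-3); transformer segmenter embed 24,
depths (2,2), window 4 (lr 5e-3 — attention blocks want a slightly
larger step at this size); classifiers with stage layout (conv, conv,
transformer) and channels (8,16,32) at lr 2e-3, batch 32, 12 epochs.
The 4-stage default layout at 64 px would downsample to a 2×2 final map
and trains unreliably; three stages keep an 8×8/4×4 pyramid.  The
"paper" profile records the full-scale configuration (38 classes,
224 px, Adam lr 1e-3, batch 32, 200 epochs) and is not exercised by the
tests.  LFHBA runs pop 20 for 60 iterations in the pipeline (100 by
default standalone).

Typical desk-profile results (seed 0): U-Net validation Dice 0.94,
transformer member 0.84, fused test accuracy 0.96 over members
0.96/0.93, macro AUC ≈ 0.999; the standalone 3-class learning checks
reach 0.97–1.0 classifier validation accuracy.

## Numerical choices and degenerate inputs

* Thresholds: score == threshold counts as foreground; argmax ties break
  toward the lowest class index (numpy convention).
* Dice of two empty masks is 1; BCE probabilities are clipped by 1e-6.
* Batch norm in training mode rejects batches of one; inference mode
  uses running statistics (momentum 0.1).
* Empty segmentation masks fall back to the whole image at ROI
  extraction (logged).
* Checkpoints are keyed by a SHA-256 fingerprint of the producing
  configuration; a stale or corrupt checkpoint triggers retraining with
  a warning.
* Augmentation rotates by exact `rot90` at right angles and bilinear
  interpolation with border-median fill otherwise; masks always use
  nearest-neighbor and are re-binarized.

## Known limitations

* The synthetic classes are separable by lesion color alone; nothing
  here measures robustness to realistic intra-class variation.
* The transformer segmenter's light upsampling head caps its standalone
  Dice well below the U-Net's at desk scale.
* The optimizer implements the single printed attraction update plus
  Levy moves; the full Honey Badger Algorithm's digging/honey phases,
  smell intensity and density factor are intentionally out of scope.
* Grad-CAM argmax localization is only meaningful under the detection
  probe described above, and even there a minority of training
  initializations learn diffuse features whose heatmap argmax scatters;
  the acceptance script reports the hit rate its seed actually produces.
* float32 without any mixed-precision or SIMD tuning: the full-scale
  profile is far outside this implementation's practical envelope.
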
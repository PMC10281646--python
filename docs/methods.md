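# Methods

`lesionfuse` implements a multiclass skin-lesion recognition pipeline:
geometric augmentation with class balancing, deep-feature extraction at
the global-average-pooling (GAP) layer of two CNN backbones, serial
(concatenation) fusion of the two feature streams, wrapper feature
selection with a butterfly-optimization metaheuristic, cross-validated
evaluation over a fixed classifier roster, and Grad-CAM saliency maps.
This note records the model choices, defaults, and the numerical
decisions behind each stage.

## Augmentation and balancing

The augmentation vocabulary is purely geometric: transpose, vertical
flip, horizontal flip, and exact 90° rotation.  Flips reverse row or
column order (the 0-based equivalent of mapping row *a* to *m* + 1 − *a*
in 1-based matrix notation); rotation is the index permutation induced
by the 2-D rotation matrix at quarter turns applied to homogeneous
pixel coordinates.  No interpolation occurs anywhere, so every operator
is a bijection on pixel values and the pixel multiset is preserved
exactly.

These operators generate the 8-element dihedral symmetry group of the
pixel grid.  Class balancing retains all originals and then cycles
through the seven non-identity symmetries (vertical, horizontal, 90°,
180°, vertical∘90°, horizontal∘90°, 270°), each applied to the
originals in order, until the target count is reached.  Variant-major
order spreads the oversampling evenly across originals.  Because only
eight distinct variants of an image exist under this group, targets
beyond 8× the class size are refused rather than silently emitting
duplicates.  Balancing a 6-class set to 6,000 images per class — the
pipeline's full-scale operating point — therefore requires at least 750
originals per class and yields 36,000 images.

Rotation direction is counter-clockwise; since the operator set is
closed under composition, the choice does not affect balancing
coverage.  Transpose is exposed in the API but is not part of the
default balancing cycle, which uses only the flip/rotate operators.

## Backbones and the numpy CNN engine

Backbones run on the package's own CNN engine (`lesionfuse.nn`):
2-D convolution, depthwise and depthwise-separable convolution, ReLU,
max pooling, GAP, dense and softmax layers, each with an exact analytic
backward pass verified against numeric differentiation in the test
suite.  Everything is plain numpy with no hidden global state, so a
fixed seed yields bit-identical training runs across platforms — the
property the end-to-end determinism guarantees rest on.

Three presets are registered:

| preset       | GAP layer  | feature width | role |
|--------------|-----------|---------------|------|
| `xception`   | `avg1`    | 2048 (FV1)    | compact separable-conv stack, channel progression …728 → 1024 → 1536 → 2048 |
| `shufflenet` | `node_200`| 544 (FV2)     | light separable stack, 24 → 136 → 272 → 544 |
| `tinycnn`    | `gap`     | 8 (configurable) | two-conv fixture backbone for desk-scale training |

The two large presets reproduce the *feature geometry* of their
namesakes — the GAP widths that determine every downstream dimension —
at reduced depth, with weights drawn from the construction seed.
Externally trained weights can be loaded onto any preset through the
layer parameter arrays; nothing in the pipeline depends on how the body
weights were obtained.

Fine-tuning replaces the final three layers (dense prediction, softmax,
classification output) with a fresh head of width `n_classes` and
retrains **all** layers with mini-batch RMSProp on cross-entropy.
Defaults follow the deep-transfer recipe: 3 epochs, learning rate 1e-4,
mini-batch 16, on a stratified 50:50 train/test split that is recorded
and returned so downstream stages can reuse the same partition.  (The
training literature for this setup quotes both batch 8 and mini-batch
16; the default is 16 with 8 available via config.)  For the
from-scratch `tinycnn` fixture the tests use learning rate 1e-2 — the
standard RMSProp scale when no pretrained initialization exists; 1e-4
is a transfer-learning rate and barely moves a randomly initialized
network in 3 epochs.

Features are read at the GAP layer — the spatial mean of each channel
of the last convolutional block — for **all** images, with the
train/test split recorded alongside, since downstream cross-validation
re-partitions the data itself.

## Serial fusion

Fusion is column-wise concatenation: a *k*-dimensional and an
*n*-dimensional feature vector combine into a (*k* + *n*)-dimensional
one.  For the two presets this is 2048 + 544 = 2,592 columns.  No value
is scaled or transformed; both blocks remain recoverable by column
slicing, and block boundaries plus provenance tags are kept on the
fused matrix.  Alignment is enforced by sample id and label equality —
mismatches raise rather than silently reordering.

## Butterfly-optimization feature selection

A candidate subset is a butterfly: a point **b** ∈ [0, 1]^D binarized
at 0.5 into a column mask (an all-below-threshold position falls back
to its single largest coordinate, so masks are never empty).  Each
butterfly emits fragrance F = s·K^x with sensory modality s = 0.01 and
stimulus intensity K = 1/(1 + cost), so lower-cost subsets smell
stronger; the power exponent x grows linearly 0.1 → 0.3 over the run.
Per iteration each butterfly draws d ~ U[0, 1] and takes the global
move toward the incumbent best c* with probability p = 0.8,

    b ← clamp₀₁( b + (d²·c* − b)·F ),

else the local move against a random population member b_m,

    b ← clamp₀₁( b + (d²·b − b_m)·F ).

Defaults: population 10, 100 iterations.

Two elements beyond the bare move equations make the search effective,
and both are documented as this package's intensification design:

1. **Greedy acceptance.**  A butterfly keeps a move only if it does not
   worsen its own cost — the acceptance rule the original
   butterfly-algorithm reference code (like the flower-pollination code
   it derives from) applies.  The pseudo-code is silent on acceptance.
2. **Elitist flip/swap refinement.**  After each iteration, the best
   mask proposed in that iteration is hill-climbed over single-bit
   flips and drop-one/add-one swaps (budget 512 cost evaluations per
   iteration, configurable; 0 disables it).  Any improvement replaces
   the incumbent.  Without refinement, the continuous dynamics under
   threshold binarization revisit only a few dozen unique masks in a
   whole run and essentially never resolve the one- and two-bit
   differences that separate neighboring subsets under the size
   penalty; with it, the search matches an exhaustive oracle on
   12-column planted tables in ≥ 9 of 10 seeds.

The wrapper cost of mask S over D columns is

    cost(S) = α·err(S) + (1 − α)·|S|/D + γ·(1 − H̄(S)),   α = 0.99, γ = 0,

where err(S) is the misclassification rate of a 1-nearest-neighbor
classifier on the selected columns under a stratified 70/30 internal
holdout drawn once per run from the config seed (so every mask in a
run, and the exhaustive oracle sharing the config, is scored against
the same partition).  The optional entropy term rewards subsets whose
columns have high mean normalized Shannon entropy after equal-width
10-bin discretization; it is an interpretation of an "entropy added to
handle uncertainty" for which no formula exists, is off by default, and
is clearly flagged as such.  Inside the evaluator the 1-NN error is
computed by a direct BLAS distance arg-min (identical to a fitted 1-NN
classifier, orders of magnitude faster over the thousands of masks a
run scores); results are memoized by mask.

`exhaustive_select` scores every nonempty mask with the same evaluator
and is guarded to D ≤ 20; ties break toward the smaller subset, then
lexicographically on the selected indices.  Elitism makes the
best-cost-per-iteration trajectory non-increasing by construction.

## Evaluation harness

The roster mirrors the named presets of point-and-click classification
tools: narrow/medium/wide neural networks (one hidden layer of
10/25/100 units), bilayered and trilayered networks (2 or 3 × 10),
quadratic and cubic SVMs (polynomial kernels, degree 2 and 3), a coarse
Gaussian SVM (RBF, kernel scale 4·√D, i.e. γ = 1/(16 D)), fine KNN
(k = 1), a bagged-tree ensemble (30 trees) and a fine decision tree
(≤ 100 leaves).  These names are conventions, not published parameter
sets; exact parity with any particular toolbox is a non-goal.  Neural
networks and SVMs fit standardized features; KNN and trees take raw
columns.

Cross-validation is stratified 10-fold with shuffling; each sample is
predicted exactly once by a model that never saw it, and the confusion
matrix is aggregated over folds.  From it: accuracy, macro recall,
macro precision and macro F1 in percent, and FNR = 100 − macro recall.
Macro averaging (equal class weight) is the single convention under
which the FNR/recall identity holds exactly, and it is enforced as a
test.  A class whose predicted column is empty has undefined precision
and contributes 0 to the macro precision average.  Wall-clock training
time is recorded per classifier for information only — it is
hardware-dependent and never asserted or compared.

## Grad-CAM

For target class c and a convolutional layer (default: the last one,
whose activations the GAP features are pooled from), the pre-softmax
class score is backpropagated to the layer's activation maps A_k;
channel weights w_k are the spatial means of those gradients, and the
map is ReLU(Σ_k w_k·A_k), max-normalized to [0, 1] and bilinearly
upsampled to the input size.  An identically-zero raw map stays zero
rather than dividing by zero.  Max-normalization makes the map
invariant to positive rescaling of the class-score gradients.

## Synthetic data: what it emulates and what it does not

`make_image_set` draws class-labeled images of one colored, striped
elliptical blob (class-specific hue and stripe period, randomized
position/size/orientation) on a noisy gray background, recording each
blob's bounding box.  It gives every downstream stage a verifiable
ground truth: classes are nearly separable even on raw pixels, and the
recorded boxes define the "important region" a faithful saliency map
must hit.  It deliberately does **not** mimic dermoscopic image
statistics — no hair, rulers, vignetting, or the low inter-class /
high intra-class variation of real lesion data — so passing fixture
tests demonstrates mechanical correctness of the pipeline, not clinical
performance.

`make_feature_table` plants `d_informative` signal columns among
independent standard-Gaussian noise columns.  Class means follow a
cyclic one-hot pattern — column j carries a +`class_sep` shift for
classes c with (j − c) mod n_classes = 0 — so no single column
separates all classes but the planted subset jointly does, which makes
the exhaustive-search optimum computable and the planted subset
recoverable.  Labels are round-robin, hence exactly uniform when the
class count divides n.  At the standard test operating point
(n = 200, 3 informative + 9 noise columns, class_sep = 4) the
holdout granularity (60 test points) means the exact optimum
occasionally includes one extra "lucky" noise column; the planted
subset is still recovered with mean Jaccard ≈ 0.8 across split seeds.

## Problem sizes used in tests and the acceptance script

Fixture tests run at small scale by design: blob sets of 50 images per
class at 32 px for training/saliency, 12-column planted tables for
selection, and a 3-class 32-px end-to-end pipeline.  The acceptance
script additionally runs the full-scale balancing computation (6
classes × 1,000 originals at 64 px balanced to 6,000 per class =
36,000 images) and the preset-width/fusion path on real forward passes
of the 2048- and 544-channel backbones.

## Known limitations

* Preset backbones reproduce GAP feature geometry, not the full
  36-layer / channel-shuffle internals or any pretrained weights, and
  no claim is made about matching published training trajectories.
* The selection metaheuristic's oracle-equality behavior is verified on
  planted tables up to D = 12 (bounded by exhaustive search); on
  2,592-column inputs only the qualitative reduction behavior is
  checked.
* The entropy regularizer is an interpretation, not a published
  formula, and defaults to off.
* Wall-clock columns in reports are informational; they vary across
  machines and runs.
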
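# Methods

## Problem and scope

`toothmark` classifies microscope images of carnivore tooth marks on bone
into four taxa — crocodile, hyena, leopard, lion — and reports how much
trust to place in each attribution. It implements two training regimes
that share one classification-head architecture over a frozen
feature-extracting backbone:

* **FSSL** (few-shot supervised learning): ordinary supervised
  transfer-learning optimization, but with the n-way k-shot batch
  structure of few-shot learning — every mini-batch holds exactly
  `k_shot` examples of each of the four classes, and an epoch consists of
  `n_tasks` such batches.
* **MAML** (model-agnostic meta-learning): episodic training. Each
  episode draws a class-balanced *support* set and a *query* set; an
  inner loop adapts the head parameters on the support loss by a few
  plain gradient steps, and the outer loop updates the meta-parameters by
  the gradient of the query loss **through** the inner steps
  (second-order by default; a `first_order` flag selects the FOMAML
  approximation).

A third component combines trained models of each regime into an
accuracy-weighted soft-voting ensemble and applies a dual-method
reliability rule to individual marks: an attribution is *reliable* only
when the FSSL and MAML ensembles agree on the arg-max taxon and both
arg-max probabilities exceed 0.70; otherwise it is flagged
*interpretation with caution* (the arg-max taxon is still reported).

## Data model and the synthetic bank

The reference image bank holds 1296 marks with unbalanced per-class
counts (crocodile 124, hyena 364, leopard 544, lion 264) and variable
native image sizes. Because that bank is an external download, the
package ships a synthetic generator that reproduces the bank's
*statistical* structure — four separable classes, unbalanced counts,
variable sizes — without attempting realistic mark micro-morphology.

Each image is one elliptical mark over a bone-like background (warm base
color plus Gaussian-smoothed low-frequency noise). Class information
lives only in the mark region, controlled by a five-parameter signature:
ellipse aspect ratio, boundary roughness, center-to-edge depth gradient,
hue tint (degrees on the circular 0–180 hue scale) and interior texture
frequency. A single `separability` scalar interpolates all four class
signatures linearly between one shared base signature (`0` — class
distributions identical, so chance accuracy 0.25 is the ceiling) and
four fixed, well-separated signatures (`1`). Images are written as PNG
so regeneration under a fixed seed is bit-identical.

What the generator deliberately does **not** emulate: real mark
morphology (pits vs scores), magnification and lighting variation,
bone-surface weathering, inter-individual variation within a taxon.
Passing tests on synthetic banks therefore demonstrate that the
*pipeline learns what it is given* (and cannot beat chance when given
nothing), not that the architecture reaches any particular accuracy on
real tooth marks.

## Splitting

Banks are split 70/15/15 (train/validation/test). The global train size
is round-half-up(0.70·N) and the validation size round-half-up(0.15·N);
the test split takes the remainder. For N = 1296 this yields 907/194/195
— matching the published training count (907) and test support (195);
the source's own arithmetic (907 + 390) is internally inconsistent by
one record, and the remainder convention above is how this package
resolves it. Per-class allocations use the largest-remainder rule with
ties broken by descending class size, so every class's share of every
split is within one record of its exact quota.

## Architectures

Backbones are frozen feature extractors. The five named ImageNet
backbones (ResNet50/152 and DenseNet201 at 224×224 input,
Xception and EfficientNetV2L at 299×299) are declared with their
normalization contracts, but pretrained weights are not shipped;
requesting one raises an error pointing to the **standin** backbone: a
three-stage conv/ReLU/average-pool stack with randomly initialized,
frozen weights mapping a 64×64 RGB input to an 8×8×32 feature map. The
standin is the default for tests and desk-scale experiments; random
frozen convolutional features are a standard cheap proxy for a
pretrained extractor at this problem scale.

Two heads sit on the backbone's last convolutional feature map:

* **complex** — two residual blocks of depthwise-separable convolutions
  (kernel 3, stride 1, 'same' padding), each followed by a
  squeeze-and-excitation (SE) channel gate, then global average pooling,
  a 512-unit ReLU dense layer, dropout, batch normalization and a
  4-class softmax. The residual shortcut is the identity when channel
  counts match (always true here) and a 1×1 convolution otherwise.
* **baseline** — a single standard convolution with 512 filters, then
  the same GAP → dense(512) → dropout → batch-norm → softmax tail.

Defaults: dropout 0.5 (from a tested 0.3–0.8 range with little effect),
SE reduction ratio 16 (configurable; the bottleneck width is
`max(1, c // reduction)`), dense width 512. Dropout precedes batch
normalization, following the order in which the original regularization
stack lists them.

## Training

Optimizers: Adam (default learning rate 1e-3 for FSSL), Adagrad, and
SGD with momentum. Early stopping monitors validation loss with
patience 15 and restores the best-epoch weights. The learning rate is
multiplied by 0.1 at predefined milestone epochs (default [40, 70];
the source does not specify its milestones). Maximum epochs default to
100 with early stopping as the effective stop.

Shot-task presets: FSSL low-shot (5-shot, 40 tasks), FSSL high-shot
(10-shot, 20 tasks), MAML low-shot (5-shot, 40 tasks, 3 query per
class), MAML high-shot (10-shot, 24 tasks, 3 query per class).
`n_way` is always 4 — all taxa appear in every batch/episode. The
"three query" count is read *per class* (12 query images per episode);
per-episode total is available as a config switch. Classes smaller than
an epoch's demand (the crocodile training split under 5-shot × 40-task)
use an exhaust-then-recycle queue: draws are without replacement until
the class is exhausted, then the queue reshuffles; every record appears
at least once per epoch and recycles are logged.

MAML specifics: the inner loop adapts **head parameters only** (the
backbone is frozen in both regimes); inner learning rate 0.01 and one
inner step by default, meta-optimizer Adam at 1e-4 (none of these are
specified by the source; all are exposed in config). Batch
normalization inside episodes uses current-batch statistics
(transductive convention) and never updates the running estimates;
dropout is disabled inside episode passes, since a stochastic mask
inside the differentiated inner loop adds gradient noise without a
regularization target — the meta-objective itself regularizes.
Validation is episodic (adapt on a validation support set, score the
validation query set) to match the meta-objective. After training, the
deployed predictor is produced by one final adaptation on a support
episode from the training split, with that support batch's
normalization statistics frozen in as the running estimates; standard
evaluation-mode prediction applies from then on.

## Differentiation engine

No deep-learning framework is used: the package carries a small
reverse-mode automatic-differentiation engine over numpy arrays
(`toothmark.autodiff`). Its backward pass is built from the same
differentiable primitives as the forward pass, so higher-order
derivatives — required by the second-order MAML meta-gradient — work by
construction. Convolutions are lowered to cached gather indices plus
matrix multiplication (im2col); the gather/scatter pair is linear and
self-adjoint, which keeps the lowering valid at every derivative order.
Correctness is pinned by tests: elementwise and matrix primitives
against central finite differences, the meta-gradient of a two-parameter
logistic toy model against finite differences at 1e-4 relative
tolerance (observed agreement ~1e-11), and inner-loop updates against
closed forms on quadratic losses at 1e-10.

All computation is float64. Log-softmax subtracts the detached row
maximum (gradient-exact by shift invariance). Batch-norm epsilon is
1e-5; optimizer epsilons are the usual 1e-8 (Adam) and 1e-10 (Adagrad).

## Augmentation

Geometric: rotation uniform in ±20°, width/height shifts uniform in
±0.2 of the image side (drawn independently per axis), horizontal flip
with probability 0.5, nearest-edge border fill, bilinear interpolation.
HSV: exactly one of hue/saturation/value is modified per augmented
image, chosen uniformly; hue lives on a circular 0–180 scale and a
shift in [−10, +10] wraps modulo 180; saturation and value scale by a
factor in [0.8, 1.2] with clamping to the valid range; conversion back
to 8-bit rounds half-up. Augmentation is applied online to training
images only — never to validation or test sets (the source is silent;
this is standard practice). Resizing is bilinear (also unstated;
mainstream default).

## Evaluation and ensembles

Reports carry per-class precision/recall/F1/support plus accuracy,
macro (unweighted) and support-weighted averages, computed unrounded
with two-decimal half-up rounding at render time only. Zero
denominators yield 0 (the convention of mainstream report tooling).
`report_from_rates` reconstructs a full report from printed per-class
precision/recall/support alone, using the identity accuracy =
support-weighted mean recall; this is what lets the package reproduce
published table rows exactly without the underlying label lists.

Ensemble weights are member test accuracies normalized proportionally
(scale-invariant, so percent vs fraction does not matter); raw
accuracies are used rather than accuracy-minus-chance. The reliability
threshold "greater than 70%" is implemented strictly (`> 0.70`); the
borderline published case (0.53) is unaffected either way. Printed
probability vectors are accepted if they sum to 1 within 0.02, since
published rows are rounded.

## Problem sizes for desk-scale runs

End-to-end demonstrations and the acceptance script use banks of 120
images per class at 64×64 with the standin backbone and the complex
head: FSSL trains up to 30 epochs and MAML up to 15 (early stopping
usually fires sooner), which reaches ceiling accuracy on separability-1
banks in about a minute each on one CPU. The complex head is used for
these runs because its depthwise-separable blocks train in a fraction
of the time of the 512-filter baseline convolution at identical
accuracy on synthetic banks; both heads remain available and tested.
Chance-level checks use a 3-standard-deviation binomial band around
0.25 on the 72-image test split.

## Known limitations

* Only the standin backbone is runnable; results on named ImageNet
  backbones require supplying pretrained weights, which the package does
  not ship.
* The published headline accuracies (e.g. 85.13% test accuracy for the
  best meta-learned model) are properties of the real 1296-image bank
  and heavy pretrained backbones, and are not reproducible from the
  synthetic bank; the package reproduces the *metric arithmetic* of the
  published tables exactly and the *behavioral contracts* of the
  pipeline at desk scale.
* The naming of head variants in the source tables ("simple") vs its
  architecture section ("baseline") collides; this package treats them
  as the same object and exposes both `baseline` and `complex`.
* Inclusion probabilities under exhaust-then-recycle are exactly equal
  within a class only in expectation over epochs; within one epoch the
  tail of a recycled queue is drawn with slightly different frequency.
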
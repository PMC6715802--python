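# Methods

## Model

The package centers on one construction: turning a patch classifier into an
end-to-end trainable whole-image classifier.

A patch classifier *f* maps a p × q grayscale patch to softmax
probabilities over c = 5 classes (background, benign calcification,
malignant calcification, benign mass, malignant mass). Its trunk is built
from a block grammar: a VGG block *N* × *K* is *K* 3 × 3 convolutions of
depth *N* followed by 2 × 2 max pooling; a residual block
[*L* − *M* − *N*] × *K* is *K* bottleneck units (1 × 1, 3 × 3, 1 × 1
convolutions, each with batch normalization, plus an identity shortcut;
the first unit carries the block's stride, with a 1 × 1 projection shortcut
where shape changes). The head is global average pooling (GAP) followed by
one fully connected (FC) layer — no flattened FC stack — which is what
makes the trunk input-size agnostic.

Because convolution weights are shared across space, the trained trunk
applies unchanged to a whole r × s image, yielding a u × v × c grid of
patch-class scores (the *heatmap*); the GAP+FC head is equivalently a
1 × 1 convolution whose kernel is the transposed FC weight matrix, applied
at every grid cell. Conversion to a whole-image classifier h = g∘f removes
the head and appends top layers *g* in one of three variants:

* **conv blocks, no heatmap** (default): two convolutional blocks directly
  on the trunk's feature map, then GAP and a d = 2-way output;
* **heatmap then conv blocks**: a 1 × 1 convolution initialized from the
  head weights (optionally random) reduces to the 5 class channels with
  ReLU or per-cell softmax activation before the top blocks — ReLU is the
  default activation because a per-cell softmax squashes gradients flowing
  to the trunk;
* **heatmap, max-pool, FC with shortcut**: the activated heatmap is
  max-pooled (e.g. 5 × 5), flattened, passed through two FC layers, with an
  additive shortcut from the flattened heatmap straight to the output
  scores. This variant fixes the image size at construction.

Receptive-field bookkeeping uses the standard layer walk (rf ← rf +
(k − 1)·jump, jump ← jump·stride), verified in the tests against a
brute-force influence-tracing oracle on random chains. Under same-padding
the heatmap grid is ⌈dim/stride⌉ per side; under valid padding it is
⌊(dim − rf)/stride⌋ + 1; both conventions are recorded on every Heatmap.
The exact equality between the fully convolutional heatmap and brute-force
sliding-window evaluation holds only for valid padding (same-padding
borders see zeros rather than neighboring tissue), so the equivalence
suite uses valid-padding toy trunks whose trunk output on a patch is
exactly 1 × 1; production presets use same-padding, as is standard for
VGG/ResNet.

The two-class output uses a two-unit softmax rather than a single sigmoid
so the whole-image head mechanically mirrors the c-class patch head; the
reported score is the malignant unit's probability.

## Training

All training uses Adam (β₁ = 0.9, β₂ = 0.999 — framework-standard values)
with softmax cross-entropy. The only preprocessing is subtraction of the
training-split mean gray value, computed once and reused for validation,
test and patch data. Patch batches are re-weighted so each class present
in a batch contributes equal total weight.

Progressive unfreezing is expressed as staged schedules whose scopes must
widen monotonically:

* **patch, pre-trained trunk**: 10⁻³ on the last layer (3 epochs), 10⁻⁴ on
  the top weighted layers (10 epochs; presets 46 for Resnet50, 11 for
  VGG16, otherwise the top 30%), 10⁻⁵ on all layers (37 epochs) — 50
  total; 200 total for the smaller centered-patch (S1) variant;
* **patch, random init**: constant 10⁻³;
* **whole image**: 10⁻⁴ with weight decay 0.001 on the newly added top
  layers (30 epochs), then 10⁻⁵ with weight decay 0.01 on everything (20
  epochs); an optional 200-epoch continuation preset exists for VGG-based
  image classifiers, which converge more slowly;
* **transfer**: a single all-layer stage at 10⁻⁵, 200 epochs, weight decay
  0.01, consuming image-level labels only. Patient subsets are drawn
  preserving the cohort's positive/negative patient ratio.

A weighted "layer" for freeze scoping is a convolution or FC layer
together with its following batch-norm; freezing is enforced by the
optimizer and asserted bit-exactly in the tests. Weight decay is an L2
penalty added to the gradient of weight matrices (not biases or BN
parameters); decoupled decay was not used, matching the era of the
canonical schedules. Best-model selection keeps the weights of the epoch
with the highest validation metric (accuracy for patch training, AUC for
whole-image training); ties resolve to the *later* epoch, because with
small validation sets the metric saturates while training still improves
the model — with strict earlier-epoch selection, the all-layer stage could
never improve on a saturated stage-1 model.

### Desk-scale presets

The test suite and the synthetic experiments run on one CPU, so they use
`desk_scale` presets chosen once as this package's study conditions: 144 ×
112 frames (1/8 of the 1152 × 896 production frame) with 14–28-pixel
lesions, 32-pixel patches, a two-block trunk (widths 8 and 16), a patch
schedule of 2 + 4 + 8 epochs at rates 10⁻²/3·10⁻³/10⁻³, and a whole-image
schedule of 12 + 8 epochs at 10⁻³/10⁻⁴ with the same weight-decay pairing
as the canonical schedule. The desk rates are an order of magnitude higher
than the canonical ones because the canonical ladder exists to protect
externally pre-trained bottom layers, which the randomly initialized tiny
trunks do not have; the staged structure (scopes, monotone widening,
decay) is preserved so the same code paths are exercised.

## Synthetic cohorts

The generator emulates the structure of a screening cohort, not its
appearance: one breast per patient (which keeps breast-level bootstrap
units simple), two views (CC/MLO) carrying the same lesions with jittered
position and size (no projective geometry), backgrounds of smoothed noise
plus low-frequency tissue gradients in a 16-bit intensity range, and
labels defined by lesion pathology — an image is malignant iff it carries
at least one malignant ROI. Lesion phenotypes are fixed defaults chosen so
that the five classes are separable but benign/malignant pairs share their
base morphology (and are therefore confusable, as in real screening):

* masses: smooth elliptical blobs; malignant masses add 8–14 radial
  spicules;
* calcifications: clusters of bright dots over a faint halo (the halo
  keeps the ROI mask a solid region); benign clusters have 4–7 uniform,
  larger dots, malignant clusters 10–18 finer dots of varied
  (pleomorphic) size.

ROI masks cover exactly the modified pixels, so mask-derived contracts
(mean intensity inside > surrounding annulus, tight bounding boxes) hold
by construction.

The platform shift is a pointwise monotone intensity map. The default
platform-B profile is a film-like response with a saturation shoulder:
linear below a knee (26000), compressed to slope 0.15 above it, plus a
base-fog offset (+6000). The shoulder is the load-bearing part: batch-norm
trunks are nearly invariant to smooth monotone remaps such as gamma
curves, which we found leave the whole-image AUC essentially unchanged
across platforms; a shoulder that flattens lesion-range intensities
genuinely degrades zero-shot transfer (held-out AUC drops from ≥0.97
in-domain to roughly 0.56–0.81 across seeds), which is the phenomenon the
transfer experiments need to exhibit. A gamma profile remains available.

What passing tests on this generator do **not** show: performance on real
mammograms. The generator has no breast outline, pectoral muscle, skin
line or vendor-specific noise; its lesions are analytically simple; and
its class phenotypes are chosen to be learnable by small networks. The
synthetic experiments validate the *machinery* — sampling constraints,
conversion exactness, schedule scoping, statistical procedures and the
qualitative orderings (S10 over S1, end-to-end over the two-step baseline,
fine-tuning over zero-shot) — not clinical accuracy.

## Patch sampling

The overlap ratio of a patch with an ROI is the fraction of ROI pixels the
patch captures; for ROIs with more pixels than the patch area the fraction
of the patch covered by ROI is also computed and the larger value used
(otherwise "overlap ≥ 0.9" would be unsatisfiable for large lesions).
Background patches must have zero intersection with every ROI mask.
Centered schemes place the patch center on the ROI bounding-box center,
shifted minimally to stay in bounds; the around-ROI scheme (S10) draws
distinct offsets by rejection sampling and fails loudly, naming the image,
if the constraint cannot be met. Augmentation (flips, rotation ±25°, zoom
0.8–1.2, intensity shift ±20) uses bilinear interpolation with reflective
borders; the intensity shift is applied after the geometric transforms and
clipped to the valid range; identity parameters return the patch
bit-exactly.

## Evaluation statistics

AUC follows the Mann-Whitney convention with ties credited 0.5 (the tie
rule is asserted against brute-force pair counting). Bootstrap confidence
intervals are percentile intervals (2.5/97.5) over resampled units —
images for single-view analyses, breasts for two-view comparisons; paired
differences resample both models jointly. Degenerate resamples containing
one class are redrawn rather than skipped, keeping the run count fixed.
The empirical coverage of the 95% interval is checked by simulation in the
test suite. Operating points pick the smallest sensitivity at or above a
benchmark, breaking ties toward higher specificity. Multi-class confusion
matrices are row-normalized; empty rows stay zero and are flagged.

## Saliency

Guided backpropagation propagates the gradient of the pre-softmax target
score, zeroing negative gradients at every ReLU on the way down. The
positive part of the input gradient is min-max rescaled per image to
[0, 1]; a 0.06 cutoff removes background noise in the rendered overlay
(rescaling precedes the cutoff). Inputs are single-channel, so no
per-channel threshold question arises. Overlay rendering is best-effort
plotting, not part of the tested contract.

## Two-step baseline

Softmax heatmaps of the four foreground classes are binarized at cutoffs
0.3/0.5/0.7/0.9; on each binary grid, connected components
(8-connectivity, standard for blob detection) yield area, major axis
length (from second-order central moments) and mean probability. When
several components exist the largest-area component is read (screening
images carry a single dominant lesion, here and in the data the pipeline
emulates); a `mode="sum"` switch aggregates instead. The fixed-order
concatenation (4 classes × 4 cutoffs × 3 features = 48) feeds a random
forest with published defaults (500 trees, depth 9, min samples split
300); desk-scale experiments lower `min_samples_split` to 10 because 300
exceeds the synthetic training-set size and would reduce every tree to a
single leaf, making the comparison against the end-to-end classifier
vacuous.

## Numerical and degenerate-input choices

* float32 activations/weights; convolution via im2col and BLAS matmul.
* Same-padding is TF-style (asymmetric when total padding is odd).
* Heatmap/sliding-window equivalence is asserted at 1e−5 in float32.
* Percentile CIs are clipped to bracket the point estimate.
* Empty patch datasets, single-class label sets, non-monotone profiles,
  out-of-bounds lesions, oversized patient subsets and malformed block
  grammars raise typed errors rather than propagating NaNs; a NaN/inf
  training loss raises a divergence error naming the stage.
* BI-RADS 0 (incomplete exam) is excluded with a warning: no label can be
  derived from it, and screening-era category-3 exclusion does not cover
  it.

## Known limitations

* No GPU path; the canonical 50-epoch schedules on 224-pixel patches and
  1152 × 896 images are expressed but impractical to run in this engine at
  full scale.
* Loading externally pre-trained VGG16/Resnet50 weights is a supported
  hook (`init=` dict / `load_weights`), but no converter from other
  frameworks' checkpoint formats is bundled.
* The synthetic two-view pairing jitters geometry only; it cannot test
  view-registration methods.
* Batch-norm running statistics update even in frozen stages (freezing is
  defined over trainable parameters); with batch size 2 this is a known
  source of evaluation noise.
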
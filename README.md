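# mammofcn

End-to-end whole-mammogram cancer classification by converting patch
classifiers into fully convolutional whole-image networks.

## The problem

A screening mammogram is large (a full-field digital image is ~4000 × 3000
pixels) while a cancerous lesion can be as small as 100 × 100 pixels, so
classifying whole images directly wastes the signal, and classifiers
trained only on annotated regions of interest (ROIs) cannot run on the
databases that lack ROI annotations. `mammofcn` implements the middle path:

1. **Patch classifier *f*.** A CNN maps a fixed-size patch
   *X* ∈ ℝ^(p×q) to *c* = 5 class probabilities — background, benign /
   malignant calcification, benign / malignant mass — trained on
   ROI-annotated images with the S1 / S10 / S1g patch sampling schemes.
2. **Conversion.** Because *f* is all-convolutional with a global average
   pooling (GAP) head, its trunk applies unchanged to a whole image
   *M* ∈ ℝ^(r×s), producing a *u* × *v* × *c* grid of patch scores — the
   **heatmap** *f*(*M*). The GAP+FC head becomes an optional 1 × 1
   convolution initialized from the head weights.
3. **Whole-image classifier *h* = *g*∘*f*.** Top layers *g* (two VGG or
   residual bottleneck blocks + GAP, or max-pool + FC layers with a
   shortcut) are appended and the whole network is trained end to end on
   image-level labels only, in two stages (new top layers first, then
   everything). Adding a k × k convolution on a trunk with receptive field
   *r* and stride *s* widens the receptive field by (k − 1)·*s* per side.
4. **Evaluation.** Flip-averaged (augmented) prediction, model ensembling,
   CC/MLO two-view averaging, ROC AUC with percentile-bootstrap confidence
   intervals (image- or breast-level resampling), operating points against
   a sensitivity benchmark, guided-backprop saliency maps, and the
   classical two-step baseline (binarized heatmaps → regional features →
   random forest) for comparison.

A seeded synthetic screening-image generator (implanted masses with or
without spicules, calcification clusters, two views per breast, a film-like
platform intensity shift) makes every stage testable on a laptop without
any external data. The CNN engine itself (convolution, pooling, batch
norm, Adam, backprop) is a compact numpy implementation inside the package,
which is what lets the library walk layer chains for receptive-field
arithmetic, copy head weights into heatmap convolutions, freeze arbitrary
layer groups, and run guided backpropagation.

## Worked example

```python
import numpy as np
from mammofcn import data, evaluate, models, patches, synthetic, train

# 1. a seeded synthetic screening cohort (20 patients, 2 views each)
cfg = synthetic.SyntheticConfig.desk_scale(n_patients=20, seed=42)
cohort = synthetic.generate_cohort(cfg)
n_mal = sum(img.label == "malignant" for img, _ in cohort)
print(f"{len(cohort)} images, {n_mal} malignant")

# 2. S10 patches: 10 lesion patches (overlap >= 0.9) + 10 background per ROI
rng = np.random.default_rng(42)
scheme = patches.SamplingScheme.S10(patch_size=32)
records = []
for img, rois in cohort:
    if rois:
        records.extend(patches.sample_patches(img, rois, scheme, rng))
x, y = patches.to_arrays(records)
print(f"{len(records)} patches, class counts {np.bincount(y, minlength=5)}")

# 3. patch classifier -> whole-image classifier
patch_net = models.build_patch_classifier(
    models.tiny_backbone(32, widths=(8, 16)), seed=42)
rf, stride = models.receptive_field(patch_net)
print(f"patch trunk: receptive field {rf}, stride {stride}, "
      f"{models.count_parameters(patch_net):,} parameters")

mean_pixel = float(x.mean())
tc = train.TrainConfig(batch_size=32, mean_pixel=mean_pixel, seed=42)
train.train_patch(patch_net, (x, y), train.desk_scale_patch_schedule(), tc)

top = models.TopSpec(variant="conv_blocks_no_heatmap",
                     top_blocks=[models.BlockSpec("vgg", (16, 1),
                                                  batch_norm=True)] * 2)
whole = models.to_whole_image(patch_net, top, seed=42)
images, meta = data.cohort_to_arrays(cohort)
score = evaluate.augmented_predict(whole, images[0, 0], mean_pixel=mean_pixel)
print(f"malignancy score of image {meta.image_id[0]} (flip-averaged): {score:.3f}")

# 4. heatmap of the first malignant image
i = int(np.flatnonzero(meta.label.to_numpy())[0])
hm = models.heatmap_of(images[i, 0] - mean_pixel, patch_net,
                       activation="softmax")
print(f"heatmap grid {hm.grid.shape}, cells sum to {hm.grid.sum(axis=2).mean():.3f}")
```

Output:

```
40 images, 20 malignant
800 patches, class counts [400  80 120 120  80]
patch trunk: receptive field 10, stride 4, 1,381 parameters
malignancy score of image P0000_CC (flip-averaged): 0.683
heatmap grid (36, 28, 5), cells sum to 1.000
```

The cohort yields 800 patches (half background; per-batch sample weights
rebalance the five classes during training). The tiny two-block trunk sees
a 10-pixel receptive field at stride 4, so the 144 × 112 frame gives a
36 × 28 × 5 heatmap whose softmax cells each sum to one. The flip-averaged
malignancy score shown comes from the converted network *before* its
two-stage whole-image training (the top layers are freshly initialized
here), so it is near chance; the staged training that drives it to a
useful operating point is exercised in `tests/test_acceptance.py` and
available through the CLI:

```bash
mammofcn --seed 7 synthesize --out cohort/ --n-patients 50 --desk-scale
mammofcn --seed 7 sample-patches --cohort cohort/ --scheme S10 \
         --patch-size 32 --out patches.npz
mammofcn --seed 7 train-patch --patches patches.npz --out patch.npz --epochs 14
mammofcn --seed 7 convert --patch-weights patch.npz --out whole.npz
mammofcn --seed 7 train-image --weights whole.npz --cohort cohort/ \
         --epochs 20 --out trained.npz
mammofcn --seed 7 predict --weights trained.npz --cohort cohort/ --out pred.csv
mammofcn evaluate --predictions pred.csv
```

The canonical full-scale presets are available throughout: `VGG16` /
`Resnet50` backbones (their trunks count 15M / 24M parameters), 224- and
448-pixel sampling schemes, the 3-stage patch schedule (learning rates
10⁻³/10⁻⁴/10⁻⁵ over 50 epochs, top-layer scopes 46 for Resnet50 and 11 for
VGG16), the 2-stage whole-image schedule (30 + 20 epochs, weight decay
0.001 then 0.01), and transfer fine-tuning (10⁻⁵, 200 epochs).

## Layout

| module | role |
| --- | --- |
| `mammofcn.synthetic` | seeded synthetic screening cohorts, lesion implanting, platform intensity shifts |
| `mammofcn.patches` | S1 / S10 / S1g patch sampling, overlap ratios, augmentation, class balancing |
| `mammofcn.models` | block-grammar backbones, conversion to whole-image nets, receptive-field / parameter / sliding-window oracles |
| `mammofcn.train` | staged training with progressive unfreezing, transfer fine-tuning |
| `mammofcn.evaluate` | augmented prediction, ensembling, two-view averaging, AUC + bootstrap CIs, operating points |
| `mammofcn.saliency` | guided-backprop saliency maps and overlays |
| `mammofcn.baseline` | two-step heatmap → regional features → random-forest baseline |
| `mammofcn.data` | PNG/DICOM loading, manifests, BI-RADS mapping, patient-level stratified splits |
| `mammofcn.nn` | the numpy CNN engine |
| `mammofcn.cli` | `mammofcn` command-line verbs |

See `docs/methods.md` for the modeling choices and their rationale.
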
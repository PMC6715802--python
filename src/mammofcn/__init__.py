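"""mammofcn: whole-mammogram cancer classification by converting patch
classifiers into fully convolutional whole-image networks.

The workflow: train a 5-class patch classifier on ROI-annotated images,
convert it into an end-to-end trainable whole-image classifier by replacing
the classification head with convolutional top layers (optionally through a
class "heatmap"), fine-tune on image-level labels only, and evaluate with
flip-augmented prediction, model/view averaging and bootstrap confidence
intervals. A seeded synthetic screening-image generator makes every stage
testable without external data.
"""

from . import baseline, data, evaluate, models, nn, patches, saliency, synthetic, train

__all__ = ["baseline", "data", "evaluate", "models", "nn", "patches",
           "saliency", "synthetic", "train"]
__version__ = "0.1.0"
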
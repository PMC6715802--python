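"""Guided-backpropagation saliency maps.

The gradient of a chosen class score with respect to the input pixels is
computed while suppressing negative gradients at every ReLU on the backward
pass (only positive gradients flow through positive activations). The
positive part of the resulting gradient is min-max rescaled to [0, 1]; a
low cutoff (default 0.06) removes background noise in rendered overlays.
Used to verify qualitatively that whole-image decisions localize to
lesions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .models import NetworkHandle

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.06


@dataclass
class SaliencyMap:
    values: np.ndarray            # (r, s), rescaled to [0, 1]
    target_class: int
    cutoff: float = DEFAULT_CUTOFF

    def thresholded(self) -> np.ndarray:
        """Values with everything below the cutoff zeroed (the rendered
        overlay's content)."""
        out = self.values.copy()
        out[out < self.cutoff] = 0.0
        return out


def guided_saliency(handle: NetworkHandle, image: np.ndarray,
                    target_class: int, mean_pixel: float = 0.0,
                    cutoff: float = DEFAULT_CUTOFF) -> SaliencyMap:
    """Gradient of the target-class score w.r.t. the input under guided
    backpropagation, min-max rescaled over positive gradients to [0, 1]."""
    if not 0 <= target_class < handle.n_classes:
        raise ValueError(f"target class {target_class} out of range "
                         f"(0..{handle.n_classes - 1})")
    image = np.asarray(image, dtype=np.float32)
    x = image[None, None] - np.float32(mean_pixel)
    net = handle.net
    # forward through everything (caches activations), then backprop the
    # one-hot gradient from the pre-softmax class score
    net.forward(x, train=False)
    last = len(net.layers)
    if isinstance(net.layers[-1], nn.Softmax):
        last -= 1
    dout = np.zeros((1, handle.n_classes), dtype=np.float32)
    dout[0, target_class] = 1.0
    nn.GUIDED_BACKPROP[0] = True
    try:
        grad = net.backward(dout, start_after=last)
    finally:
        nn.GUIDED_BACKPROP[0] = False
    g = np.maximum(grad[0, 0], 0.0)
    lo, hi = float(g.min()), float(g.max())
    values = (g - lo) / (hi - lo) if hi > lo else np.zeros_like(g)
    return SaliencyMap(values=values.astype(np.float32),
                       target_class=target_class, cutoff=cutoff)


def saliency_overlaps_roi(smap: SaliencyMap, roi_mask: np.ndarray) -> bool:
    """Whether any above-cutoff saliency falls inside the ROI mask."""
    return bool((smap.thresholded() > 0)[np.asarray(roi_mask, dtype=bool)].any())


def render_overlay(image: np.ndarray, smap: SaliencyMap, path,
                   rois=None):
    """Best-effort PNG overlay: image in gray, above-cutoff saliency in red
    dots, ROI outlines in blue (malignant) / green (benign)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage import measure

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image, cmap="gray")
    sal = smap.thresholded()
    ys, xs = np.nonzero(sal)
    ax.scatter(xs, ys, s=1, c="red", alpha=0.5)
    for roi in rois or []:
        color = "blue" if roi.is_malignant else "green"
        for contour in measure.find_contours(roi.mask.astype(float), 0.5):
            ax.plot(contour[:, 1], contour[:, 0], color=color, lw=1)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
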
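"""Two-step heatmap baseline: binarize, extract regional features, classify.

The comparison pipeline that end-to-end training replaces: the softmax
heatmap of each foreground class is binarized at several probability
cutoffs (0.3, 0.5, 0.7, 0.9), regional features (area, major axis length,
mean intensity) are measured on the connected components of each binary
grid, and a random forest classifies the concatenated feature vectors into
malignant vs nonmalignant.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage import measure
from sklearn.ensemble import RandomForestClassifier

from .models import Heatmap

log = logging.getLogger(__name__)

CUTOFFS = (0.3, 0.5, 0.7, 0.9)
FOREGROUND_CLASSES = (1, 2, 3, 4)     # heatmap channels, 0 = background
FEATURES_PER_GROUP = 3
FEATURE_LENGTH = len(FOREGROUND_CLASSES) * len(CUTOFFS) * FEATURES_PER_GROUP

RF_DEFAULTS = {"trees": 500, "max_depth": 9, "min_samples_split": 300}


def binarize_heatmap(heatmap: Heatmap, class_index: int,
                     cutoff: float) -> np.ndarray:
    """Cells whose class probability reaches the cutoff."""
    if heatmap.activation_kind != "softmax":
        raise ValueError("binarization requires a softmax heatmap")
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly inside (0, 1)")
    return heatmap.grid[:, :, class_index] >= cutoff


def regional_features(binary_grid: np.ndarray, probability_grid: np.ndarray,
                      mode: str = "largest") -> tuple[float, float, float]:
    """(area, major_axis_length, mean_intensity) of the connected components
    (8-connectivity) of a binary grid.

    mode='largest' (default) reads the features off the largest-area
    component — screening images carry a single dominant lesion; mode='sum'
    instead sums areas, takes the max major axis, and averages intensity
    over the union. An empty grid yields (0, 0, 0).
    """
    binary_grid = np.asarray(binary_grid)
    probability_grid = np.asarray(probability_grid)
    if binary_grid.shape != probability_grid.shape:
        raise ValueError("binary and probability grids differ in shape")
    labeled = measure.label(binary_grid, connectivity=2)
    props = measure.regionprops(labeled, intensity_image=probability_grid)
    if not props:
        return (0.0, 0.0, 0.0)
    if mode == "largest":
        best = max(props, key=lambda p: p.area)
        return (float(best.area), float(best.axis_major_length),
                float(best.intensity_mean))
    if mode == "sum":
        area = float(sum(p.area for p in props))
        major = float(max(p.axis_major_length for p in props))
        mean_int = float(probability_grid[binary_grid.astype(bool)].mean())
        return (area, major, mean_int)
    raise ValueError(f"unknown mode {mode!r}")


def feature_vector(heatmap: Heatmap, mode: str = "largest") -> np.ndarray:
    """Fixed-order concatenation over (foreground class x cutoff) groups:
    4 classes x 4 cutoffs x 3 features = 48 values."""
    out = []
    for cls in FOREGROUND_CLASSES:
        for cut in CUTOFFS:
            binary = binarize_heatmap(heatmap, cls, cut)
            out.extend(regional_features(binary, heatmap.grid[:, :, cls],
                                         mode=mode))
    vec = np.asarray(out, dtype=np.float64)
    assert vec.shape == (FEATURE_LENGTH,)
    return vec


def fit_and_score_rf(features: np.ndarray, labels: np.ndarray,
                     trees: int = RF_DEFAULTS["trees"],
                     max_depth: int = RF_DEFAULTS["max_depth"],
                     min_samples_split: int = RF_DEFAULTS["min_samples_split"],
                     rng: int | np.random.Generator = 0,
                     test_features: np.ndarray | None = None):
    """Fit the random-forest image classifier on regional features and
    return (model, scores); scores are the malignant-class vote fraction on
    `test_features` when given, else on the training features."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("random forest fit needs both classes")
    seed = (int(rng.integers(2 ** 31)) if isinstance(rng, np.random.Generator)
            else int(rng))
    model = RandomForestClassifier(n_estimators=trees, max_depth=max_depth,
                                   min_samples_split=min_samples_split,
                                   random_state=seed)
    model.fit(features, labels)
    target = features if test_features is None else test_features
    scores = model.predict_proba(target)[:, list(model.classes_).index(1)]
    return model, scores
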
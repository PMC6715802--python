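"""Scoring and statistical evaluation of whole-image classifiers.

Provides flip-augmented prediction, ensemble and two-view score averaging,
ROC AUC (Mann-Whitney convention, ties credited 0.5), percentile bootstrap
confidence intervals for AUCs and paired AUC differences (image- or
breast-level resampling units), ROC operating points against a sensitivity
benchmark, and row-normalized confusion matrices for the 5-class patch
task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion

log = logging.getLogger(__name__)

PRED_COLUMNS = ["image_id", "patient_id", "breast_id", "view", "score", "label"]


class UndefinedAUCError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


def make_prediction_set(image_ids, patient_ids, breast_ids, views, scores,
                        labels) -> pd.DataFrame:
    df = pd.DataFrame({"image_id": image_ids, "patient_id": patient_ids,
                       "breast_id": breast_ids, "view": views,
                       "score": np.asarray(scores, dtype=float),
                       "label": np.asarray(labels, dtype=int)})
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    if df["image_id"].duplicated().any():
        raise ValueError("one row per image expected")
    return df


@dataclass
class BootstrapResult:
    point_estimate: float
    ci_low: float
    ci_high: float
    n_runs: int
    resampling_unit: str


# ---------------------------------------------------------------------------
# Prediction

def _flips(image: np.ndarray):
    yield image
    yield image[:, ::-1]
    yield image[::-1, :]
    yield image[::-1, ::-1]


def augmented_predict(handle, image: np.ndarray,
                      mean_pixel: float = 0.0) -> float:
    """Average malignancy score over the four flip variants of an image."""
    batch = np.stack([np.ascontiguousarray(v) for v in _flips(image)])[:, None]
    batch = batch.astype(np.float32) - np.float32(mean_pixel)
    probs = handle.net.forward(batch, train=False)
    return float(probs[:, 1].mean())


def predict_images(handle, images, meta: pd.DataFrame, mean_pixel: float = 0.0,
                   augmented: bool = True) -> pd.DataFrame:
    """Score a stack of images, returning a prediction set aligned with the
    metadata frame (image_id, patient_id, breast_id, view, label)."""
    scores = []
    for img in images:
        img2 = img[0] if img.ndim == 3 else img
        if augmented:
            scores.append(augmented_predict(handle, img2, mean_pixel))
        else:
            x = (img2[None, None].astype(np.float32) - np.float32(mean_pixel))
            scores.append(float(handle.net.forward(x, train=False)[0, 1]))
    return make_prediction_set(meta["image_id"], meta["patient_id"],
                               meta["breast_id"], meta["view"], scores,
                               meta["label"])


def average_scores(prediction_sets, group_by: str = "model") -> pd.DataFrame:
    """Combine scores by arithmetic mean.

    group_by='model': ensemble across aligned prediction sets (same images).
    group_by='view': average the CC and MLO scores of each breast; breasts
    with a single view are dropped (count logged).
    """
    if group_by == "model":
        sets = list(prediction_sets)
        base = sets[0].sort_values("image_id").reset_index(drop=True)
        scores = np.zeros(len(base))
        for ps in sets:
            ps = ps.sort_values("image_id").reset_index(drop=True)
            if not ps["image_id"].equals(base["image_id"]):
                raise AlignmentError("prediction sets cover different images")
            scores += ps["score"].to_numpy()
        out = base.copy()
        out["score"] = scores / len(sets)
        return out
    if group_by == "view":
        df = (pd.concat(prediction_sets, ignore_index=True)
              if isinstance(prediction_sets, (list, tuple))
              else prediction_sets.copy())
        rows = []
        dropped = 0
        for breast, grp in df.groupby("breast_id"):
            if set(grp["view"]) >= {"CC", "MLO"}:
                rows.append({"image_id": f"{breast}_2view",
                             "patient_id": grp["patient_id"].iloc[0],
                             "breast_id": breast, "view": "BOTH",
                             "score": float(grp["score"].mean()),
                             "label": int(grp["label"].max())})
            else:
                dropped += 1
        if dropped:
            log.info("two-view averaging dropped %d single-view breasts", dropped)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown group_by {group_by!r}")


# ---------------------------------------------------------------------------
# AUC

def roc_auc_values(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted 0.5, via the rank-sum identity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def roc_auc(pred: pd.DataFrame) -> float:
    return roc_auc_values(pred["score"].to_numpy(), pred["label"].to_numpy())


def _auc_rows(scores_matrix, labels_matrix):
    """Row-wise Mann-Whitney AUC for (B, n) resampled scores/labels; rows
    with a single class yield nan."""
    ranks = rankdata(scores_matrix, axis=1)
    pos = labels_matrix == 1
    n_pos = pos.sum(axis=1)
    n_neg = labels_matrix.shape[1] - n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = ((np.where(pos, ranks, 0).sum(axis=1) - n_pos * (n_pos + 1) / 2)
               / (n_pos * n_neg))
    auc[(n_pos == 0) | (n_neg == 0)] = np.nan
    return auc


def bootstrap_auc(pred_a: pd.DataFrame, pred_b: pd.DataFrame | None = None,
                  n_runs: int = 3000, unit: str = "image",
                  rng: np.random.Generator | int | None = None,
                  ) -> BootstrapResult:
    """Percentile bootstrap CI for an AUC, or for a paired AUC difference
    when `pred_b` is given (same images, resampled jointly).

    Resampling draws whole units (images or breasts) with replacement;
    degenerate resamples containing a single class are redrawn so n_runs is
    preserved.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a = pred_a.reset_index(drop=True)
    if pred_b is not None:
        b = pred_b.sort_values("image_id").reset_index(drop=True)
        a = a.sort_values("image_id").reset_index(drop=True)
        if not a["image_id"].equals(b["image_id"]):
            raise AlignmentError("paired bootstrap needs identical image sets")
    if unit == "image":
        units = [np.array([i]) for i in range(len(a))]
    elif unit == "breast":
        units = [grp.index.to_numpy() for _, grp in a.groupby("breast_id")]
    else:
        raise ValueError(f"unknown resampling unit {unit!r}")

    s_a = a["score"].to_numpy()
    lab = a["label"].to_numpy()
    s_b = b["score"].to_numpy() if pred_b is not None else None
    point = (roc_auc_values(s_a, lab) if pred_b is None
             else roc_auc_values(s_a, lab) - roc_auc_values(s_b, lab))

    fixed_size = all(len(u) == 1 for u in units)
    stats = np.empty(n_runs)
    if fixed_size and pred_b is None:
        # vectorized path: all units are single rows
        n = len(a)
        remaining = n_runs
        filled = 0
        while remaining > 0:
            idx = rng.integers(0, n, size=(remaining, n))
            auc = _auc_rows(s_a[idx], lab[idx])
            ok = ~np.isnan(auc)
            take = auc[ok]
            stats[filled:filled + len(take)] = take
            filled += len(take)
            redraws = remaining - len(take)
            if redraws:
                log.debug("redrawing %d degenerate bootstrap resamples", redraws)
            remaining = redraws
    else:
        n_units = len(units)
        for r in range(n_runs):
            while True:
                pick = rng.integers(0, n_units, size=n_units)
                idx = np.concatenate([units[k] for k in pick])
                if lab[idx].min() != lab[idx].max():
                    break
                log.debug("redrawing degenerate bootstrap resample")
            if pred_b is None:
                stats[r] = roc_auc_values(s_a[idx], lab[idx])
            else:
                stats[r] = (roc_auc_values(s_a[idx], lab[idx])
                            - roc_auc_values(s_b[idx], lab[idx]))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return BootstrapResult(point_estimate=float(point),
                           ci_low=float(min(lo, point)),
                           ci_high=float(max(hi, point)),
                           n_runs=n_runs, resampling_unit=unit)


# ---------------------------------------------------------------------------
# Operating points and confusion matrices

def sens_spec_at_benchmark(pred: pd.DataFrame, target_sensitivity: float
                           ) -> tuple[float, float, float]:
    """The ROC operating point with the smallest sensitivity >= target
    (ties broken toward higher specificity); returns (sensitivity,
    specificity, threshold)."""
    if target_sensitivity > 1.0:
        raise ValueError("target sensitivity cannot exceed 1")
    scores = pred["score"].to_numpy()
    labels = pred["label"].to_numpy()
    if labels.min() == labels.max():
        raise UndefinedAUCError("operating points need both classes")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    best = None
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    for t in thresholds:
        calls = scores >= t
        sens = (calls & (labels == 1)).sum() / n_pos
        spec = (~calls & (labels == 0)).sum() / n_neg
        if sens >= target_sensitivity:
            key = (sens, -spec)
            if best is None or key < best[0]:
                best = (key, (float(sens), float(spec), float(t)))
    if best is None:  # only possible if target > 1, already rejected
        raise ValueError("target sensitivity unreachable")
    return best[1]


def confusion_matrix_rownorm(predicted_classes, true_classes,
                             n_classes: int = 5) -> np.ndarray:
    """Row-normalized confusion matrix: row i is the distribution of
    predictions among true-class-i samples; empty rows stay all-zero."""
    pred = np.asarray(predicted_classes)
    true = np.asarray(true_classes)
    if pred.min() < 0 or pred.max() >= n_classes or \
            true.min() < 0 or true.max() >= n_classes:
        raise ValueError("labels out of range")
    counts = _sk_confusion(true, pred, labels=range(n_classes)).astype(float)
    sums = counts.sum(axis=1, keepdims=True)
    empty = sums[:, 0] == 0
    if empty.any():
        log.warning("confusion matrix has empty true-class rows: %s",
                    np.flatnonzero(empty).tolist())
    sums[sums == 0] = 1.0
    return counts / sums
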
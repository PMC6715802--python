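"""Shared fixtures: small synthetic cohorts for unit tests and one
session-scoped end-to-end training run (the desk-scale recovery experiment)
reused by the evaluation, saliency, baseline and acceptance suites."""

from __future__ import annotations

import numpy as np
import pytest

from mammofcn import baseline as bl
from mammofcn import (data, evaluate, models, nn, patches, saliency,
                      synthetic, train)

SEED = 20240
PATCH_SIZE = 32
TINY_WIDTHS = (8, 16)


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = synthetic.SyntheticConfig.desk_scale(n_patients=8, seed=3)
    return cfg, synthetic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def lesion_image(tiny_cohort):
    _, cohort = tiny_cohort
    return next((img, rois) for img, rois in cohort if rois)


def _patch_set(cohort, indices, scheme_name, seed):
    rng = np.random.default_rng(seed)
    sch = patches.SamplingScheme.by_name(scheme_name, PATCH_SIZE)
    recs = []
    for i in indices:
        img, rois = cohort[i]
        if rois:
            recs.extend(patches.sample_patches(img, rois, sch, rng))
    return patches.to_arrays(recs)


def _split_indices(meta, seed):
    man = data.split_patients(meta, (0.85, 0.15), seed=seed,
                              split_names=("train", "test"))
    tr = data.split_patients(man[man.split == "train"].drop(columns="split"),
                             (0.9, 0.1), seed=seed + 1,
                             split_names=("train", "val"))
    split = np.where(
        np.isin(meta.image_id, tr[tr.split == "train"].image_id), "train",
        np.where(np.isin(meta.image_id, tr[tr.split == "val"].image_id),
                 "val", "test"))
    return {s: np.flatnonzero(split == s) for s in ("train", "val", "test")}


def _train_whole_from_patches(cohort, images, meta, idx, scheme, mean_pixel,
                              seed):
    xtr, ytr = _patch_set(cohort, idx["train"], scheme, seed + 11)
    xva, yva = _patch_set(cohort, idx["val"], scheme, seed + 12)
    handle = models.build_patch_classifier(
        models.tiny_backbone(PATCH_SIZE, widths=TINY_WIDTHS), seed=seed)
    tc = train.TrainConfig(batch_size=32, mean_pixel=mean_pixel, seed=seed)
    _, patch_hist = train.train_patch(handle, (xtr, ytr),
                                      train.desk_scale_patch_schedule(), tc,
                                      val_set=(xva, yva))
    top = models.TopSpec(
        variant="conv_blocks_no_heatmap",
        top_blocks=[models.BlockSpec("vgg", (16, 1), batch_norm=True),
                    models.BlockSpec("vgg", (16, 1), batch_norm=True)])
    whole = models.to_whole_image(handle, top, seed=seed)
    wtc = train.TrainConfig(batch_size=2, mean_pixel=mean_pixel, seed=seed)
    labels = meta.label.to_numpy()
    _, whole_hist = train.train_whole(
        whole, (images[idx["train"]], labels[idx["train"]]),
        train.desk_scale_whole_schedule(), wtc,
        val_set=(images[idx["val"]], labels[idx["val"]]))
    pred = evaluate.predict_images(whole, images[idx["test"]],
                                   meta.iloc[idx["test"]],
                                   mean_pixel=mean_pixel)
    return {"patch": handle, "whole": whole, "patch_hist": patch_hist,
            "whole_hist": whole_hist, "pred": pred,
            "auc": evaluate.roc_auc(pred)}


@pytest.fixture(scope="session")
def pipeline():
    """The desk-scale synthetic recovery experiment: a 100-patient cohort,
    S10- and S1-trained classifiers, the two-step baseline, and transfer to
    a platform-shifted cohort. Heavy (minutes); computed once."""
    seed = SEED
    cfg = synthetic.SyntheticConfig.desk_scale(n_patients=100, seed=seed)
    cohort = synthetic.generate_cohort(cfg)
    images, meta = data.cohort_to_arrays(cohort)
    idx = _split_indices(meta, seed)
    mean_pixel = float(images[idx["train"]].mean())

    out = {"cohort": cohort, "images": images, "meta": meta, "idx": idx,
           "mean_pixel": mean_pixel, "seed": seed}
    for scheme in ("S10", "S1"):
        out[scheme] = _train_whole_from_patches(cohort, images, meta, idx,
                                                scheme, mean_pixel, seed)

    # two-step baseline on the S10 patch classifier's softmax heatmaps
    patch_handle = out["S10"]["patch"]
    labels = meta.label.to_numpy()
    fit_idx = np.concatenate([idx["train"], idx["val"]])

    def features(which):
        return np.stack([bl.feature_vector(models.heatmap_of(
            images[i, 0] - mean_pixel, patch_handle, activation="softmax"))
            for i in which])

    _, scores = bl.fit_and_score_rf(
        features(fit_idx), labels[fit_idx], min_samples_split=10, rng=seed,
        test_features=features(idx["test"]))
    out["baseline_auc"] = evaluate.roc_auc_values(scores, labels[idx["test"]])

    # transfer to the shifted platform: zero-shot vs fine-tuned
    ft_cohort = synthetic.generate_cohort(synthetic.SyntheticConfig.desk_scale(
        n_patients=30, seed=seed + 101, platform="B"))
    te_cohort = synthetic.generate_cohort(synthetic.SyntheticConfig.desk_scale(
        n_patients=25, seed=seed + 202, platform="B"))
    ft_im, ft_meta = data.cohort_to_arrays(ft_cohort)
    te_im, te_meta = data.cohort_to_arrays(te_cohort)
    whole = out["S10"]["whole"]
    pred0 = evaluate.predict_images(whole, te_im, te_meta,
                                    mean_pixel=mean_pixel)
    out["transfer_zero_shot_auc"] = evaluate.roc_auc(pred0)
    before = nn.snapshot_state(whole.net)
    ftc = train.TrainConfig(batch_size=2, mean_pixel=mean_pixel, seed=seed)
    train.finetune_transfer(whole, ft_im, ft_meta.label.to_numpy(),
                            ft_meta.patient_id.to_numpy(), 20, ftc,
                            learning_rate=1e-4, epochs=12, weight_decay=0.01)
    pred1 = evaluate.predict_images(whole, te_im, te_meta,
                                    mean_pixel=mean_pixel)
    out["transfer_finetuned_auc"] = evaluate.roc_auc(pred1)
    nn.restore_state(whole.net, before)  # keep the platform-A model intact

    # saliency localization on correctly classified malignant test images
    hits = total = 0
    pred = out["S10"]["pred"].set_index("image_id")
    for i in idx["test"]:
        if labels[i] != 1:
            continue
        if pred.loc[meta.image_id[i], "score"] <= 0.5:
            continue
        total += 1
        smap = saliency.guided_saliency(whole, images[i, 0], target_class=1,
                                        mean_pixel=mean_pixel)
        mal_mask = np.zeros(images[i, 0].shape, dtype=bool)
        for roi in cohort[i][1]:
            if roi.is_malignant:
                mal_mask |= roi.mask
        hits += saliency.saliency_overlaps_roi(smap, mal_mask)
    out["saliency_hits"] = hits
    out["saliency_total"] = total
    return out
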
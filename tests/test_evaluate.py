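"""Evaluation: AUC oracle, augmented prediction, score averaging, bootstrap
confidence intervals and operating points."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammofcn import evaluate, models, nn
from mammofcn.evaluate import (AlignmentError, UndefinedAUCError,
                               augmented_predict, average_scores,
                               bootstrap_auc, confusion_matrix_rownorm,
                               make_prediction_set, roc_auc, roc_auc_values,
                               sens_spec_at_benchmark)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def pred_frame(scores, labels, breasts=None, views=None):
    n = len(scores)
    return make_prediction_set(
        [f"im{i}" for i in range(n)], [f"p{i}" for i in range(n)],
        breasts or [f"b{i}" for i in range(n)],
        views or ["CC"] * n, scores, labels)


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        assert roc_auc(pred_frame([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])) == 1.0

    def test_hand_counted_pairs(self):
        # positives {0.9, 0.4}, negatives {0.3, 0.5}: 3 wins, 1 loss of 4
        assert roc_auc_values([0.9, 0.4, 0.3, 0.5],
                              [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert roc_auc_values([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc_values([0.1, 0.9], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1), st.integers(4, 1000))
    def test_matches_brute_force_pair_counting(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 17), n)  # force many ties
        labels = np.zeros(n, int)
        labels[: n // 2] = 1
        labels = labels[rng.permutation(n)]
        if labels.min() == labels.max():
            return
        assert roc_auc_values(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))


class TestAugmentedPredict:
    @pytest.fixture()
    def whole(self):
        handle = models.build_patch_classifier(
            models.tiny_backbone(16, widths=(6, 8)), seed=2)
        top = models.TopSpec(
            variant="conv_blocks_no_heatmap",
            top_blocks=[models.BlockSpec("vgg", (8, 1), batch_norm=True)])
        return models.to_whole_image(handle, top)

    def test_flip_symmetric_image_equals_plain_prediction(self, whole):
        quadrant = np.random.default_rng(0).random((24, 24)).astype(np.float32)
        sym = np.block([[quadrant, quadrant[:, ::-1]],
                        [quadrant[::-1, :], quadrant[::-1, ::-1]]])
        plain = float(whole.net.forward(sym[None, None], train=False)[0, 1])
        assert augmented_predict(whole, sym) == pytest.approx(plain, abs=1e-6)

    def test_equals_mean_of_four_explicit_scores(self, whole):
        img = np.random.default_rng(1).random((48, 40)).astype(np.float32)
        variants = [img, img[:, ::-1], img[::-1, :], img[::-1, ::-1]]
        scores = [float(whole.net.forward(
            np.ascontiguousarray(v)[None, None], train=False)[0, 1])
            for v in variants]
        assert augmented_predict(whole, img) == pytest.approx(
            np.mean(scores), abs=1e-7)


class TestAverageScores:
    def test_model_ensemble_mean(self):
        a = pred_frame([0.2, 0.4], [1, 0])
        b = pred_frame([0.8, 0.0], [1, 0])
        out = average_scores([a, b], group_by="model")
        assert np.allclose(out["score"], [0.5, 0.2])

    def test_ensemble_of_identical_models_is_idempotent(self):
        a = pred_frame([0.3, 0.7, 0.1], [0, 1, 0])
        out = average_scores([a, a, a, a], group_by="model")
        assert np.allclose(out["score"], a["score"])

    def test_mismatched_ids_rejected(self):
        a = pred_frame([0.2], [1])
        b = a.copy()
        b["image_id"] = ["other"]
        with pytest.raises(AlignmentError):
            average_scores([a, b], group_by="model")

    def test_single_view_breasts_dropped(self):
        df = make_prediction_set(
            ["i1", "i2", "i3"], ["p1", "p1", "p2"], ["b1", "b1", "b2"],
            ["CC", "MLO", "CC"], [0.2, 0.6, 0.9], [1, 1, 0])
        out = average_scores(df, group_by="view")
        assert list(out["breast_id"]) == ["b1"]
        assert out["score"].iloc[0] == pytest.approx(0.4)


class TestBootstrap:
    def test_paired_self_difference_ci_is_zero(self):
        pred = pred_frame([0.9, 0.2, 0.7, 0.4], [1, 0, 1, 0])
        res = bootstrap_auc(pred, pred_b=pred, n_runs=50, rng=0)
        assert res.point_estimate == 0.0
        assert res.ci_low == res.ci_high == 0.0

    def test_single_run_interval_collapses_to_that_resample(self):
        pred = pred_frame([0.9, 0.2, 0.7, 0.4], [1, 0, 1, 0])
        res = bootstrap_auc(pred, n_runs=1, rng=1)
        assert res.ci_low == res.ci_high
        assert res.n_runs == 1

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        pred = pred_frame(rng.random(60), rng.integers(0, 2, 60))
        for unit in ("image", "breast"):
            res = bootstrap_auc(pred, n_runs=200, unit=unit, rng=3)
            assert res.ci_low <= res.point_estimate <= res.ci_high
            assert res.resampling_unit == unit

    def test_breast_unit_resamples_views_together(self):
        df = make_prediction_set(
            [f"i{k}" for k in range(8)], [f"p{k // 2}" for k in range(8)],
            [f"b{k // 2}" for k in range(8)],
            ["CC", "MLO"] * 4, [0.9, 0.8, 0.7, 0.6, 0.2, 0.3, 0.4, 0.1],
            [1, 1, 1, 1, 0, 0, 0, 0])
        res = bootstrap_auc(df, n_runs=100, unit="breast", rng=4)
        assert 0.0 <= res.ci_low <= res.ci_high <= 1.0

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)

        def widths(n, reps=8):
            out = []
            for _ in range(reps):
                scores = np.concatenate([rng.normal(1, 1, n // 2),
                                         rng.normal(0, 1, n // 2)])
                scores = 1 / (1 + np.exp(-scores))
                labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
                res = bootstrap_auc(pred_frame(scores, labels), n_runs=300,
                                    rng=rng)
                out.append(res.ci_high - res.ci_low)
            return np.median(out)

        assert widths(400) < widths(100)


class TestOperatingPoint:
    def test_perfect_classifier_reaches_target_with_full_specificity(self):
        pred = pred_frame([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        sens, spec, _ = sens_spec_at_benchmark(pred, 0.86)
        assert sens == 1.0 and spec == 1.0

    def test_target_zero_gives_specificity_one(self):
        pred = pred_frame([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        sens, spec, thr = sens_spec_at_benchmark(pred, 0.0)
        assert sens == 0.0 and spec == 1.0
        assert thr > 0.9

    def test_matches_exhaustive_threshold_scan(self):
        scores = [0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95]
        labels = [0, 0, 1, 0, 1, 0, 1, 1, 0, 1]
        pred = pred_frame(scores, labels)
        target = 0.8
        best = None
        for t in np.linspace(-0.1, 1.1, 1000):
            calls = np.asarray(scores) >= t
            sens = (calls & (np.asarray(labels) == 1)).sum() / 5
            spec = (~calls & (np.asarray(labels) == 0)).sum() / 5
            if sens >= target and (best is None or (sens, -spec) < best):
                best = (sens, -spec)
        sens, spec, _ = sens_spec_at_benchmark(pred, target)
        assert (sens, -spec) == pytest.approx(best)

    def test_unreachable_target_rejected(self):
        pred = pred_frame([0.9, 0.1], [1, 0])
        with pytest.raises(ValueError):
            sens_spec_at_benchmark(pred, 1.5)


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self):
        y = np.array([0, 1, 2, 3, 4] * 3)
        assert np.array_equal(confusion_matrix_rownorm(y, y), np.eye(5))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 5, 100)
        pred = rng.integers(0, 5, 100)
        m = confusion_matrix_rownorm(pred, true)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_two_class_hand_count(self):
        true = [0, 0, 0, 0, 1, 1, 1, 1]
        pred = [0, 0, 0, 1, 1, 1, 1, 1]
        m = confusion_matrix_rownorm(pred, true, n_classes=2)
        assert np.allclose(m, [[0.75, 0.25], [0.0, 1.0]])

    def test_empty_class_row_stays_zero(self):
        m = confusion_matrix_rownorm([0, 1], [0, 1], n_classes=3)
        assert np.all(m[2] == 0)
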
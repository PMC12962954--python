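"""Metric formulas against brute-force tallies and independent oracles."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from bronchoseg.metrics import (ConfusionCounts, auprc, classification_metrics,
                                confusion_from_masks, format_percent,
                                macro_f1_from_pr, segmentation_metrics,
                                segmentation_metrics_from_confusion,
                                table_delta)

RNG = np.random.default_rng(0)


# ------------------------------------------------------------- classification
def test_reported_confusion_matrix_false_negative_rate():
    """TN=6, FP=4, FN=1, TP=62: one missed malignant of 63 -> 1.6%."""
    m = classification_metrics(ConfusionCounts(tp=62, fp=4, tn=6, fn=1))
    assert m["fnr"] == pytest.approx(1 / 63)
    assert format_percent(m["fnr"], 1) == "1.6"
    assert m["recall"] == pytest.approx(62 / 63)


def test_all_positive_predictions():
    m = classification_metrics(ConfusionCounts(tp=10, fp=0, tn=0, fn=0))
    assert m["accuracy"] == 1.0 and m["recall"] == 1.0 and m["fnr"] == 0.0


def test_uniform_confusion_gives_half_everywhere():
    m = classification_metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
    assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 0.5


def test_undefined_ratios_flagged_as_zero():
    m = classification_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
    assert m["precision"] == 0.0 and "precision" in m["undefined"]
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)


def test_macro_f1_from_tabulated_class_rows():
    """Per-class PR (0.983, 0.939) / (0.800, 0.889) -> ~90.2% macro-F1."""
    macro = macro_f1_from_pr(0.983, 0.939, 0.800, 0.889)
    assert 100 * macro == pytest.approx(90.2, abs=0.15)  # table rounding
    assert macro_f1_from_pr(1, 1, 1, 1) == 1.0
    assert macro_f1_from_pr(1, 1, 0, 0) == 0.5
    with pytest.raises(ValueError):
        macro_f1_from_pr(1.2, 0.5, 0.5, 0.5)


# ---------------------------------------------------------------------- AUPRC
def brute_force_auprc(scores, labels):
    """Exhaustive threshold enumeration: rectangles of the PR step curve."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    thresholds = sorted(set(scores), reverse=True)
    n_pos = labels.sum()
    area, prev_r = 0.0, 0.0
    for t in thresholds:
        kept = scores >= t
        tp = int((labels[kept] == 1).sum())
        r = tp / n_pos
        p = tp / kept.sum()
        area += (r - prev_r) * p
        prev_r = r
    return area


def test_perfect_ranking_gives_unit_area():
    assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)


def test_constant_scores_give_prevalence():
    labels = np.array([1, 0, 0, 1, 0])
    assert auprc(np.full(5, 0.3), labels) == pytest.approx(labels.mean())


def test_documented_four_item_example():
    scores = np.array([0.9, 0.8, 0.7, 0.6])
    labels = np.array([1, 0, 1, 0])
    assert auprc(scores, labels) == pytest.approx(
        brute_force_auprc(scores, labels), abs=1e-12)


@pytest.mark.parametrize("n", [5, 10, 20])
def test_auprc_matches_enumeration_and_sklearn(n):
    for trial in range(30):
        rng = np.random.default_rng(100 * n + trial)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.random(n), 2)  # rounded scores force ties
        got = auprc(scores, labels)
        assert got == pytest.approx(brute_force_auprc(scores, labels), abs=1e-12)
        assert got == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        auprc([0.1, 0.9], [1, 1])


# --------------------------------------------------------------- segmentation
def brute_force_confusion(pred, gt):
    p = np.zeros((2, 2), dtype=int)
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            true_cls = 0 if gt[i, j] == 1 else 1      # 0 = lesion
            pred_cls = 0 if pred[i, j] == 1 else 1
            p[true_cls, pred_cls] += 1
    return p


def test_perfect_prediction_scores_one_everywhere():
    gt = (RNG.random((6, 6)) > 0.6).astype(np.uint8)
    m = segmentation_metrics(gt.copy(), gt)
    for k in ("oAcc", "mAcc", "mIoU", "mDice", "mPrec", "mRecall"):
        assert m[k] == 1.0


def test_half_overlap_toy_hand_tally():
    """GT lesion = left half, prediction = top half of a 4x4 grid."""
    gt = np.zeros((4, 4), np.uint8)
    gt[:, :2] = 1
    pred = np.zeros((4, 4), np.uint8)
    pred[:2, :] = 1
    p = confusion_from_masks(pred, gt)
    assert np.array_equal(p, [[4, 4], [4, 4]])
    m = segmentation_metrics_from_confusion(p)
    assert m["mIoU"] == pytest.approx(1 / 3)    # 4/12 per class
    assert m["mDice"] == pytest.approx(0.5)     # 8/16 per class
    assert m["oAcc"] == pytest.approx(0.5)


def test_complement_prediction_zero_overall_accuracy():
    gt = np.zeros((4, 4), np.uint8)
    gt[:, :2] = 1
    m = segmentation_metrics(1 - gt, gt)
    assert m["oAcc"] == 0.0


def test_confusion_matches_brute_force_on_random_pairs():
    for trial in range(40):
        rng = np.random.default_rng(trial)
        gt = (rng.random((7, 5)) > 0.5).astype(np.uint8)
        pred = (rng.random((7, 5)) > 0.5).astype(np.uint8)
        assert np.array_equal(confusion_from_masks(pred, gt),
                              brute_force_confusion(pred, gt))


def test_dice_iou_identity_on_random_confusions():
    """Per class, D = 2J / (1 + J) when both come from the same counts."""
    for trial in range(50):
        rng = np.random.default_rng(trial)
        p = rng.integers(1, 50, (2, 2)).astype(float)
        row, col, diag = p.sum(1), p.sum(0), np.diag(p)
        iou = diag / (row + col - diag)
        dice = 2 * diag / (row + col)
        assert np.allclose(dice, 2 * iou / (1 + iou))
        m = segmentation_metrics_from_confusion(p)
        assert m["mIoU"] == pytest.approx(iou.mean())
        assert m["mDice"] == pytest.approx(dice.mean())


def test_relabeling_invariance_of_class_means():
    p = np.array([[9.0, 3.0], [2.0, 6.0]])
    swapped = p[::-1, ::-1]
    a = segmentation_metrics_from_confusion(p)
    b = segmentation_metrics_from_confusion(swapped)
    for k in ("oAcc", "mAcc", "mIoU", "mDice", "mPrec", "mRecall"):
        assert a[k] == pytest.approx(b[k])


def test_absent_class_skipped_and_flagged():
    gt = np.zeros((4, 4), np.uint8)          # no lesion in ground truth
    pred = np.zeros((4, 4), np.uint8)
    m = segmentation_metrics(pred, gt)
    assert m["oAcc"] == 1.0
    assert "mIoU" in m["undefined"]
    assert m["mIoU"] == 1.0                  # background-only mean


def test_per_image_vs_pooled_modes_differ_when_sizes_do():
    gts, preds = [], []
    for size, frac in ((4, 0.8), (8, 0.2)):
        rng = np.random.default_rng(size)
        gt = (rng.random((size, size)) < frac).astype(np.uint8)
        preds.append((rng.random((size, size)) < frac).astype(np.uint8))
        gts.append(gt)
    a = segmentation_metrics(preds, gts, mode="per_image")
    b = segmentation_metrics(preds, gts, mode="pooled")
    assert a["oAcc"] != pytest.approx(b["oAcc"])


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion_from_masks(np.zeros((3, 3)), np.zeros((4, 4)))


# -------------------------------------------------------------------- reports
def test_tabulated_metric_deltas():
    assert table_delta(56.74, 53.73) == pytest.approx(3.01)
    assert table_delta(42.93, 41.69) == pytest.approx(1.24)
    assert table_delta(7.5, 7.5) == 0.0


def test_percent_formatting():
    assert format_percent(0.9020, 1) == "90.2"
    assert format_percent(0.5674, 2) == "56.74"
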
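"""Metric identities: IoU, matching, Dice, per-run summaries, aggregation."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mammopart.detector import DetectionSet, Instance
from mammopart.errors import ValidationError
from mammopart.evaluate import (
    MatchResult,
    aggregate_runs,
    box_iou,
    dice_score,
    match_detections,
    summarize_run,
    MetricSummary,
)

# Per-run metric rows of the six-experiment comparison (three random-split
# runs, three case-wise runs), used to pin down the aggregation conventions.
RANDOM_TPR = [0.875, 0.933, 1.000]
RANDOM_FPPI = [1.47, 1.35, 1.09]
RANDOM_DICE = [0.885, 0.857, 0.874]
RANDOM_DICE_SD = [0.044, 0.118, 0.097]
CASE_TPR = [0.909, 0.909, 0.906]
CASE_FPPI = [0.77, 1.32, 1.33]
CASE_DICE = [0.891, 0.880, 0.897]
CASE_DICE_SD = [0.050, 0.061, 0.036]


def pixel_iou_oracle(a, b, grid=20):
    """Enumerate pixels of a small grid; the definition, computed the slow way."""
    in_a = {(r, c) for r in range(a[0], a[2]) for c in range(a[1], a[3])}
    in_b = {(r, c) for r in range(b[0], b[2]) for c in range(b[1], b[3])}
    return len(in_a & in_b) / len(in_a | in_b)


def det_set(boxes, scores=None, shape=(20, 20)):
    scores = scores or [1.0 - 0.01 * i for i in range(len(boxes))]
    instances = []
    for box, score in zip(boxes, scores):
        mask = np.zeros(shape, dtype=bool)
        mask[box[0] : box[2], box[1] : box[3]] = True
        instances.append(Instance(box=box, mask=mask, score=score))
    return DetectionSet("img", instances)


class TestBoxIoU:
    def test_identical_boxes(self):
        assert box_iou((0, 0, 5, 5), (0, 0, 5, 5)) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou((0, 0, 5, 5), (10, 10, 15, 15)) == 0.0

    def test_half_overlap_thirds(self):
        assert box_iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            box_iou((0, 0, 0, 5), (0, 0, 5, 5))

    def test_matches_pixel_enumeration_on_1000_random_pairs(self, rng):
        for _ in range(1000):
            r0, c0, r1, c1 = rng.integers(0, 10, 4)
            a = (r0, c0, r0 + r1 + 1, c0 + c1 + 1)
            r0, c0, r1, c1 = rng.integers(0, 10, 4)
            b = (r0, c0, r0 + r1 + 1, c0 + c1 + 1)
            assert box_iou(a, b) == pytest.approx(pixel_iou_oracle(a, b))


def max_matching_oracle(det_boxes, truth_boxes, thr):
    """Exhaustive maximum-cardinality matching over all assignments."""
    n_det, n_truth = len(det_boxes), len(truth_boxes)
    edges = {
        (i, j)
        for i in range(n_det)
        for j in range(n_truth)
        if box_iou(det_boxes[i], truth_boxes[j]) >= thr
    }
    best = 0
    k = min(n_det, n_truth)
    for dets in itertools.permutations(range(n_det), k):
        for truths in itertools.combinations(range(n_truth), k):
            matched = sum((d, t) in edges for d, t in zip(dets, truths))
            best = max(best, matched)
    return best


class TestMatching:
    def test_boundary_iou_exactly_threshold_is_tp(self):
        # boxes of area 3 overlapping in 1 px: IoU = 1/5 = threshold
        result = match_detections(det_set([(0, 0, 1, 3)]), [(0, 2, 1, 5)], 0.2)
        assert result.tp == 1 and result.fp == 0 and result.fn == 0

    def test_just_below_threshold_is_fp_and_fn(self):
        result = match_detections(det_set([(0, 0, 1, 3)]), [(0, 2, 1, 6)], 0.2)
        assert result.tp == 0 and result.fp == 1 and result.fn == 1

    def test_no_detection_one_truth(self):
        result = match_detections(det_set([]), [(0, 0, 4, 4)], 0.2)
        assert (result.tp, result.fp, result.fn) == (0, 0, 1)

    def test_greedy_never_exceeds_maximum_matching(self, rng):
        agree = 0
        trials = 500
        for _ in range(trials):
            n_det, n_truth = rng.integers(0, 5), rng.integers(0, 5)
            boxes = []
            for _ in range(n_det + n_truth):
                r0, c0 = rng.integers(0, 8, 2)
                boxes.append((int(r0), int(c0), int(r0 + rng.integers(1, 6)), int(c0 + rng.integers(1, 6))))
            det_boxes, truth_boxes = boxes[:n_det], boxes[n_det:]
            greedy = match_detections(det_set(det_boxes, shape=(16, 16)), truth_boxes, 0.2)
            best = max_matching_oracle(det_boxes, truth_boxes, 0.2)
            assert greedy.tp <= best
            agree += greedy.tp == best
            # count conservation on every trial
            assert greedy.tp + greedy.fn == n_truth
            assert greedy.tp + greedy.fp == n_det
        assert agree / trials >= 0.95

    def test_maximum_matching_mode_reaches_oracle(self, rng):
        for _ in range(100):
            n_det, n_truth = rng.integers(1, 5), rng.integers(1, 5)
            boxes = []
            for _ in range(n_det + n_truth):
                r0, c0 = rng.integers(0, 8, 2)
                boxes.append((int(r0), int(c0), int(r0 + rng.integers(1, 6)), int(c0 + rng.integers(1, 6))))
            det_boxes, truth_boxes = boxes[:n_det], boxes[n_det:]
            ours = match_detections(
                det_set(det_boxes, shape=(16, 16)), truth_boxes, 0.2, maximum_matching=True
            )
            assert ours.tp == max_matching_oracle(det_boxes, truth_boxes, 0.2)

    def test_raising_threshold_never_increases_tp(self, rng):
        for _ in range(50):
            det_boxes = [(0, 0, int(rng.integers(2, 10)), int(rng.integers(2, 10)))]
            truth_boxes = [(1, 1, int(rng.integers(2, 10)), int(rng.integers(2, 10)))]
            tps = [
                match_detections(det_set(det_boxes, shape=(16, 16)), truth_boxes, thr).tp
                for thr in (0.1, 0.3, 0.5, 0.7, 0.9)
            ]
            assert all(a >= b for a, b in zip(tps, tps[1:]))


class TestDice:
    def test_identical_masks(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:3, 1:3] = True
        assert dice_score(mask, mask) == 1.0

    def test_hand_counted_half(self):
        # pred 4 px, truth 4 px, overlap 2 px -> 2*2 / (2*2 + 2 + 2) = 0.5
        pred = np.zeros((4, 4), dtype=bool)
        truth = np.zeros((4, 4), dtype=bool)
        pred[0, 0:4] = True
        truth[0, 2:4] = True
        truth[1, 0:2] = True
        assert dice_score(pred, truth) == pytest.approx(0.5)

    def test_disjoint_masks(self):
        pred = np.zeros((4, 4), dtype=bool)
        truth = np.zeros((4, 4), dtype=bool)
        pred[0, 0] = True
        truth[3, 3] = True
        assert dice_score(pred, truth) == 0.0

    def test_both_empty_is_one_by_convention(self):
        empty = np.zeros((4, 4), dtype=bool)
        assert dice_score(empty, empty) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            dice_score(np.zeros((3, 3), dtype=bool), np.zeros((4, 4), dtype=bool))


class TestSummarize:
    def test_pooled_tpr(self):
        matches = [MatchResult(tp=9, fn=1)]
        summary = summarize_run(matches, [0.8])
        assert summary.tpr == pytest.approx(0.9)

    def test_fp_per_image_and_false_discovery(self):
        matches = [MatchResult(tp=0, fp=2) for _ in range(5)] + [
            MatchResult(tp=7, fp=3, fn=0)
        ] + [MatchResult() for _ in range(4)]
        dices = [None] * 5 + [0.9] + [None] * 4
        summary = summarize_run(matches, dices)
        assert summary.fp_per_image == pytest.approx(1.3)
        assert summary.false_discovery_fraction == pytest.approx(13 / 20)

    def test_zero_truth_testset_rejected(self):
        with pytest.raises(ValidationError, match="TPR undefined"):
            summarize_run([MatchResult(fp=3)], [None])

    def test_macro_tpr_averages_per_image(self):
        matches = [MatchResult(tp=1, fn=1), MatchResult(tp=1, fn=0)]
        micro = summarize_run(matches, [0.5, 0.5]).tpr
        macro = summarize_run(matches, [0.5, 0.5], macro_tpr=True).tpr
        assert micro == pytest.approx(2 / 3)
        assert macro == pytest.approx(0.75)


def rows(tprs, fppis, dices, dice_sds):
    return [
        MetricSummary(
            tpr=t, fp_per_image=f, false_discovery_fraction=0.0,
            dice_mean=d, dice_std=s, n_images=65,
        )
        for t, f, d, s in zip(tprs, fppis, dices, dice_sds)
    ]


class TestAggregateRuns:
    def test_random_scheme_rows_aggregate_to_printed_values(self):
        agg = aggregate_runs(rows(RANDOM_TPR, RANDOM_FPPI, RANDOM_DICE, RANDOM_DICE_SD))
        assert round(agg.tpr_mean, 3) == 0.936
        assert round(agg.tpr_std, 3) == 0.063
        assert round(agg.fppi_mean, 2) == 1.30
        assert round(agg.fppi_std, 2) == 0.19
        assert round(agg.dice_mean_mean, 3) == 0.872
        assert round(agg.dice_mean_std, 3) == 0.014
        assert round(agg.dice_std_mean, 3) == 0.086
        assert round(agg.dice_std_std, 3) == 0.038

    def test_case_scheme_rows_aggregate_to_printed_values(self):
        agg = aggregate_runs(rows(CASE_TPR, CASE_FPPI, CASE_DICE, CASE_DICE_SD))
        assert round(agg.tpr_mean, 3) == 0.908
        assert round(agg.tpr_std, 3) == 0.002
        assert round(agg.fppi_mean, 2) == 1.14
        assert round(agg.fppi_std, 2) == 0.32
        assert round(agg.dice_mean_mean, 3) == 0.889
        assert round(agg.dice_mean_std, 3) == 0.009

    def test_sample_sd_convention_discriminates_from_population_sd(self):
        """The cross-run SD uses the n-1 denominator: the population SD of
        the random-scheme TPRs would round to 0.051, not 0.063."""
        arr = np.array(RANDOM_TPR)
        assert round(float(arr.std(ddof=0)), 3) == 0.051
        assert round(float(arr.std(ddof=1)), 3) == 0.063

    def test_identical_summaries_have_zero_sd(self):
        agg = aggregate_runs(rows([0.9] * 3, [1.0] * 3, [0.8] * 3, [0.1] * 3))
        for value in (agg.tpr_std, agg.fppi_std, agg.dice_mean_std, agg.dice_std_std):
            assert value == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            aggregate_runs(rows([0.9], [1.0], [0.8], [0.1]))
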
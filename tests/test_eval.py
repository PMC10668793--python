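"""Precision, recall, matching and average-precision behavior."""

import numpy as np
import pytest

from shssd.evaluation import (EvalCounts, average_precision, evaluate_detections,
                              match_detections, pr_curve, precision, recall,
                              small_target_ap)
from shssd.head import BoxSet


def boxset(boxes, scores=None):
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.ones(len(boxes)) if scores is None else np.asarray(scores)
    return BoxSet(boxes, scores, np.zeros(len(boxes), dtype=np.int64))


class TestMatching:
    def test_perfect_detections(self):
        gts = np.array([[0, 0, 10, 10], [20, 20, 40, 40]], dtype=float)
        c = match_detections(boxset(gts, [0.9, 0.8]), gts, 0.5)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_duplicate_detection_one_tp_one_fp(self):
        gts = np.array([[0, 0, 10, 10]], dtype=float)
        c = match_detections(boxset([[0, 0, 10, 10], [1, 0, 11, 10]],
                                    [0.9, 0.8]), gts, 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_empty_detections(self):
        gts = np.array([[0, 0, 10, 10]], dtype=float)
        c = match_detections(boxset(np.zeros((0, 4))), gts, 0.5)
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_greedy_prefers_highest_iou_gt(self):
        gts = np.array([[0, 0, 10, 10], [0, 0, 20, 20]], dtype=float)
        c = match_detections(boxset([[0, 0, 19, 20]], [0.9]), gts, 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)


class TestPrecisionRecall:
    def test_formula_values(self):
        assert precision(EvalCounts(9, 1, 0)) == 90.0
        assert precision(EvalCounts(0, 0, 5)) == 0.0
        assert recall(EvalCounts(9, 0, 3)) == 75.0
        assert recall(EvalCounts(9, 2, 0)) == 100.0
        assert recall(EvalCounts(0, 0, 4)) == 0.0

    def test_counting_accuracy_rate(self):
        """518 exact of 530 trials is the published 97.74% accuracy rate."""
        assert round(100.0 * 518 / 530, 2) == 97.74
        assert round(precision(EvalCounts(518, 530 - 518, 0)), 2) == 97.74


class TestAveragePrecision:
    def test_unit_square(self):
        assert average_precision([0.5, 1.0], [1.0, 1.0]) == 100.0

    def test_step_curve(self):
        """P=1 up to R=0.5, then P=0.5: area 0.75."""
        assert abs(average_precision([0.5, 1.0], [1.0, 0.5]) - 75.0) < 1e-9

    def test_no_detections(self):
        assert average_precision([], []) == 0.0

    def test_101_point_close_to_exact(self, rng):
        """COCO 101-point sampling tracks the exact integral within the
        grid quantization."""
        for _ in range(20):
            n = int(rng.integers(2, 30))
            r = np.sort(rng.uniform(0, 1, n))
            p = rng.uniform(0, 1, n)
            exact = average_precision(r, p)
            coco = average_precision(r, p, n_points=101)
            assert abs(exact - coco) < 1.5

    def test_matches_rectangle_integration_oracle(self, rng):
        """Exact integrator vs independent right-Riemann summation of the
        interpolated curve at 1e-4 resolution."""
        for _ in range(20):
            n = int(rng.integers(2, 20))
            r = np.sort(rng.uniform(0, 1, n))
            p = rng.uniform(0, 1, n)
            got = average_precision(r, p)
            grid = np.arange(1e-4, r[-1] + 1e-12, 1e-4)
            interp = [max(p[j] for j in range(n) if r[j] >= g) for g in grid]
            ref = float(np.sum(np.array(interp) * 1e-4) * 100)
            assert abs(got - ref) < 0.1

    def test_adding_true_positive_never_decreases_ap(self, rng):
        gts = np.array([[0, 0, 10, 10], [50, 50, 60, 60], [100, 0, 110, 10]],
                       dtype=float)
        dets = boxset([[0, 0, 10, 10], [200, 200, 210, 210]], [0.8, 0.6])
        base = average_precision(*pr_curve([(dets, gts)], 0.5))
        more = boxset([[0, 0, 10, 10], [200, 200, 210, 210], [50, 50, 60, 60]],
                      [0.8, 0.6, 0.5])
        assert average_precision(*pr_curve([(more, gts)], 0.5)) >= base


def test_coco_json_round_trip(rng):
    from shssd.evaluation import from_coco_json, to_coco_json

    gts = np.array([[0, 0, 20, 30], [40, 40, 70, 90]], dtype=float)
    dets = boxset([[1, 1, 21, 29]], [0.8])
    per_image = [(dets, gts), (boxset(np.zeros((0, 4))), np.zeros((0, 4)))]
    back = from_coco_json(to_coco_json(per_image))
    assert len(back) == 2
    assert np.allclose(back[0][1], gts)
    assert np.allclose(back[0][0].boxes, dets.boxes)
    assert np.allclose(back[0][0].scores, dets.scores)
    assert len(back[1][0]) == 0 and len(back[1][1]) == 0


class TestCocoStyle:
    def test_ap_mean_over_ten_thresholds(self):
        gts = np.array([[0, 0, 40, 40]], dtype=float)
        dets = boxset([[2, 0, 40, 40]], [0.9])     # IoU = 38/40 = 0.95
        res = evaluate_detections([(dets, gts)])
        assert len(res.ap_per_iou) == 10
        assert list(res.ap_per_iou) == [0.5, 0.55, 0.6, 0.65, 0.7, 0.75,
                                        0.8, 0.85, 0.9, 0.95]
        assert abs(res.ap - np.mean(list(res.ap_per_iou.values()))) < 1e-9

    def test_small_target_stratum(self):
        big = np.array([[0, 0, 40, 40]], dtype=float)
        small = np.array([[100, 100, 116, 116]], dtype=float)
        gts = np.concatenate([big, small])
        dets = boxset(gts, [0.9, 0.8])
        # empty stratum -> NaN
        assert np.isnan(small_target_ap([(dets, big)]))
        # perfect detections of a 16x16 target -> 100
        assert small_target_ap([(boxset(small, [0.9]), small)]) == 100.0
        # mixed sizes == filter-then-evaluate
        direct = small_target_ap([(dets, gts)])
        filtered = np.mean([average_precision(*pr_curve([(dets, small)], t),
                                              n_points=101)
                            for t in np.round(np.arange(0.5, 1.0, 0.05), 2)])
        assert abs(direct - filtered) < 1e-9
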
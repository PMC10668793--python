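"""IoU, NMS, box coding, anchors and the decoupled head."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shssd.config import default_config
from shssd.head import (BoxSet, DCHead, build_anchors, decode_boxes,
                        decode_offsets, encode, iou, iou_matrix, nms)


def random_boxset(rng, n, span=100.0):
    x1 = rng.uniform(0, span, n)
    y1 = rng.uniform(0, span, n)
    w = rng.uniform(1, span / 2, n)
    h = rng.uniform(1, span / 2, n)
    boxes = np.stack([x1, y1, x1 + w, y1 + h], axis=1)
    return BoxSet(boxes, rng.uniform(0, 1, n), np.zeros(n, dtype=np.int64))


class TestIoU:
    def test_known_values(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
        assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0
        assert abs(iou((0, 0, 10, 10), (5, 0, 15, 10)) - 50 / 150) < 1e-12

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            a, b = random_boxset(rng, 2).boxes
            assert iou(a, b) == iou(b, a)
            assert 0.0 <= iou(a, b) <= 1.0
            assert iou(a, a) == 1.0


class TestNMS:
    def test_single_box_kept(self):
        d = BoxSet([[0, 0, 10, 10]], [0.7], [0])
        out = nms(d, 0.5)
        assert len(out) == 1 and np.allclose(out.boxes[0], [0, 0, 10, 10])

    def test_duplicate_suppressed(self):
        d = BoxSet([[0, 0, 10, 10], [0, 0, 10, 10]], [0.9, 0.8], [0, 0])
        out = nms(d, 0.5)
        assert len(out) == 1 and out.scores[0] == 0.9

    def test_disjoint_boxes_survive(self):
        d = BoxSet([[0, 0, 10, 10], [50, 50, 60, 60]], [0.9, 0.8], [0, 0])
        assert len(nms(d, 0.5)) == 2

    @pytest.mark.parametrize("thresh", [0.3, 0.5, 0.7])
    def test_matches_brute_force_reference(self, thresh, rng):
        """Greedy NMS against an O(M^2) literal transcription of the rule."""
        for _ in range(30):
            dets = random_boxset(rng, int(rng.integers(1, 50)))
            got = nms(dets, thresh)
            kept = []
            order = np.lexsort((np.arange(len(dets)), -dets.scores))
            for i in order:
                if all(iou(dets.boxes[i], dets.boxes[j]) <= thresh for j in kept):
                    kept.append(i)
            assert sorted(map(tuple, got.boxes.tolist())) == \
                sorted(map(tuple, dets.boxes[kept].tolist()))
            assert (np.diff(got.scores) <= 1e-12).all()   # sorted descending


class TestBoxCoding:
    def test_zero_offsets_decode_to_anchor(self):
        anchors = np.array([[50.0, 60.0, 32.0, 32.0]])
        box = decode_offsets(np.zeros((1, 4)), anchors)[0]
        assert np.allclose(box, [34, 44, 66, 76])

    def test_hand_computed_decode(self):
        """Offsets (0.1, 0.1, log 2, log 2) on a 32x32 anchor at (50, 60):
        center moves by 3.2 px, sides double."""
        anchors = np.array([[50.0, 60.0, 32.0, 32.0]])
        t = np.array([[0.1, 0.1, np.log(2), np.log(2)]])
        box = decode_offsets(t, anchors)[0]
        assert np.allclose(box, [53.2 - 32, 63.2 - 32, 53.2 + 32, 63.2 + 32])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_encode_decode_identity(self, seed):
        rng = np.random.default_rng(seed)
        anchors = np.stack([rng.uniform(10, 600, 5), rng.uniform(10, 600, 5),
                            rng.uniform(8, 128, 5), rng.uniform(8, 128, 5)], axis=1)
        b = random_boxset(rng, 5, span=500).boxes
        assert np.allclose(decode_offsets(encode(b, anchors), anchors), b,
                           atol=1e-5)


class TestAnchors:
    def test_grid_tiling_and_scales(self):
        aset = build_anchors(320, default_config())
        assert [len(a) for a in aset.per_level] == [40 * 40 * 3, 20 * 20 * 3,
                                                    10 * 10 * 3]
        lvl0 = aset.per_level[0].reshape(40, 40, 3, 4)
        assert np.allclose(lvl0[0, 0, 0], [4, 4, 32, 32])
        assert np.allclose(lvl0[0, 1, 0, 0], 12)            # next cell center
        assert np.allclose(lvl0[0, 0, 1, 2], 32 * 2 ** (1 / 3))

    def test_score_threshold_one_gives_empty_set(self):
        aset = build_anchors(320)
        cls = [np.zeros((3, 40, 40), np.float32), np.zeros((3, 20, 20), np.float32),
               np.zeros((3, 10, 10), np.float32)]
        reg = [np.zeros((12, 40, 40), np.float32), np.zeros((12, 20, 20), np.float32),
               np.zeros((12, 10, 10), np.float32)]
        assert len(decode_boxes(cls, reg, aset, score_thresh=1.0)) == 0


class TestDCHead:
    def test_channel_arithmetic(self, rng):
        head = DCHead(16, num_classes=1, anchors_per_cell=3,
                      rng=np.random.default_rng(0))
        c, r = head(rng.random((1, 16, 8, 8), dtype=np.float32))
        assert c.shape == (1, 3, 8, 8)
        assert r.shape == (1, 12, 8, 8)

    def test_branches_share_only_the_stem(self):
        head = DCHead(16, rng=np.random.default_rng(0))
        cls_params = {id(p) for p in head.cls_branch.parameters()} \
            | {id(p) for p in head.cls_pred.parameters()}
        reg_params = {id(p) for p in head.reg_branch.parameters()} \
            | {id(p) for p in head.reg_pred.parameters()}
        assert not (cls_params & reg_params)
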
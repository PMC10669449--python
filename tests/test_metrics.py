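"""Overlap metrics against brute-force pixel-set oracles."""

import itertools

import numpy as np
import pytest

from dafdnet.geometry import BBox
from dafdnet.metrics import (EvalRecord, box_iou, dice, evaluate_pair, jaccard,
                             summarize)


def pixel_set(box, width):
    """Bitmask of the pixels a half-open box covers on a width x width grid."""
    bits = 0
    for r in range(box[0], box[2]):
        for c in range(box[1], box[3]):
            bits |= 1 << (r * width + c)
    return bits


class TestBoxIOU:
    def test_identical_boxes(self):
        assert box_iou((1, 2, 5, 6), (1, 2, 5, 6)) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou((0, 0, 2, 2), (5, 5, 8, 8)) == 0.0

    def test_known_overlap(self):
        assert box_iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_empty_box_scores_zero(self):
        assert box_iou(BBox.empty(), (0, 0, 4, 4)) == 0.0

    def test_malformed_box_rejected(self):
        with pytest.raises(ValueError):
            box_iou((3, 0, 1, 4), (0, 0, 1, 1))

    def test_symmetry(self, rng):
        def rand_box():
            r = np.sort(rng.integers(0, 12, 2))
            c = np.sort(rng.integers(0, 12, 2))
            return (int(r[0]), int(c[0]), int(r[1]), int(c[1]))

        for _ in range(50):
            a, b = rand_box(), rand_box()
            assert box_iou(a, b) == box_iou(b, a)

    def test_exhaustive_against_pixel_counting(self):
        # every half-open box pair on a 6x6 grid, scored by bit-set counting
        width = 6
        spans = [(lo, hi) for lo in range(width + 1) for hi in range(lo, width + 1)]
        boxes = [(r0, c0, r1, c1) for (r0, r1) in spans for (c0, c1) in spans]
        masks = {b: pixel_set(b, width) for b in boxes}
        for a, b in itertools.product(boxes, repeat=2):
            inter = (masks[a] & masks[b]).bit_count()
            union = (masks[a] | masks[b]).bit_count()
            expected = inter / union if union else 0.0
            assert box_iou(a, b) == pytest.approx(expected, abs=1e-12)


class TestMaskMetrics:
    def test_identical_nonempty_masks(self, rng):
        m = rng.random((10, 10)) < 0.4
        m[0, 0] = True
        assert dice(m, m) == 1.0 and jaccard(m, m) == 1.0

    def test_known_counts(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True          # |A| = 4
        b[0, 2:4] = b[1, 0:2] = True  # |B| = 4, overlap 2
        assert dice(a, b) == pytest.approx(0.5)
        assert jaccard(a, b) == pytest.approx(1 / 3)

    def test_empty_mask_conventions(self):
        empty = np.zeros((5, 5), bool)
        full = ~empty
        assert dice(empty, empty) == 1.0 and jaccard(empty, empty) == 1.0
        assert dice(empty, full) == 0.0 and jaccard(full, empty) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_random_pairs_match_pixel_count_oracle(self, rng):
        for _ in range(100):
            a = rng.random((12, 12)) < rng.uniform(0.1, 0.9)
            b = rng.random((12, 12)) < rng.uniform(0.1, 0.9)
            inter = int((a & b).sum())
            na, nb = int(a.sum()), int(b.sum())
            if na + nb:
                assert dice(a, b) == pytest.approx(2 * inter / (na + nb), abs=1e-12)
                assert jaccard(a, b) == pytest.approx(inter / (na + nb - inter), abs=1e-12)
            d, j = dice(a, b), jaccard(a, b)
            # algebraic identity J = D / (2 - D)
            assert j == pytest.approx(d / (2 - d), abs=1e-12)
            assert 0.0 <= j <= d <= 1.0


class TestSummarize:
    def records(self, ious):
        return [EvalRecord(str(i), iou, min(1.0, iou * 1.2), iou, iou > 0)
                for i, iou in enumerate(ious)]

    def test_three_way_split(self):
        s = summarize(self.records([0.6, 0.3, 0.1]))
        assert s.pct_iou_high == pytest.approx(100 / 3)
        assert s.pct_iou_mid == pytest.approx(100 / 3)
        assert s.pct_iou_low == pytest.approx(100 / 3)
        assert s.mean_iou == pytest.approx(100 / 3, abs=0.1)

    def test_perfect_scores(self):
        s = summarize(self.records([1.0, 1.0]))
        assert (s.pct_iou_high, s.pct_iou_mid, s.pct_iou_low) == (100.0, 0.0, 0.0)
        assert s.mean_iou == 100.0

    def test_boundary_half_counts_as_high(self):
        s = summarize(self.records([0.5]))
        assert s.pct_iou_high == 100.0

    def test_bins_always_sum_to_hundred(self, rng):
        s = summarize(self.records(list(rng.random(37))))
        assert s.pct_iou_high + s.pct_iou_mid + s.pct_iou_low == pytest.approx(100.0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


def test_evaluate_pair_derives_boxes_from_masks():
    pred = np.zeros((10, 10), bool)
    label = np.zeros((10, 10), bool)
    pred[2:4, 2:4] = True
    label[2:4, 2:4] = True
    rec = evaluate_pair("img0", pred, label)
    assert rec.iou == 1.0 and rec.dice == 1.0 and rec.detected


def test_record_range_validation():
    with pytest.raises(ValueError):
        EvalRecord("x", iou=1.5, dice=0.5, jaccard=0.5, detected=True)
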
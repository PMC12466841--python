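"""Assignment, loss, decode and NMS contracts."""

import numpy as np
import pytest

from vetstar._core.tensor import Tensor
from vetstar.detection import (
    AssignmentResult,
    DetectionBox,
    assign_targets,
    ciou,
    decode,
    decode_boxes_t,
    detection_loss,
    encode_ltrb_onehot,
    grid_centers,
    iou_matrix,
    nms,
)
from vetstar.model import RawPrediction


def _uniform_preds(l, k=2, score=0.5):
    scores = np.full((1, l, k), score, dtype=np.float32)
    boxes = np.tile(np.array([[0.0, 0.0, 1.0, 1.0]], np.float32), (l, 1))[None]
    return scores, boxes


class TestAssignment:
    def test_single_gt_covering_grid_gets_topk_cells(self):
        centers = grid_centers(8, 8)
        scores, boxes = _uniform_preds(64)
        asg = assign_targets([np.array([[0, 0, 8, 8]], np.float32)], [np.array([0])],
                             scores, boxes, centers, topk=10)
        assert asg.fg_mask.sum() == 10

    def test_zero_gt_all_background(self):
        centers = grid_centers(4, 4)
        scores, boxes = _uniform_preds(16)
        asg = assign_targets([np.zeros((0, 4), np.float32)], [np.zeros(0, np.int64)],
                             scores, boxes, centers)
        assert not asg.fg_mask.any()
        assert (asg.gt_idx == -1).all()
        assert asg.target_scores.sum() == 0

    def test_disjoint_gts_have_disjoint_cells(self, rng):
        """Brute-force check on an 8×8 grid: cells assigned to either of two
        disjoint boxes never overlap, and each box gets at least one cell."""
        centers = grid_centers(8, 8)
        scores = rng.random((1, 64, 2)).astype(np.float32)
        boxes = np.tile(np.array([[0.0, 0.0, 8.0, 8.0]], np.float32), (64, 1))[None]
        gts = np.array([[0, 0, 3.5, 3.5], [4.5, 4.5, 8, 8]], np.float32)
        asg = assign_targets([gts], [np.array([0, 1])], scores, boxes, centers)
        cells_a = set(np.nonzero(asg.fg_mask[0] & (asg.gt_idx[0] == 0))[0])
        cells_b = set(np.nonzero(asg.fg_mask[0] & (asg.gt_idx[0] == 1))[0])
        assert cells_a and cells_b and not (cells_a & cells_b)
        inside_a = {i for i in range(64)
                    if 0 < centers[i, 0] < 3.5 and 0 < centers[i, 1] < 3.5}
        assert cells_a <= inside_a

    def test_tiny_box_falls_back_to_nearest_cell(self):
        centers = grid_centers(4, 4)
        scores, boxes = _uniform_preds(16)
        gts = np.array([[1.9, 1.9, 2.1, 2.1]], np.float32)  # contains no center
        asg = assign_targets([gts], [np.array([1])], scores, boxes, centers)
        assert asg.fg_mask.sum() >= 1

    def test_assigned_cell_centers_inside_gt(self, rng):
        centers = grid_centers(8, 8)
        scores = rng.random((1, 64, 2)).astype(np.float32)
        boxes = np.tile(np.array([[0.0, 0.0, 8.0, 8.0]], np.float32), (64, 1))[None]
        gts = np.array([[1, 2, 6, 7]], np.float32)
        asg = assign_targets([gts], [np.array([0])], scores, boxes, centers)
        for i in np.nonzero(asg.fg_mask[0])[0]:
            assert gts[0, 0] < centers[i, 0] < gts[0, 2]
            assert gts[0, 1] < centers[i, 1] < gts[0, 3]


class TestLoss:
    def _assignment_for(self, gt, hg=4, wg=4, k=2):
        centers = grid_centers(hg, wg)
        scores, boxes = _uniform_preds(hg * wg, k)
        return assign_targets([gt], [np.array([0] * len(gt))], scores, boxes, centers), centers

    def test_perfect_predictions_zero_box_and_dfl(self):
        # edges at x.5 so every cell's l/t/r/b distance is a whole bin
        gt = np.array([[0.5, 0.5, 3.5, 3.5]], np.float32)
        asg, centers = self._assignment_for(gt)
        # build logits that decode exactly to the gt box at every assigned cell
        ltrb = np.stack([
            centers[:, 0] - gt[0, 0], centers[:, 1] - gt[0, 1],
            gt[0, 2] - centers[:, 0], gt[0, 3] - centers[:, 1]
        ], axis=1)
        box_logits = encode_ltrb_onehot(ltrb, 16).reshape(1, 4, 4, 64).transpose(0, 3, 1, 2)
        cls_logits = np.where(asg.target_scores.reshape(1, 4, 4, 2) > 0, 12.0, -12.0)
        cls_logits = cls_logits.transpose(0, 3, 1, 2).astype(np.float32)
        lb = detection_loss(Tensor(cls_logits), Tensor(box_logits.astype(np.float32)),
                            asg, centers)
        # offsets here are integers, so the one-hot decode is exact
        assert lb.components["box"] == pytest.approx(0.0, abs=1e-3)
        assert lb.components["dfl"] == pytest.approx(0.0, abs=1e-3)

    def test_loss_finite_positive_at_random_init(self, rng):
        gt = np.array([[0.5, 0.5, 3.0, 3.0]], np.float32)
        asg, centers = self._assignment_for(gt)
        cls = Tensor(rng.standard_normal((1, 2, 4, 4)).astype(np.float32))
        box = Tensor(rng.standard_normal((1, 64, 4, 4)).astype(np.float32))
        lb = detection_loss(cls, box, asg, centers)
        assert np.isfinite(lb.total.data) and lb.total.data > 0

    def test_zero_gt_pure_background_cls(self, rng):
        centers = grid_centers(4, 4)
        scores, boxes = _uniform_preds(16)
        asg = assign_targets([np.zeros((0, 4), np.float32)], [np.zeros(0, np.int64)],
                             scores, boxes, centers)
        cls = Tensor(rng.standard_normal((1, 2, 4, 4)).astype(np.float32))
        box = Tensor(rng.standard_normal((1, 64, 4, 4)).astype(np.float32))
        lb = detection_loss(cls, box, asg, centers)
        assert lb.components["box"] == 0 and lb.components["dfl"] == 0
        assert lb.components["cls"] > 0

    def test_ciou_identical_boxes_is_one(self):
        b = np.array([[1.0, 1.0, 3.0, 4.0], [0.0, 0.0, 2.0, 2.0]], np.float32)
        out = ciou(Tensor(b), b)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-5)


class TestDecode:
    def _raw(self, cls, box):
        return RawPrediction(cls_logits=cls, box_logits=box, stride=16)

    def test_all_low_logits_decode_empty(self):
        raw = self._raw(np.full((4, 4, 2), -10.0, np.float32),
                        np.zeros((4, 4, 64), np.float32))
        assert decode(raw, conf_thr=0.5) == []

    def test_onehot_dfl_decodes_to_bin_times_stride(self):
        hg = wg = 2
        ltrb = np.full((hg * wg, 4), 3.0)
        box = encode_ltrb_onehot(ltrb, 16).reshape(hg, wg, 64).astype(np.float32)
        cls = np.full((hg, wg, 2), -20.0, np.float32)
        cls[0, 0, 1] = 8.0
        dets = decode(self._raw(cls, box), conf_thr=0.5, nms_iou=0.7)
        assert len(dets) == 1
        d = dets[0]
        # cell (0,0) center (0.5, 0.5); offsets 3 bins → ±3 stride units
        assert d.class_id == 1
        np.testing.assert_allclose(d.xyxy, [(0.5 - 3) * 16, (0.5 - 3) * 16,
                                            (0.5 + 3) * 16, (0.5 + 3) * 16], atol=1e-3)

    def test_decode_encode_roundtrip_within_half_stride(self, rng):
        """Encoding a box to one-hot DFL targets and decoding recovers it to
        within half a stride."""
        hg = wg = 8
        centers = grid_centers(hg, wg)
        gt = np.array([17.0, 33.0, 100.0, 90.0])  # pixels
        ltrb_units = np.stack([
            centers[:, 0] - gt[0] / 16, centers[:, 1] - gt[1] / 16,
            gt[2] / 16 - centers[:, 0], gt[3] / 16 - centers[:, 1],
        ], axis=1)
        box = encode_ltrb_onehot(np.clip(ltrb_units, 0, 15), 16).reshape(hg, wg, 64)
        cls = np.full((hg, wg, 2), -20.0, np.float32)
        cls[3, 3, 0] = 6.0  # a cell whose center is inside the box
        dets = decode(self._raw(cls, box.astype(np.float32)), conf_thr=0.5)
        assert len(dets) == 1
        np.testing.assert_allclose(dets[0].xyxy, gt, atol=8.0 + 1e-6)  # 0.5·stride

    def test_differentiable_decode_matches_inference_decode(self, rng):
        box_logits = rng.standard_normal((1, 64, 4, 4)).astype(np.float32)
        centers = grid_centers(4, 4)
        t_boxes = decode_boxes_t(Tensor(box_logits), centers, 16).data[0] * 16
        raw = self._raw(np.full((4, 4, 2), 8.0, np.float32),
                        np.moveaxis(box_logits[0], 0, -1))
        dets = decode(raw, conf_thr=0.5, nms_iou=1.01)  # keep all
        decoded = {tuple(round(float(v), 2) for v in d.xyxy) for d in dets}
        expected = {tuple(round(float(v), 2) for v in b) for b in t_boxes
                    if b[0] < b[2] and b[1] < b[3]}
        assert decoded == expected


class TestNMS:
    def test_identical_boxes_keep_highest(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], float)
        keep = nms(boxes, np.array([0.8, 0.9]), iou_thr=0.7)
        assert keep == [1]

    def test_idempotent(self, rng):
        boxes = rng.random((20, 2)) * 50
        boxes = np.concatenate([boxes, boxes + 5 + rng.random((20, 2)) * 20], axis=1)
        scores = rng.random(20)
        keep1 = nms(boxes, scores, 0.5)
        keep2_rel = nms(boxes[keep1], scores[keep1], 0.5)
        assert [keep1[i] for i in keep2_rel] == keep1

    def test_disjoint_boxes_all_kept(self):
        boxes = np.array([[0, 0, 5, 5], [10, 10, 15, 15], [20, 20, 25, 25]], float)
        keep = nms(boxes, np.array([0.5, 0.9, 0.7]), 0.5)
        assert sorted(keep) == [0, 1, 2]


def test_detection_box_validation():
    with pytest.raises(ValueError):
        DetectionBox(5, 0, 4, 10, 0, 0.5)
    with pytest.raises(ValueError):
        DetectionBox(0, 0, 4, 10, 0, float("nan"))


def test_iou_matrix_degenerate_boxes_zero():
    a = np.array([[0, 0, 0, 0]], float)
    b = np.array([[0, 0, 5, 5]], float)
    assert iou_matrix(a, b)[0, 0] == 0
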
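"""BCKD distillation math and training contracts."""

import numpy as np
import pytest

from vetstar._core.tensor import Tensor
from vetstar.distill import (
    DistillConfig,
    cls_distill_loss,
    distill_train,
    iou_pairs,
    loc_distill_loss,
    sigmoid_protocol,
    total_distill_loss,
    total_loss,
)
from vetstar.model import build_teacher, build_vetstar


class TestSigmoidProtocol:
    def test_worked_example_teacher(self):
        """Per-class sigmoid keeps the confidence gap the softmax protocol
        erases: teacher logits [1, 3, 6] map to [0.73, 0.95, 1.00]."""
        np.testing.assert_allclose(
            np.round(sigmoid_protocol([1.0, 3.0, 6.0]), 2), [0.73, 0.95, 1.00])

    def test_worked_example_student(self):
        np.testing.assert_allclose(
            np.round(sigmoid_protocol([1.0, 2.0, 4.0]), 2), [0.73, 0.88, 0.98])

    def test_zero_logit_is_half(self):
        assert sigmoid_protocol(0.0) == pytest.approx(0.5)

    def test_no_summation_constraint(self):
        s = sigmoid_protocol([3.0, 3.0, 3.0])
        assert s.sum() > 1.0  # unlike softmax


class TestClsDistill:
    def test_identical_scores_zero_loss(self):
        s = np.array([[0.2, 0.7], [0.9, 0.1]])
        assert cls_distill_loss(s, s).data == 0.0

    def test_hand_evaluated_single_element(self):
        # teacher 0.9, student 0.5: β = 0.4, BCE = −(0.1·log0.5 + 0.9·log0.5)
        loss = cls_distill_loss(np.array([[0.5]]), np.array([[0.9]]))
        assert loss.data == pytest.approx(0.4 * 0.6931, abs=1e-4)

    def test_permutation_invariance(self, rng):
        s = rng.random((6, 2)).astype(np.float32)
        t = rng.random((6, 2)).astype(np.float32)
        perm = rng.permutation(6)
        a = cls_distill_loss(s, t).data
        b = cls_distill_loss(s[perm], t[perm]).data
        assert a == pytest.approx(b, rel=1e-6)

    def test_beta_monotonicity(self):
        """For a fixed teacher score the weighted BCE grows with |s_t′ − s_s′|."""
        t = np.array([[0.9]])
        losses = [cls_distill_loss(np.array([[s]]), t).data
                  for s in (0.9, 0.7, 0.5, 0.3, 0.1)]
        assert all(a < b for a, b in zip(losses, losses[1:]))

    def test_extreme_scores_clamped(self):
        loss = cls_distill_loss(np.array([[0.0]]), np.array([[1.0]]))
        assert np.isfinite(loss.data)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cls_distill_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestLocDistill:
    def test_identical_boxes_zero(self):
        b = np.array([[0, 0, 4, 4], [2, 2, 8, 9]], np.float32)
        assert loc_distill_loss(b, b, np.array([[0.5, 0.2], [0.1, 0.9]])).data == \
            pytest.approx(0.0, abs=1e-6)

    def test_direct_evaluation_half_iou(self):
        # one position, β row [0.2, 0.5], IoU 0.5 → 0.5 · 0.5 = 0.25
        s = np.array([[0.0, 0.0, 1.0, 1.0]], np.float32)
        t = np.array([[0.0, 0.0, 1.0, 2.0]], np.float32)  # IoU = 0.5
        loss = loc_distill_loss(s, t, np.array([[0.2, 0.5]]))
        assert loss.data == pytest.approx(0.25, abs=1e-6)

    def test_disjoint_boxes_contribute_max_beta(self):
        s = np.array([[0, 0, 1, 1]], np.float32)
        t = np.array([[5, 5, 6, 6]], np.float32)
        loss = loc_distill_loss(s, t, np.array([[0.3, 0.7]]))
        assert loss.data == pytest.approx(0.7)

    def test_degenerate_boxes_get_iou_zero(self):
        s = np.array([[2, 2, 2, 2]], np.float32)  # zero area
        t = np.array([[0, 0, 4, 4]], np.float32)
        assert iou_pairs(Tensor(s), t).data[0] == 0.0


class TestTotals:
    def test_ratio_15_to_1(self):
        # cls = loc = 1 with the 15:1 weighting → 16 (unnormalised)
        assert total_distill_loss(1.0, 1.0) == pytest.approx(16.0)

    def test_loc_zero_leaves_cls_weight(self):
        assert total_distill_loss(2.0, 0.0) == pytest.approx(2.0)

    def test_zero_both(self):
        assert total_distill_loss(0.0, 0.0) == 0.0

    def test_total_loss_lambda(self):
        assert total_loss(2.0, 1.0, 1.3) == pytest.approx(3.6)
        assert total_loss(5.0, 1.0, 0.0) == 1.0
        assert total_loss(2.0, 1.0, 1.5) > total_loss(2.0, 1.0, 1.3)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DistillConfig(alpha_loc=-1)


class TestProtocolContrast:
    @staticmethod
    def _softmax(x):
        e = np.exp(x - x.max())
        return e / e.sum()

    def test_softmax_stalls_on_shifted_logits_sigmoid_does_not(self):
        """The protocol inconsistency: softmax is shift-invariant, so a
        student whose logits are the teacher's minus a constant produces
        exactly zero softmax-KL — learning stalls — while the sigmoid
        protocol still sees the absolute confidence gap and keeps a positive
        loss."""
        t_log = np.array([1.0, 3.0, 6.0])
        s_log = t_log - 2.0
        pt, ps = self._softmax(t_log), self._softmax(s_log)
        kl = float(np.sum(pt * np.log(pt / ps)))
        assert kl == pytest.approx(0.0, abs=1e-12)
        sig_loss = float(cls_distill_loss(
            sigmoid_protocol(s_log)[None], sigmoid_protocol(t_log)[None]).data)
        assert sig_loss > 0.01

    def test_worked_pair_confidence_gap_survives_sigmoid_not_softmax(self):
        """On the printed teacher/student pair the softmax outputs nearly
        coincide on the dominant class while the sigmoid scores keep a
        visible gap on the non-background classes."""
        t_log = np.array([1.0, 3.0, 6.0])
        s_log = np.array([1.0, 2.0, 4.0])
        pt, ps = self._softmax(t_log), self._softmax(s_log)
        assert abs(pt[2] - ps[2]) < 0.11  # both ≈ 1 for the top class
        sig_gap = sigmoid_protocol(t_log) - sigmoid_protocol(s_log)
        assert sig_gap[1] > 0.05 and sig_gap[2] > 0.015
        # and the sigmoid-protocol loss is positive: no stalling
        assert float(cls_distill_loss(sigmoid_protocol(s_log)[None],
                                      sigmoid_protocol(t_log)[None]).data) > 0.01


@pytest.fixture()
def tiny(bench):
    _, tr, va, _, _ = bench
    return tr, va


class TestDistillTraining:

    def test_student_copy_of_teacher_has_zero_distill_loss(self, tiny):
        """Zero-loss identity: identical logits and identical decoded boxes
        give exactly zero classification and localization distillation."""
        from vetstar.detection import decode_boxes_t, grid_centers

        tr, _ = tiny
        student = build_vetstar(seed=5).eval()
        teacher = build_vetstar(seed=5).eval()  # same init → same outputs
        imgs = np.stack(tr.images[:2])
        raw_s = student.predict_raw(imgs)
        raw_t = teacher.predict_raw(imgs)
        s_scores = sigmoid_protocol(raw_s.cls_logits.reshape(-1, 2))
        t_scores = sigmoid_protocol(raw_t.cls_logits.reshape(-1, 2))
        assert cls_distill_loss(s_scores, t_scores).data == 0.0
        centers = grid_centers(16, 16)
        sb = decode_boxes_t(
            Tensor(np.moveaxis(raw_s.box_logits, -1, 1).reshape(2, 64, 16, 16)),
            centers, 16).data.reshape(-1, 4)
        tb = decode_boxes_t(
            Tensor(np.moveaxis(raw_t.box_logits, -1, 1).reshape(2, 64, 16, 16)),
            centers, 16).data.reshape(-1, 4)
        beta = np.abs(t_scores - s_scores)
        assert loc_distill_loss(sb, tb, beta).data == pytest.approx(0.0, abs=1e-6)

    def test_teacher_frozen_and_gradients_flow_to_student(self, tiny):
        from vetstar.benchmark import small_train_config

        tr, _ = tiny
        student = build_vetstar(seed=6)
        teacher = build_vetstar(seed=7)
        teacher_state = {k: v.copy() for k, v in teacher.state_dict().items()}
        student_state = {k: v.copy() for k, v in student.state_dict().items()}
        cfg = small_train_config(seed=6, max_epochs=1)
        distill_train(student, teacher, tr, None, cfg)
        for k, v in teacher.state_dict().items():
            np.testing.assert_array_equal(v, teacher_state[k])
        changed = any(
            not np.array_equal(v, student_state[k])
            for k, v in student.state_dict().items()
        )
        assert changed

    def test_lambda_sweep_logs_one_entry_per_value(self, tiny):
        from vetstar.benchmark import small_train_config

        tr, va = tiny
        entries = {}
        for lam in (1.0, 1.3):
            r = distill_train(build_vetstar(seed=0), build_vetstar(seed=9), tr, va,
                              small_train_config(seed=0, max_epochs=1),
                              DistillConfig(lam=lam))
            entries[lam] = r["best_map50"]
        assert set(entries) == {1.0, 1.3}
        assert all(np.isfinite(v) for v in entries.values())

    def test_protocol_mismatch_rejected(self, tiny):
        from vetstar.benchmark import small_train_config
        from vetstar.model import ChannelPlan

        tr, _ = tiny
        student = build_vetstar(seed=0)
        teacher = build_vetstar(plan=ChannelPlan(reg_max=8,
                                                 stage_widths=(12, 24, 32, 32)), seed=0)
        with pytest.raises(ValueError):
            distill_train(student, teacher, tr, None,
                          small_train_config(max_epochs=1))
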
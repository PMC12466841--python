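"""BCKD: logit distillation with a sigmoid protocol.

Softmax matching normalises class scores to sum to one, so a student whose
logits are a scaled copy of the teacher's produces near-zero distillation
loss and stops learning the absolute confidence gaps that distinguish faint
test-card lines.  BCKD instead maps every class logit through an independent
sigmoid, treats the N×K score map as N·K binary tasks, and matches them with
binary cross-entropy weighted by the teacher–student score gap
β = |s_t′ − s_s′|.  Localization is distilled through the IoU between the
teacher's and student's decoded boxes at the same grid position, weighted by
the strongest class gap at that position.

The combined objective is
``L = λ·(α_loc·L_loc + α_cls·L_cls) + L_gt``  with the localization:
classification ratio fixed at 15:1 and λ defaulting to 1.3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._core.tensor import Tensor, no_grad
from .detection import decode_boxes_t
from .model import VetStar
from .train import TrainConfig, YoloDataset, train

__all__ = [
    "DistillConfig",
    "sigmoid_protocol",
    "cls_distill_loss",
    "loc_distill_loss",
    "total_distill_loss",
    "total_loss",
    "iou_pairs",
    "distill_train",
]

_EPS = 1e-7


@dataclass(frozen=True)
class DistillConfig:
    """Weights of the distillation objective (localization:classification 15:1)."""

    alpha_loc: float = 15.0
    alpha_cls: float = 1.0
    lam: float = 1.3
    teacher_checkpoint: str | None = None

    def __post_init__(self):
        if self.alpha_loc <= 0 or self.alpha_cls <= 0 or self.lam < 0:
            raise ValueError("weights must be positive (lam >= 0)")


def sigmoid_protocol(logits):
    """Independent per-class sigmoid scores; no cross-class normalisation."""
    if isinstance(logits, Tensor):
        return logits.sigmoid()
    return 1.0 / (1.0 + np.exp(-np.asarray(logits, dtype=np.float64)))


def cls_distill_loss(s_student, s_teacher) -> Tensor:
    """Σᵢⱼ βᵢⱼ · BCE(s′ᵢⱼ^s, s′ᵢⱼ^t) with β = |s_t′ − s_s′| (stop-gradient).

    Scores are sigmoid outputs of matching N×K shape; they are clamped to
    (ε, 1−ε) before the logarithms.  Identical scores give exactly zero.
    """
    s = s_student if isinstance(s_student, Tensor) else Tensor(np.asarray(s_student, np.float32))
    t = np.asarray(s_teacher.data if isinstance(s_teacher, Tensor) else s_teacher,
                   np.float32)
    if s.shape != t.shape:
        raise ValueError("student/teacher score shapes differ")
    beta = np.abs(t - s.data)  # same dtype as the student scores: exact zero at equality
    sc = s.clamp(_EPS, 1 - _EPS)
    tt = Tensor(t)
    bce = -((1.0 - tt) * (1.0 - sc).log() + tt * sc.log())
    return (Tensor(beta) * bce).sum()


def iou_pairs(pred: Tensor, target: np.ndarray) -> Tensor:
    """Differentiable positionwise IoU between (M,4) box rows (o_i′ ∈ [0,1])."""
    t = Tensor(np.asarray(target, dtype=np.float32))
    ix0 = pred[:, 0].maximum(t[:, 0])
    iy0 = pred[:, 1].maximum(t[:, 1])
    ix1 = pred[:, 2].minimum(t[:, 2])
    iy1 = pred[:, 3].minimum(t[:, 3])
    inter = (ix1 - ix0).clamp(0) * (iy1 - iy0).clamp(0)
    area_p = (pred[:, 2] - pred[:, 0]).clamp(0) * (pred[:, 3] - pred[:, 1]).clamp(0)
    area_t = ((t[:, 2] - t[:, 0]) * (t[:, 3] - t[:, 1])).clamp(0)
    union = area_p + area_t - inter
    return inter / union.maximum(Tensor(np.float32(1e-9)))


def loc_distill_loss(student_boxes, teacher_boxes, beta: np.ndarray) -> Tensor:
    """Σᵢ maxⱼ(βᵢⱼ) · (1 − IoU(oᵢ^s, oᵢ^t)) over matched grid positions."""
    beta = np.atleast_2d(np.asarray(beta, dtype=np.float32))
    w = beta.max(axis=1)
    s = student_boxes if isinstance(student_boxes, Tensor) else Tensor(
        np.asarray(student_boxes, np.float32))
    o = iou_pairs(s, teacher_boxes)
    return ((1.0 - o) * Tensor(w)).sum()


def total_distill_loss(cls_loss, loc_loss, alpha_loc: float = 15.0, alpha_cls: float = 1.0):
    """Weighted sum of the two distillation terms (localization weight 15×)."""
    return loc_loss * alpha_loc + cls_loss * alpha_cls


def total_loss(distill, gt_loss, lam: float = 1.3):
    """λ·L_dis + L_gt."""
    return distill * lam + gt_loss


def distill_train(
    student: VetStar,
    teacher: VetStar,
    train_ds: YoloDataset,
    val_ds: YoloDataset | None,
    cfg: TrainConfig,
    dcfg: DistillConfig | None = None,
    log_path=None,
    ckpt_path=None,
) -> dict:
    """Train the student with ground-truth loss plus dense BCKD distillation.

    The teacher is frozen (evaluated under no-grad; its parameters are not
    in the optimizer).  Both models must share the C4 grid geometry; per
    batch, the distillation sums of Eq-style ``cls``/``loc`` terms are
    normalised by the number of grid positions before weighting so the
    printed 15:1 ratio and λ act on a per-position scale.
    """
    dcfg = dcfg or DistillConfig()
    if teacher.plan.reg_max != student.plan.reg_max or \
       teacher.plan.num_classes != student.plan.num_classes:
        raise ValueError("teacher/student head protocols differ")
    if dcfg.teacher_checkpoint:
        teacher.load(dcfg.teacher_checkpoint)
    teacher.eval()
    reg_max = student.plan.reg_max
    cache: dict[int, tuple] = {}  # teacher is frozen → outputs are image-constant

    def teacher_outputs(idx, imgs, centers, expected_shape):
        missing = [j for j, i in enumerate(idx) if int(i) not in cache]
        if missing:
            with no_grad():
                t_cls, t_box = teacher.forward(Tensor(imgs[missing]))
            if t_cls.shape[1:] != expected_shape[1:]:
                raise ValueError("teacher/student grid shapes differ")
            t_scores = sigmoid_protocol(
                np.moveaxis(t_cls.data, 1, -1)).astype(np.float32)
            with no_grad():
                t_boxes = decode_boxes_t(Tensor(t_box.data), centers, reg_max).data
            for slot, j in enumerate(missing):
                cache[int(idx[j])] = (t_scores[slot].reshape(-1, t_scores.shape[-1]),
                                      t_boxes[slot])
        scores = np.concatenate([cache[int(i)][0] for i in idx])
        boxes = np.concatenate([cache[int(i)][1] for i in idx])
        return scores, boxes

    def step(idx, imgs, cls_t, box_t, centers):
        n, k = cls_t.shape[0], cls_t.shape[1]
        npos = n * cls_t.shape[2] * cls_t.shape[3]
        t_scores, t_boxes = teacher_outputs(idx, imgs, centers, cls_t.shape)
        s_scores = cls_t.reshape(n, k, -1).transpose(0, 2, 1).reshape(-1, k).sigmoid()
        l_cls = cls_distill_loss(s_scores, t_scores)
        beta = np.abs(t_scores - s_scores.data)
        s_boxes = decode_boxes_t(box_t, centers, reg_max).reshape(-1, 4)
        l_loc = loc_distill_loss(s_boxes, t_boxes, beta)
        dis = total_distill_loss(l_cls * (1.0 / npos), l_loc * (1.0 / npos),
                                 dcfg.alpha_loc, dcfg.alpha_cls)
        return dis * dcfg.lam, {"dis_cls": float(l_cls.data) / npos,
                                "dis_loc": float(l_loc.data) / npos}

    return train(student, train_ds, val_ds, cfg, log_path=log_path,
                 ckpt_path=ckpt_path, distill_step=step)
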
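"""Anchor-free detection plumbing on the C4 grid.

Covers target assignment (task-aligned, top-k), the supervised loss
(classification BCE + CIoU box loss + distribution focal loss), and
inference-time decoding (DFL expectation + per-class greedy NMS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core.tensor import Tensor
from .model import RawPrediction

__all__ = [
    "DetectionBox",
    "AssignmentResult",
    "assign_targets",
    "detection_loss",
    "decode",
    "nms",
    "iou_matrix",
    "ciou",
    "grid_centers",
    "encode_ltrb_onehot",
]


@dataclass(frozen=True)
class DetectionBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_id: int
    confidence: float

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate box")
        if not np.isfinite(self.confidence):
            raise ValueError("confidence must be finite")

    @property
    def xyxy(self):
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max])


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (M,4) and (N,4) xyxy boxes; degenerate boxes get 0."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.prod(np.clip(br - tl, 0, None), axis=2)
    area_a = np.clip(np.prod(a[:, 2:] - a[:, :2], axis=1), 0, None)
    area_b = np.clip(np.prod(b[:, 2:] - b[:, :2], axis=1), 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def grid_centers(hg: int, wg: int) -> np.ndarray:
    """(Hg*Wg, 2) cell centers in stride units (x, y)."""
    ys, xs = np.meshgrid(np.arange(hg), np.arange(wg), indexing="ij")
    return np.stack([xs.ravel() + 0.5, ys.ravel() + 0.5], axis=1).astype(np.float32)


# ---------------------------------------------------------------------------
# task-aligned assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    """Per-cell matching for one batch (all arrays flattened over the grid)."""

    fg_mask: np.ndarray  # (N, L) bool
    gt_idx: np.ndarray  # (N, L) int, -1 for background
    target_scores: np.ndarray  # (N, L, K) soft classification targets
    target_boxes: np.ndarray  # (N, L, 4) xyxy in stride units
    target_ltrb: np.ndarray  # (N, L, 4) regression distances in stride units


def assign_targets(
    gt_boxes: list,
    gt_classes: list,
    pred_scores: np.ndarray,
    pred_boxes: np.ndarray,
    centers: np.ndarray,
    num_classes: int = 2,
    topk: int = 10,
    alpha: float = 0.5,
    beta: float = 6.0,
) -> AssignmentResult:
    """Task-aligned label assignment on the C4 grid.

    Candidate cells are those whose center lies inside a ground-truth box
    (falling back to the nearest cell for boxes smaller than the grid pitch).
    The alignment metric ``score**alpha * IoU**beta`` selects the ``topk``
    cells per ground truth; conflicts go to the best-aligned ground truth.
    Soft classification targets are the alignment metric normalised per
    ground truth to its best IoU.
    """
    n, l, k = pred_scores.shape
    fg = np.zeros((n, l), dtype=bool)
    gi = np.full((n, l), -1, dtype=np.int64)
    tscores = np.zeros((n, l, k), dtype=np.float32)
    tboxes = np.zeros((n, l, 4), dtype=np.float32)
    for b in range(n):
        boxes = np.asarray(gt_boxes[b], dtype=np.float32).reshape(-1, 4)
        classes = np.asarray(gt_classes[b], dtype=np.int64)
        g = len(boxes)
        if g == 0:
            continue
        inside = (
            (centers[None, :, 0] > boxes[:, None, 0])
            & (centers[None, :, 0] < boxes[:, None, 2])
            & (centers[None, :, 1] > boxes[:, None, 1])
            & (centers[None, :, 1] < boxes[:, None, 3])
        )
        ctr = (boxes[:, :2] + boxes[:, 2:]) / 2
        for gidx in range(g):  # tiny-box fallback: nearest cell
            if not inside[gidx].any():
                d2 = ((centers - ctr[gidx]) ** 2).sum(1)
                inside[gidx, np.argmin(d2)] = True
        iou = iou_matrix(boxes, pred_boxes[b])  # (G, L)
        score = pred_scores[b][:, classes].T  # (G, L)
        align = np.power(np.clip(score, 1e-9, 1), alpha) * np.power(iou, beta)
        # keep interior cells as candidates even at zero IoU so every ground
        # truth with an interior (or nearest-fallback) cell gets an assignment
        align = np.where(inside, align + 1e-12, 0.0)
        kk = min(topk, l)
        cand = np.argpartition(-align, kk - 1, axis=1)[:, :kk]
        mask = np.zeros_like(align, dtype=bool)
        np.put_along_axis(mask, cand, True, axis=1)
        mask &= align > 0
        # resolve cells claimed by several ground truths
        masked_align = np.where(mask, align, -1.0)
        best_gt = masked_align.argmax(axis=0)
        assigned = mask.any(axis=0)
        fg[b] = assigned
        gi[b, assigned] = best_gt[assigned]
        # per-gt normalisation of the soft target
        pos_align = np.where(mask, align, 0.0)
        gt_max_align = pos_align.max(axis=1, keepdims=True)
        gt_max_iou = np.where(mask, iou, 0.0).max(axis=1, keepdims=True)
        norm = pos_align * gt_max_iou / np.maximum(gt_max_align, 1e-9)
        cells = np.nonzero(assigned)[0]
        tscores[b, cells, classes[best_gt[cells]]] = norm[best_gt[cells], cells]
        tboxes[b, cells] = boxes[best_gt[cells]]
    ltrb = np.zeros((n, l, 4), dtype=np.float32)
    ltrb[..., 0] = centers[None, :, 0] - tboxes[..., 0]
    ltrb[..., 1] = centers[None, :, 1] - tboxes[..., 1]
    ltrb[..., 2] = tboxes[..., 2] - centers[None, :, 0]
    ltrb[..., 3] = tboxes[..., 3] - centers[None, :, 1]
    return AssignmentResult(fg, gi, tscores, tboxes, ltrb)


# ---------------------------------------------------------------------------
# differentiable pieces
# ---------------------------------------------------------------------------

def dfl_expectation(box_logits: Tensor, reg_max: int) -> Tensor:
    """(N, 4*reg_max, Hg, Wg) logits → (N, 4, Hg*Wg) expected l,t,r,b offsets."""
    n = box_logits.shape[0]
    hw = box_logits.shape[2] * box_logits.shape[3]
    z = box_logits.reshape(n, 4, reg_max, hw).softmax(axis=2)
    bins = Tensor(np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max, 1))
    return (z * bins).sum(axis=2)


def decode_boxes_t(box_logits: Tensor, centers: np.ndarray, reg_max: int) -> Tensor:
    """Differentiable decode to (N, L, 4) xyxy boxes in stride units."""
    ltrb = dfl_expectation(box_logits, reg_max).transpose(0, 2, 1)  # (N, L, 4)
    cx = Tensor(centers[None, :, 0:1])
    cy = Tensor(centers[None, :, 1:2])
    x0 = cx - ltrb[:, :, 0:1]
    y0 = cy - ltrb[:, :, 1:2]
    x1 = cx + ltrb[:, :, 2:3]
    y1 = cy + ltrb[:, :, 3:4]
    return Tensor.concatenate([x0, y0, x1, y1], axis=2)


def ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between (M,4) predicted (Tensor) and target (array) boxes."""
    t = Tensor(np.asarray(target, dtype=np.float32))
    eps = 1e-7
    ix0 = pred[:, 0].maximum(t[:, 0])
    iy0 = pred[:, 1].maximum(t[:, 1])
    ix1 = pred[:, 2].minimum(t[:, 2])
    iy1 = pred[:, 3].minimum(t[:, 3])
    inter = (ix1 - ix0).clamp(0) * (iy1 - iy0).clamp(0)
    area_p = (pred[:, 2] - pred[:, 0]).clamp(0) * (pred[:, 3] - pred[:, 1]).clamp(0)
    area_t = (t[:, 2] - t[:, 0]) * (t[:, 3] - t[:, 1])
    union = area_p + area_t - inter + eps
    iou = inter / union
    # enclosing-box diagonal and center distance
    ex0 = pred[:, 0].minimum(t[:, 0])
    ey0 = pred[:, 1].minimum(t[:, 1])
    ex1 = pred[:, 2].maximum(t[:, 2])
    ey1 = pred[:, 3].maximum(t[:, 3])
    c2 = (ex1 - ex0) ** 2 + (ey1 - ey0) ** 2 + eps
    dx = (pred[:, 0] + pred[:, 2]) * 0.5 - (t[:, 0] + t[:, 2]) * 0.5
    dy = (pred[:, 1] + pred[:, 3]) * 0.5 - (t[:, 1] + t[:, 3]) * 0.5
    rho2 = dx**2 + dy**2
    # aspect-ratio consistency
    wp = (pred[:, 2] - pred[:, 0]).clamp(eps)
    hp = (pred[:, 3] - pred[:, 1]).clamp(eps)
    wt = t[:, 2] - t[:, 0]
    ht = t[:, 3] - t[:, 1]
    v = (4.0 / np.pi**2) * ((wt / ht).atan() - (wp / hp).atan()) ** 2
    a = (v.data / (1 - iou.data + v.data + eps))  # detached trade-off weight
    return iou - rho2 / c2 - Tensor(a) * v


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable elementwise BCE from logits:
    max(x,0) - x·t + log(1 + exp(-|x|))."""
    t = Tensor(np.asarray(targets, dtype=np.float32))
    absx = (logits**2 + 1e-24) ** 0.5
    return logits.clamp(0) - logits * t + (1.0 + (-absx).exp()).log()


@dataclass
class LossBreakdown:
    total: Tensor
    components: dict = field(default_factory=dict)


def detection_loss(
    cls_logits: Tensor,
    box_logits: Tensor,
    assignment: AssignmentResult,
    centers: np.ndarray,
    reg_max: int = 16,
    w_cls: float = 0.5,
    w_box: float = 7.5,
    w_dfl: float = 1.5,
) -> LossBreakdown:
    """Supervised detection loss: BCE + CIoU + DFL with weights 0.5/7.5/1.5.

    An image with no ground truth contributes pure background classification
    loss.  Raises on non-finite totals.
    """
    n, k = cls_logits.shape[0], cls_logits.shape[1]
    hw = cls_logits.shape[2] * cls_logits.shape[3]
    cls_flat = cls_logits.reshape(n, k, hw).transpose(0, 2, 1)  # (N, L, K)
    tsum = max(float(assignment.target_scores.sum()), 1.0)
    cls_loss = _bce_with_logits(cls_flat, assignment.target_scores).sum() * (1.0 / tsum)

    fg = assignment.fg_mask
    if fg.any():
        bidx, cidx = np.nonzero(fg)
        w = assignment.target_scores[bidx, cidx].sum(axis=1)
        wsum = max(float(w.sum()), 1e-9)
        pred_boxes = decode_boxes_t(box_logits, centers, reg_max)[bidx, cidx]
        ciou_val = ciou(pred_boxes, assignment.target_boxes[bidx, cidx])
        box_loss = ((1.0 - ciou_val) * Tensor(w)).sum() * (1.0 / wsum)

        # distribution focal loss on the two bins bracketing each edge distance
        tgt = np.clip(assignment.target_ltrb[bidx, cidx], 0, reg_max - 1 - 1e-3)
        lo = np.floor(tgt).astype(np.int64)
        hi = lo + 1
        wl, wh = (hi - tgt).astype(np.float32), (tgt - lo).astype(np.float32)
        logp = box_logits.reshape(n, 4, reg_max, hw).transpose(0, 3, 1, 2)[bidx, cidx]
        logp = (logp.softmax(axis=2) + 1e-9).log()  # (M, 4, reg_max)
        m = len(bidx)
        rows = np.repeat(np.arange(m)[:, None], 4, axis=1)
        cols = np.tile(np.arange(4)[None, :], (m, 1))
        dfl = -(logp[rows, cols, lo] * Tensor(wl) + logp[rows, cols, hi] * Tensor(wh))
        dfl_loss = (dfl.mean(axis=1) * Tensor(w)).sum() * (1.0 / wsum)
    else:
        box_loss = Tensor(0.0)
        dfl_loss = Tensor(0.0)

    total = cls_loss * w_cls + box_loss * w_box + dfl_loss * w_dfl
    if not np.isfinite(total.data):
        raise FloatingPointError(
            f"non-finite loss: cls={cls_loss.data}, box={box_loss.data}, dfl={dfl_loss.data}"
        )
    return LossBreakdown(
        total,
        {"cls": float(cls_loss.data), "box": float(box_loss.data), "dfl": float(dfl_loss.data)},
    )


# ---------------------------------------------------------------------------
# inference decode
# ---------------------------------------------------------------------------

def _softmax_np(x, axis):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list:
    """Greedy non-maximum suppression; returns kept indices (desc. score)."""
    order = np.argsort(-scores)
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i : i + 1], boxes[rest])[0]
        order = rest[ious < iou_thr]
    return keep


def decode(
    raw: RawPrediction,
    conf_thr: float = 0.5,
    nms_iou: float = 0.7,
    reg_max: int = 16,
) -> list:
    """Decode one image's raw grid prediction into a list of DetectionBox.

    Box offsets are the expectation over the softmaxed ``reg_max`` bins times
    the stride; class scores are independent sigmoids; NMS is per class.
    """
    hg, wg, k = raw.cls_logits.shape[-3], raw.cls_logits.shape[-2], raw.cls_logits.shape[-1]
    cls = raw.cls_logits.reshape(hg * wg, k)
    box = raw.box_logits.reshape(hg * wg, 4, reg_max)
    scores = 1.0 / (1.0 + np.exp(-cls))
    probs = _softmax_np(box, axis=2)
    ltrb = (probs * np.arange(reg_max)).sum(axis=2)  # stride units
    centers = grid_centers(hg, wg)
    s = raw.stride
    xyxy = np.stack(
        [
            (centers[:, 0] - ltrb[:, 0]) * s,
            (centers[:, 1] - ltrb[:, 1]) * s,
            (centers[:, 0] + ltrb[:, 2]) * s,
            (centers[:, 1] + ltrb[:, 3]) * s,
        ],
        axis=1,
    )
    out: list[DetectionBox] = []
    for c in range(k):
        sel = np.nonzero(scores[:, c] >= conf_thr)[0]
        if not len(sel):
            continue
        keep = nms(xyxy[sel], scores[sel, c], nms_iou)
        for i in keep:
            x0, y0, x1, y1 = xyxy[sel[i]]
            if x1 <= x0 or y1 <= y0:
                continue
            out.append(DetectionBox(float(x0), float(y0), float(x1), float(y1), c,
                                    float(scores[sel[i], c])))
    out.sort(key=lambda d: -d.confidence)
    return out


def encode_ltrb_onehot(ltrb: np.ndarray, reg_max: int = 16, scale: float = 50.0) -> np.ndarray:
    """One-hot DFL logits whose decode reproduces ``round(ltrb)`` offsets."""
    ltrb = np.asarray(ltrb)
    bins = np.clip(np.round(ltrb).astype(int), 0, reg_max - 1)
    logits = np.full((*ltrb.shape, reg_max), -scale, dtype=np.float32)
    np.put_along_axis(logits, bins[..., None], scale, axis=-1)
    return logits
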
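"""Detection evaluation: matching, macro P/R, COCO-style mAP, diagnostics.

The test-card task has two box classes (negative, positive) plus implicit
background.  Macro precision/recall are unweighted means over the two
classes.  The clinical-style diagnostics map onto detection quantities:
sensitivity = positive-class recall, specificity = negative-class recall,
PPV = positive-class precision, NPV = negative-class precision, and accuracy
is the ground-truth-count-weighted mean of class recalls (the fraction of
annotated windows detected and correctly classified) — in detection there is
no well-defined true-negative count, so the textbook accuracy formula cannot
be applied directly.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .detection import DetectionBox, iou_matrix
from .synthetic import CLASS_NAMES

__all__ = [
    "MatchResult",
    "EvalSummary",
    "match_detections",
    "precision_recall",
    "average_precision",
    "evaluate",
    "diagnostics",
    "confusion_matrix",
    "measure_latency",
]

IOU_THRESHOLDS_50_95 = np.round(np.arange(0.5, 0.96, 0.05), 2)


@dataclass
class MatchResult:
    tp: dict
    fp: dict
    fn: dict
    pairs: list = field(default_factory=list)  # (det_index, gt_index)


def _gts_as_arrays(gts):
    boxes = np.array([g[0] for g in gts], dtype=float).reshape(-1, 4)
    classes = np.array([g[1] for g in gts], dtype=int)
    return boxes, classes


def match_detections(dets: list, gts: list, iou_thr: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching in descending confidence.

    A detection is a true positive iff it overlaps an unmatched same-class
    ground truth with IoU ≥ ``iou_thr``; leftover detections are false
    positives and leftover ground truths false negatives.
    ``gts`` is a list of (xyxy, class_id).
    """
    k = len(CLASS_NAMES)
    tp = {c: 0 for c in range(k)}
    fp = {c: 0 for c in range(k)}
    fn = {c: 0 for c in range(k)}
    gt_boxes, gt_classes = _gts_as_arrays(gts)
    matched_gt = np.zeros(len(gts), dtype=bool)
    pairs = []
    order = np.argsort([-d.confidence for d in dets])
    for di in order:
        d = dets[di]
        cand = np.nonzero((gt_classes == d.class_id) & ~matched_gt)[0]
        if len(cand):
            ious = iou_matrix(d.xyxy[None], gt_boxes[cand])[0]
            j = int(np.argmax(ious))
            if ious[j] >= iou_thr:
                matched_gt[cand[j]] = True
                tp[d.class_id] += 1
                pairs.append((int(di), int(cand[j])))
                continue
        fp[d.class_id] += 1
    for gi in np.nonzero(~matched_gt)[0]:
        fn[gt_classes[gi]] += 1
    return MatchResult(tp, fp, fn, pairs)


def precision_recall(match: MatchResult):
    """(macro_p, macro_r, per_class_p, per_class_r); empty denominators → 0."""
    per_p, per_r = {}, {}
    for c in match.tp:
        denom_p = match.tp[c] + match.fp[c]
        denom_r = match.tp[c] + match.fn[c]
        per_p[c] = match.tp[c] / denom_p if denom_p else 0.0
        per_r[c] = match.tp[c] / denom_r if denom_r else 0.0
    macro_p = float(np.mean(list(per_p.values())))
    macro_r = float(np.mean(list(per_r.values())))
    return macro_p, macro_r, per_p, per_r


def _ap_101(recalls: np.ndarray, precisions: np.ndarray) -> float:
    """COCO-style 101-point interpolated average precision."""
    # precision envelope (monotone non-increasing in recall)
    mpre = np.concatenate([[0.0], precisions, [0.0]])
    mrec = np.concatenate([[0.0], recalls, [1.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    grid = np.linspace(0, 1, 101)
    idx = np.searchsorted(mrec, grid, side="left")
    return float(np.mean(mpre[np.minimum(idx, len(mpre) - 1)]))


def average_precision(dets_per_image: list, gts_per_image: list, iou_thr: float = 0.5) -> dict:
    """Per-class AP at one IoU threshold over a set of images.

    Detections are pooled across images, ranked by confidence, and matched
    greedily within their image (best IoU ≥ threshold, one match per ground
    truth).  Classes absent from the ground truth get ``nan`` and are
    excluded from means with a warning.
    """
    k = len(CLASS_NAMES)
    aps = {}
    for c in range(k):
        records = []  # (confidence, image_index, xyxy)
        n_gt = 0
        gt_state = []
        for img_i, gts in enumerate(gts_per_image):
            boxes, classes = _gts_as_arrays(gts)
            sel = classes == c
            gt_state.append([boxes[sel], np.zeros(int(sel.sum()), dtype=bool)])
            n_gt += int(sel.sum())
        for img_i, dets in enumerate(dets_per_image):
            for d in dets:
                if d.class_id == c:
                    records.append((d.confidence, img_i, d.xyxy))
        if n_gt == 0:
            warnings.warn(f"class {CLASS_NAMES[c]!r} absent from ground truth; AP undefined")
            aps[c] = float("nan")
            continue
        if not records:
            aps[c] = 0.0
            continue
        records.sort(key=lambda r: -r[0])
        tp_flags = np.zeros(len(records))
        for i, (_, img_i, xyxy) in enumerate(records):
            boxes, used = gt_state[img_i]
            if len(boxes) == 0:
                continue
            ious = iou_matrix(xyxy[None], boxes)[0]
            ious[used] = -1
            j = int(np.argmax(ious))
            if ious[j] >= iou_thr:
                used[j] = True
                tp_flags[i] = 1
        cum_tp = np.cumsum(tp_flags)
        cum_fp = np.cumsum(1 - tp_flags)
        recalls = cum_tp / n_gt
        precisions = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
        aps[c] = _ap_101(recalls, precisions)
    return aps


def _nanmean(values) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(np.mean(vals)) if vals else 0.0


def diagnostics(per_class_recall: dict, per_class_precision: dict, class_sizes: dict) -> dict:
    """Clinical-style metrics from per-class detection P/R (class 1 = positive)."""
    n_total = sum(class_sizes.values())
    if n_total == 0:
        raise ValueError("no ground-truth boxes")
    accuracy = sum(per_class_recall[c] * class_sizes[c] for c in class_sizes) / n_total
    return {
        "sensitivity": per_class_recall[1],
        "specificity": per_class_recall[0],
        "ppv": per_class_precision[1],
        "npv": per_class_precision[0],
        "accuracy": accuracy,
    }


def confusion_matrix(dets_per_image: list, gts_per_image: list,
                     iou_thr: float = 0.5, conf_thr: float = 0.5) -> np.ndarray:
    """3×3 counts over (negative, positive, background).

    Rows are ground-truth classes, columns predicted classes.  Matching is
    class-agnostic greedy by confidence so cross-class confusions land in
    off-diagonal cells; unmatched ground truths count as missed (background
    column), unmatched detections as spurious (background row).
    """
    k = len(CLASS_NAMES)
    cm = np.zeros((k + 1, k + 1), dtype=int)
    for dets, gts in zip(dets_per_image, gts_per_image):
        dets = [d for d in dets if d.confidence >= conf_thr]
        gt_boxes, gt_classes = _gts_as_arrays(gts)
        used = np.zeros(len(gts), dtype=bool)
        for d in sorted(dets, key=lambda d: -d.confidence):
            cand = np.nonzero(~used)[0]
            if len(cand):
                ious = iou_matrix(d.xyxy[None], gt_boxes[cand])[0]
                j = int(np.argmax(ious))
                if ious[j] >= iou_thr:
                    used[cand[j]] = True
                    cm[gt_classes[cand[j]], d.class_id] += 1
                    continue
            cm[k, d.class_id] += 1  # spurious detection
        for gi in np.nonzero(~used)[0]:
            cm[gt_classes[gi], k] += 1  # missed ground truth
    return cm


@dataclass
class EvalSummary:
    precision: float
    recall: float
    per_class_precision: dict
    per_class_recall: dict
    ap_per_class: dict
    map50: float
    map50_95: float
    diagnostics: dict
    confusion: np.ndarray
    n_images: int
    n_gt: dict

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "per_class_precision": {CLASS_NAMES[c]: v for c, v in self.per_class_precision.items()},
            "per_class_recall": {CLASS_NAMES[c]: v for c, v in self.per_class_recall.items()},
            "ap_per_class": {CLASS_NAMES[c]: v for c, v in self.ap_per_class.items()},
            "map50": self.map50,
            "map50_95": self.map50_95,
            "diagnostics": self.diagnostics,
            "confusion_matrix": self.confusion.tolist(),
            "n_images": self.n_images,
            "n_gt": {CLASS_NAMES[c]: v for c, v in self.n_gt.items()},
        }


def evaluate(dets_per_image: list, gts_per_image: list,
             iou_thr: float = 0.5, conf_thr: float = 0.5) -> EvalSummary:
    """Full evaluation of per-image detections against ground truth."""
    tp = {c: 0 for c in range(len(CLASS_NAMES))}
    fp = dict(tp)
    fn = dict(tp)
    for dets, gts in zip(dets_per_image, gts_per_image):
        m = match_detections([d for d in dets if d.confidence >= conf_thr], gts, iou_thr)
        for c in tp:
            tp[c] += m.tp[c]
            fp[c] += m.fp[c]
            fn[c] += m.fn[c]
    agg = MatchResult(tp, fp, fn)
    macro_p, macro_r, per_p, per_r = precision_recall(agg)
    ap50 = average_precision(dets_per_image, gts_per_image, 0.5)
    ap_all = [average_precision(dets_per_image, gts_per_image, t) for t in IOU_THRESHOLDS_50_95]
    map50 = _nanmean(ap50.values())
    map50_95 = _nanmean([_nanmean(ap.values()) for ap in ap_all])
    n_gt = {c: tp[c] + fn[c] for c in tp}
    diag = diagnostics(per_r, per_p, n_gt) if sum(n_gt.values()) else {}
    cm = confusion_matrix(dets_per_image, gts_per_image, iou_thr, conf_thr)
    return EvalSummary(macro_p, macro_r, per_p, per_r, ap50, map50, map50_95, diag, cm,
                       len(gts_per_image), n_gt)


def measure_latency(fn, inp, repeats: int = 10, warmup: int = 2) -> dict:
    """Single-sample wall-clock latency: mean/min over ``repeats`` after warm-up."""
    for _ in range(warmup):
        fn(inp)
    samples = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        fn(inp)
        samples.append(time.perf_counter() - t0)
    return {"mean": float(np.mean(samples)), "min": float(np.min(samples)),
            "samples": samples}
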
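"""Ground-truth supervised training of VetStar.

Adam with cosine decay, batch size 8, early stopping on validation mAP50;
every source of randomness is derived from the config seed.  Training logs
are JSONL (one record per epoch) and the best-on-validation checkpoint is
kept in memory and optionally written to ``.npz``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from ._core.optim import EMA, Adam, cosine_lr
from ._core.tensor import Tensor
from .detection import assign_targets, decode, detection_loss, grid_centers
from .metrics import evaluate
from .model import VetStar

__all__ = ["TrainConfig", "YoloDataset", "train", "predict_images"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    max_epochs: int = 500
    lr: float = 1e-3
    patience: int = 50
    input_side: int = 512
    seed: int = 0
    conf_thr: float = 0.5
    nms_iou: float = 0.7
    w_cls: float = 0.5
    w_box: float = 7.5
    w_dfl: float = 1.5
    assign_topk: int = 10
    assign_alpha: float = 0.5
    assign_beta: float = 6.0
    val_interval: int = 1
    warmup_epochs: int = 3
    ema_decay: float = 0.99  # 0 disables EMA evaluation

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class YoloDataset:
    """In-memory dataset of (image, boxes, classes) from a YOLO directory.

    Expects ``<root>/images/*.png`` and ``<root>/labels/*.txt`` with lines
    ``class cx cy w h`` normalized to [0, 1].  Images are resized (nearest)
    to ``input_side`` and scaled to [0, 1] CHW float32.
    """

    def __init__(self, root, input_side: int):
        root = Path(root)
        self.input_side = input_side
        self.images: list[np.ndarray] = []
        self.boxes: list[np.ndarray] = []
        self.classes: list[np.ndarray] = []
        self.files: list[str] = []
        for img_path in sorted((root / "images").glob("*.png")):
            label_path = root / "labels" / (img_path.stem + ".txt")
            img = Image.open(img_path).convert("RGB")
            if img.size != (input_side, input_side):
                img = img.resize((input_side, input_side), Image.BILINEAR)
            arr = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
            boxes, classes = [], []
            if label_path.exists():
                for line in label_path.read_text().splitlines():
                    c, cx, cy, w, h = (float(v) for v in line.split())
                    s = input_side
                    boxes.append([(cx - w / 2) * s, (cy - h / 2) * s,
                                  (cx + w / 2) * s, (cy + h / 2) * s])
                    classes.append(int(c))
            self.images.append(arr)
            self.boxes.append(np.asarray(boxes, dtype=np.float32).reshape(-1, 4))
            self.classes.append(np.asarray(classes, dtype=np.int64))
            self.files.append(img_path.name)
        if not self.images:
            raise ValueError(f"no images found under {root}")

    def __len__(self):
        return len(self.images)

    def gts(self) -> list:
        """Ground truth per image as [(xyxy, class), ...] lists."""
        return [
            [(tuple(b), int(c)) for b, c in zip(bs, cs)]
            for bs, cs in zip(self.boxes, self.classes)
        ]


def _forward_loss(model, batch_imgs, batch_boxes, batch_classes, cfg: TrainConfig):
    plan = model.plan
    cls_t, box_t = model.forward(Tensor(batch_imgs))
    n, k, hg, wg = cls_t.shape
    centers = grid_centers(hg, wg)
    stride = plan.c4_stride
    # assignment is computed on detached predictions
    scores = 1.0 / (1.0 + np.exp(-np.moveaxis(cls_t.data, 1, -1).reshape(n, -1, k)))
    from .detection import decode_boxes_t
    from ._core.tensor import no_grad

    with no_grad():
        pred_boxes = decode_boxes_t(Tensor(box_t.data), centers, plan.reg_max).data
    gt_boxes = [b / stride for b in batch_boxes]
    assignment = assign_targets(
        gt_boxes, batch_classes, scores, pred_boxes, centers,
        num_classes=plan.num_classes, topk=cfg.assign_topk,
        alpha=cfg.assign_alpha, beta=cfg.assign_beta,
    )
    loss = detection_loss(
        cls_t, box_t, assignment, centers, reg_max=plan.reg_max,
        w_cls=cfg.w_cls, w_box=cfg.w_box, w_dfl=cfg.w_dfl,
    )
    return loss, (cls_t, box_t, centers, assignment)


def predict_images(model: VetStar, images: list, conf_thr=0.5, nms_iou=0.7, batch=8) -> list:
    """Eval-mode detections for a list of CHW images in [0, 1]."""
    dets = []
    for i in range(0, len(images), batch):
        chunk = np.stack(images[i : i + batch])
        raw = model.predict_raw(chunk)
        for j in range(len(chunk)):
            from .model import RawPrediction

            one = RawPrediction(raw.cls_logits[j], raw.box_logits[j], raw.stride)
            dets.append(decode(one, conf_thr, nms_iou, model.plan.reg_max))
    return dets


def val_map50(model: VetStar, dataset: YoloDataset, cfg: TrainConfig) -> float:
    # AP integrates over the confidence ranking, so decode with a low floor
    dets = predict_images(model, dataset.images, conf_thr=0.05, nms_iou=cfg.nms_iou)
    return evaluate(dets, dataset.gts(), iou_thr=0.5, conf_thr=0.05).map50


def train(
    model: VetStar,
    train_ds: YoloDataset,
    val_ds: YoloDataset | None,
    cfg: TrainConfig,
    log_path=None,
    ckpt_path=None,
    distill_step=None,
) -> dict:
    """Train ``model``; returns {"best_map50", "best_epoch", "log", "best_state"}.

    ``distill_step(idx, imgs, cls_t, box_t, centers) -> (Tensor, dict)`` optionally adds
    a distillation term to every batch loss (used by the BCKD wrapper).
    Aborts on non-finite loss; early-stops after ``patience`` epochs without
    validation improvement.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(list(model.parameters()), lr=cfg.lr)
    ema = EMA(model, cfg.ema_decay) if cfg.ema_decay else None
    log: list[dict] = []
    best = {"map50": -1.0, "epoch": -1, "state": model.state_dict()}
    since_best = 0
    for epoch in range(cfg.max_epochs):
        model.train()
        lr = cosine_lr(cfg.lr, epoch, cfg.max_epochs)
        if cfg.warmup_epochs:
            lr *= min(1.0, (epoch + 1) / cfg.warmup_epochs)
        order = rng.permutation(len(train_ds))
        epoch_losses: dict[str, list] = {}
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            imgs = np.stack([train_ds.images[j] for j in idx])
            boxes = [train_ds.boxes[j] for j in idx]
            classes = [train_ds.classes[j] for j in idx]
            loss, (cls_t, box_t, centers, _) = _forward_loss(model, imgs, boxes, classes, cfg)
            total = loss.total
            comps = dict(loss.components)
            if distill_step is not None:
                extra, extra_comps = distill_step(idx, imgs, cls_t, box_t, centers)
                total = total + extra
                comps.update(extra_comps)
            opt.zero_grad()
            total.backward()
            opt.step(lr=lr)
            if ema is not None:
                ema.update()
            comps["total"] = float(total.data)
            for key, v in comps.items():
                epoch_losses.setdefault(key, []).append(v)
        record = {"epoch": epoch, "lr": lr}
        record.update({k: float(np.mean(v)) for k, v in epoch_losses.items()})
        do_val = val_ds is not None and (
            epoch % cfg.val_interval == 0 or epoch == cfg.max_epochs - 1
        )
        if do_val:
            if ema is not None:  # validate the averaged weights
                live = {k: p.data.copy() for k, p in model.named_parameters()}
                for k, p in model.named_parameters():
                    p.data[...] = ema.shadow[k]
            m50 = val_map50(model, val_ds, cfg)
            eval_state = model.state_dict()
            if ema is not None:
                for k, p in model.named_parameters():
                    p.data[...] = live[k]
            record["val_map50"] = m50
            if m50 > best["map50"] + 1e-6:
                best = {"map50": m50, "epoch": epoch, "state": eval_state}
                since_best = 0
            else:
                since_best += cfg.val_interval  # epochs, not validation rounds
        log.append(record)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")
        if val_ds is not None and since_best > cfg.patience:
            break
    if val_ds is not None:
        model.load_state_dict(best["state"])
    else:
        best = {"map50": float("nan"), "epoch": len(log) - 1, "state": model.state_dict()}
    if ckpt_path is not None:
        model.save(ckpt_path)
    return {"best_map50": best["map50"], "best_epoch": best["epoch"], "log": log,
            "best_state": best["state"]}
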
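"""Seeded synthetic generator for colloidal-gold test-card tray images.

Real tray photographs of veterinary drug-residue rapid tests are not
publicly shareable, so this module renders annotated stand-ins that
reproduce the *statistical structure* of such data: white-background trays
holding one of three layouts (single strips, single-window cards, or
triple-window cards), each color-development window showing a control (C)
band and a detection (T) band of variable intensity.  Because the assay is
competitive, a visible T band together with a visible C band reads
*negative*; a visible C band with no T band reads *positive*; a missing C
band voids the test (*invalid*).

Class labels are derived from the generating line intensities through
:func:`interpret_lines`, so label consistency is checkable exhaustively
from the manifest.  Rendering is fully determined by the scene seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "LineSpec",
    "CardSpec",
    "SceneSpec",
    "Annotation",
    "DatasetConfig",
    "interpret_lines",
    "render_scene",
    "generate_dataset",
    "write_yolo_labels",
    "coco_export",
    "CLASS_NAMES",
    "VISIBILITY_THRESHOLD",
]

CLASS_NAMES = ("negative", "positive")
NEGATIVE, POSITIVE = 0, 1

#: minimum band intensity at which a line counts as visible
VISIBILITY_THRESHOLD = 0.15

# wine-red colloidal-gold band color (RGB)
_LINE_COLOR = np.array([148.0, 32.0, 74.0])
_DEFAULT_GRIDS = {"strip": (6, 8), "single_card": (4, 4), "triple_card": (2, 5)}
_MAX_CARDS = {"strip": 48, "single_card": 16, "triple_card": 10}
_WINDOWS_PER_CARD = {"strip": 1, "single_card": 1, "triple_card": 3}


def interpret_lines(c_visible: bool, t_visible: bool) -> str:
    """Line-elimination rule mapping band visibility to the assay outcome.

    Competitive format: the T band disappears when analyte is present, so
    (C ✓, T ✗) is positive and (C ✓, T ✓) is negative.  Without a control
    band the test is void regardless of T.
    """
    if not c_visible:
        return "invalid"
    return "positive" if not t_visible else "negative"


@dataclass(frozen=True)
class LineSpec:
    """One chromogenic band: intensity in [0, 1] (0 = absent)."""

    intensity: float
    band_width_px: int = 4
    hue_jitter: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must be in [0, 1]")
        if self.band_width_px < 1:
            raise ValueError("band_width_px must be positive")

    def visible(self, tau: float = VISIBILITY_THRESHOLD) -> bool:
        return self.intensity >= tau


@dataclass(frozen=True)
class CardSpec:
    """One card: housing rectangle, its windows, and the C/T bands per window."""

    layout_kind: str
    card_rect: tuple  # (x0, y0, x1, y1) pixels, half-open
    window_rects: tuple  # one rect per drug channel
    lines: tuple  # per window: (C: LineSpec, T: LineSpec)

    def __post_init__(self):
        expected = _WINDOWS_PER_CARD[self.layout_kind]
        if len(self.window_rects) != expected:
            raise ValueError(f"{self.layout_kind} must have {expected} window(s)")
        if len(self.lines) != len(self.window_rects):
            raise ValueError("one (C, T) pair per window required")
        x0, y0, x1, y1 = self.card_rect
        for wx0, wy0, wx1, wy1 in self.window_rects:
            if not (x0 <= wx0 < wx1 <= x1 and y0 <= wy0 < wy1 <= y1):
                raise ValueError("windows must lie inside the card rectangle")


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one tray image."""

    layout_kind: str = "single_card"
    n_cards: int = 16
    image_size: int = 1944
    grid: tuple | None = None  # (rows, cols); default per layout
    jitter_px: float = 8.0
    illumination_gradient: float = 0.06
    gaussian_noise_sigma: float = 2.0
    positive_fraction: float = 0.17
    faint_t_fraction: float = 0.15
    visibility_threshold: float = VISIBILITY_THRESHOLD
    allow_invalid: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.layout_kind not in _MAX_CARDS:
            raise ValueError(f"unknown layout {self.layout_kind!r}")
        if not 1 <= self.n_cards <= _MAX_CARDS[self.layout_kind]:
            raise ValueError(
                f"{self.layout_kind} supports 1..{_MAX_CARDS[self.layout_kind]} cards"
            )
        if self.image_size < 64:
            raise ValueError("image_size too small")


@dataclass
class Annotation:
    """Boxes over the color-development windows of one rendered scene."""

    image_id: str
    image_size: int
    boxes: list = field(default_factory=list)  # (x0, y0, x1, y1, class_id)
    line_intensities: list = field(default_factory=list)  # (c_int, t_int) per box

    def class_counts(self) -> dict:
        counts = {name: 0 for name in CLASS_NAMES}
        for *_, cls in self.boxes:
            counts[CLASS_NAMES[cls]] += 1
        return counts


# ---------------------------------------------------------------------------
# scene sampling
# ---------------------------------------------------------------------------

def _sample_line_pair(rng, spec: SceneSpec):
    """Draw (C, T) line specs and the resulting class for one window."""
    tau = spec.visibility_threshold
    c = LineSpec(
        intensity=float(rng.uniform(0.5, 0.95)),
        band_width_px=max(2, int(round(spec.image_size / 480))),
        hue_jitter=float(rng.normal(0, 0.03)),
    )
    if rng.random() < spec.positive_fraction:
        # positive: T invisible (absent or clearly below threshold)
        t_int = 0.0 if rng.random() < 0.7 else float(rng.uniform(0.0, 0.6 * tau))
    elif rng.random() < spec.faint_t_fraction:
        # hard negative: faint but visible T just above threshold
        t_int = float(rng.uniform(tau, tau + 0.1))
    else:
        t_int = float(rng.uniform(0.45, 0.9))
    t = LineSpec(intensity=t_int, band_width_px=c.band_width_px,
                 hue_jitter=float(rng.normal(0, 0.03)))
    if spec.allow_invalid and rng.random() < 0.5:
        c = LineSpec(0.0, c.band_width_px)
    return c, t


def _card_geometry(spec: SceneSpec, rng):
    """Place card rectangles on a jittered grid; reject overlapping layouts."""
    s = spec.image_size
    rows, cols = spec.grid or _DEFAULT_GRIDS[spec.layout_kind]
    if rows * cols < spec.n_cards:
        raise ValueError("grid too small for n_cards")
    margin = 0.04 * s
    cell_w = (s - 2 * margin) / cols
    cell_h = (s - 2 * margin) / rows
    if spec.layout_kind == "strip":
        frac_w, frac_h = 0.42, 0.88
    elif spec.layout_kind == "single_card":
        frac_w, frac_h = 0.72, 0.80
    else:
        frac_w, frac_h = 0.86, 0.72
    card_w, card_h = frac_w * cell_w, frac_h * cell_h
    # jitter cannot exceed the free space in a cell, or cards would collide
    jx = min(spec.jitter_px, max(0.0, (cell_w - card_w) / 2 - 1))
    jy = min(spec.jitter_px, max(0.0, (cell_h - card_h) / 2 - 1))
    slots = [(r, c) for r in range(rows) for c in range(cols)]
    idx = rng.permutation(len(slots))[: spec.n_cards]
    rects = []
    for k in sorted(idx):
        r, c = slots[k]
        cx = margin + (c + 0.5) * cell_w + rng.uniform(-jx, jx)
        cy = margin + (r + 0.5) * cell_h + rng.uniform(-jy, jy)
        x0 = int(round(np.clip(cx - card_w / 2, 0, s - card_w - 1)))
        y0 = int(round(np.clip(cy - card_h / 2, 0, s - card_h - 1)))
        rects.append((x0, y0, int(round(x0 + card_w)), int(round(y0 + card_h))))
    for i, a in enumerate(rects):
        for b in rects[i + 1 :]:
            if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                raise ValueError("card rectangles overlap; reduce jitter or n_cards")
    return rects


def _window_rects(layout_kind: str, card_rect: tuple):
    x0, y0, x1, y1 = card_rect
    w, h = x1 - x0, y1 - y0
    n = _WINDOWS_PER_CARD[layout_kind]
    rects = []
    if n == 1:
        ww, wh = 0.52 * w, 0.42 * h
        cx, cy = x0 + 0.5 * w, y0 + 0.45 * h
        rects.append((cx - ww / 2, cy - wh / 2, cx + ww / 2, cy + wh / 2))
    else:  # triple card: three channels side by side
        ww, wh = 0.22 * w, 0.48 * h
        for k in range(3):
            cx = x0 + (0.22 + 0.28 * k) * w
            cy = y0 + 0.46 * h
            rects.append((cx - ww / 2, cy - wh / 2, cx + ww / 2, cy + wh / 2))
    return tuple(tuple(int(round(v)) for v in r) for r in rects)


def sample_cards(spec: SceneSpec, rng) -> list[CardSpec]:
    cards = []
    for rect in _card_geometry(spec, rng):
        windows = _window_rects(spec.layout_kind, rect)
        lines = tuple(_sample_line_pair(rng, spec) for _ in windows)
        cards.append(CardSpec(spec.layout_kind, rect, windows, lines))
    return cards


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _draw_band(layer: np.ndarray, alpha: np.ndarray, window: tuple, line: LineSpec,
               rel_y: float, rng):
    """Accumulate one horizontal band (hard edges; blurred later)."""
    if line.intensity <= 0:
        return
    x0, y0, x1, y1 = window
    yc = int(round(y0 + rel_y * (y1 - y0)))
    half = max(1, line.band_width_px // 2)
    ya, yb = max(y0 + 1, yc - half), min(y1 - 1, yc + half + 1)
    xa, xb = x0 + 1, x1 - 1
    if ya >= yb or xa >= xb:
        return
    color = np.clip(_LINE_COLOR * (1.0 + line.hue_jitter), 0, 255)
    alpha[ya:yb, xa:xb] = np.maximum(alpha[ya:yb, xa:xb], line.intensity)
    layer[ya:yb, xa:xb] = color


def render_scene(spec: SceneSpec):
    """Render one tray image; returns (uint8 H×W×3 image, Annotation).

    Deterministic given ``spec`` (including its seed).  One annotated box per
    window, the class computed from the generating line pair through
    :func:`interpret_lines`; invalid windows are only produced when
    ``allow_invalid`` is set and are annotated as class ``-1``.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    cards = sample_cards(spec, rng)

    img = np.full((s, s, 3), 252.0, dtype=np.float32)
    # card housings: near-white plastic with a faint grey outline
    for card in cards:
        x0, y0, x1, y1 = card.card_rect
        img[y0:y1, x0:x1] = rng.uniform(235, 245)
        img[y0:y1, x0 : x0 + 1] = 205
        img[y0:y1, x1 - 1 : x1] = 205
        img[y0 : y0 + 1, x0:x1] = 205
        img[y1 - 1 : y1, x0:x1] = 205
        for win in card.window_rects:
            wx0, wy0, wx1, wy1 = win
            img[wy0:wy1, wx0:wx1] = 250.0  # nitrocellulose membrane

    band_color = np.zeros((s, s, 3), dtype=np.float32)
    band_alpha = np.zeros((s, s), dtype=np.float32)
    annotation = Annotation(image_id=f"scene_{spec.layout_kind}_{spec.seed}", image_size=s)
    for card in cards:
        for win, (c_line, t_line) in zip(card.window_rects, card.lines):
            _draw_band(band_color, band_alpha, win, c_line, rel_y=0.28, rng=rng)
            _draw_band(band_color, band_alpha, win, t_line, rel_y=0.68, rng=rng)
            outcome = interpret_lines(
                c_line.visible(spec.visibility_threshold),
                t_line.visible(spec.visibility_threshold),
            )
            if outcome == "invalid" and not spec.allow_invalid:
                raise AssertionError("invalid window sampled with allow_invalid=False")
            cls = {"negative": NEGATIVE, "positive": POSITIVE, "invalid": -1}[outcome]
            annotation.boxes.append((*win, cls))
            annotation.line_intensities.append((c_line.intensity, t_line.intensity))

    # soften band edges, then composite over the tray
    sigma = max(0.6, s / 2000)
    band_alpha = gaussian_filter(band_alpha, sigma)
    a = band_alpha[..., None]
    img = (1 - a) * img + a * np.where(band_color.sum(-1, keepdims=True) > 0,
                                       band_color, _LINE_COLOR)

    if spec.illumination_gradient:
        ramp = 1.0 + spec.illumination_gradient * (np.linspace(0, 1, s) - 0.5)
        img *= ramp[None, :, None]
    if spec.gaussian_noise_sigma:
        img += rng.normal(0, spec.gaussian_noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), annotation


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetConfig:
    """Totals and rendering parameters for a generated dataset."""

    out_dir: str
    images_per_layout: dict = field(
        default_factory=lambda: {"strip": 10, "single_card": 10, "triple_card": 10}
    )
    image_size: int = 1944
    cards_per_layout: dict | None = None  # default: layout maxima
    grids: dict | None = None
    positive_fraction: float = 0.17
    faint_t_fraction: float = 0.15
    jitter_px: float = 8.0
    illumination_gradient: float = 0.06
    gaussian_noise_sigma: float = 2.0
    split_ratios: tuple = (0.6, 0.2, 0.2)
    seed: int = 0


def _split_counts(n: int, ratios) -> tuple:
    """Largest-remainder split of n images into train/val/test."""
    raw = [n * r for r in ratios]
    base = [int(np.floor(v)) for v in raw]
    rem = n - sum(base)
    order = np.argsort([b - v for b, v in zip(base, raw)])
    for i in order[:rem]:
        base[i] += 1
    return tuple(base)


def write_yolo_labels(path: Path, annotation: Annotation) -> None:
    s = annotation.image_size
    lines = []
    for x0, y0, x1, y1, cls in annotation.boxes:
        cx, cy = (x0 + x1) / 2 / s, (y0 + y1) / 2 / s
        w, h = (x1 - x0) / s, (y1 - y0) / s
        lines.append(f"{cls} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def generate_dataset(config: DatasetConfig) -> dict:
    """Render a train/val/test directory tree plus a JSON manifest.

    Splits follow 6:2:2 (within rounding) *per layout kind*, so every kind
    appears in every split.  The manifest records per-split class counts and
    per-box line intensities.
    """
    total = sum(config.images_per_layout.values())
    if total <= 0:
        raise ValueError("no images requested")
    out = Path(config.out_dir)
    split_names = ("train", "val", "test")
    for sp in split_names:
        (out / sp / "images").mkdir(parents=True, exist_ok=True)
        (out / sp / "labels").mkdir(parents=True, exist_ok=True)

    manifest = {
        "image_size": config.image_size,
        "class_names": list(CLASS_NAMES),
        "splits": {sp: {"images": [], "boxes": {n: 0 for n in CLASS_NAMES}} for sp in split_names},
    }
    seed_seq = np.random.SeedSequence(config.seed)
    next_seed = iter(seed_seq.generate_state(4 * total))

    for layout, n_images in config.images_per_layout.items():
        counts = _split_counts(n_images, config.split_ratios)
        k = 0
        for sp, n_sp in zip(split_names, counts):
            for _ in range(n_sp):
                scene_seed = int(next(next_seed) % (2**31))
                spec = SceneSpec(
                    layout_kind=layout,
                    n_cards=(config.cards_per_layout or _MAX_CARDS)[layout],
                    image_size=config.image_size,
                    grid=(config.grids or {}).get(layout),
                    jitter_px=config.jitter_px,
                    illumination_gradient=config.illumination_gradient,
                    gaussian_noise_sigma=config.gaussian_noise_sigma,
                    positive_fraction=config.positive_fraction,
                    faint_t_fraction=config.faint_t_fraction,
                    seed=scene_seed,
                )
                img, ann = render_scene(spec)
                stem = f"{layout}_{k:04d}"
                k += 1
                Image.fromarray(img).save(out / sp / "images" / f"{stem}.png")
                write_yolo_labels(out / sp / "labels" / f"{stem}.txt", ann)
                for name, c in ann.class_counts().items():
                    manifest["splits"][sp]["boxes"][name] += c
                manifest["splits"][sp]["images"].append(
                    {
                        "file": f"{sp}/images/{stem}.png",
                        "layout": layout,
                        "seed": scene_seed,
                        "n_boxes": len(ann.boxes),
                        "classes": [c for *_, c in ann.boxes],
                        "line_intensities": ann.line_intensities,
                    }
                )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def coco_export(manifest: dict, root: Path, split: str) -> dict:
    """COCO-style annotation dict for one split of a generated dataset."""
    images, annotations = [], []
    ann_id = 1
    for img_id, rec in enumerate(manifest["splits"][split]["images"], start=1):
        images.append(
            {"id": img_id, "file_name": rec["file"],
             "width": manifest["image_size"], "height": manifest["image_size"]}
        )
        label_path = Path(root) / rec["file"].replace("images/", "labels/").replace(".png", ".txt")
        s = manifest["image_size"]
        for line in label_path.read_text().splitlines():
            cls, cx, cy, w, h = line.split()
            bw, bh = float(w) * s, float(h) * s
            x0, y0 = float(cx) * s - bw / 2, float(cy) * s - bh / 2
            annotations.append(
                {"id": ann_id, "image_id": img_id, "category_id": int(cls) + 1,
                 "bbox": [x0, y0, bw, bh], "area": bw * bh, "iscrowd": 0}
            )
            ann_id += 1
    categories = [{"id": i + 1, "name": n} for i, n in enumerate(CLASS_NAMES)]
    return {"images": images, "annotations": annotations, "categories": categories}
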
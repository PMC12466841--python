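"""The VetStar detector: StarBlock backbone with a single DR-head at C4.

VetStar is a deliberately shallow anchor-free detector for tray images of
colloidal-gold rapid-test cards.  The backbone is a strided convolutional
stem followed by four stages, each a transition convolution plus one
StarBlock; the detection head (DR-head) is attached only to the C4 feature
map (stride 16), since the tray geometry needs no multi-scale fusion.

Two ideas keep the model small while preserving accuracy:

* **Star operation** — each StarBlock projects features through two linear
  maps and multiplies them element-wise,
  ``(M1ᵀf′) ∗ (M2ᵀf′) = Σᵢ Σⱼ m1ᵢ m2ⱼ f′ᵢ f′ⱼ``  (f′ is f with a bias
  coordinate appended), implicitly spanning ~d²/2 pairwise monomials
  without widening the network.
* **Structural reparameterization** — the head's Rep-Conv trains with
  parallel 3×3 and 1×1 branches (each with batch-norm) and is merged
  algebraically into a single biased 3×3 convolution for inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core import nn
from ._core.tensor import Parameter, Tensor, no_grad

__all__ = [
    "ChannelPlan",
    "RawPrediction",
    "ModelSummary",
    "StarBlock",
    "RepConv",
    "DRHead",
    "VetStar",
    "build_vetstar",
    "build_teacher",
    "reparameterize",
    "star_operation",
    "star_term_count",
    "count_parameters",
    "count_flops",
    "model_summary",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelPlan:
    """Architecture hyperparameters.

    The default plan is the reference VetStar: it is the narrowest plan we
    found whose merged form rounds to 0.04 M parameters while FLOPs at
    640×640 round to 0.3 G (multiply-add counted as two operations).
    """

    stem_width: int = 8
    stage_widths: tuple = (12, 24, 32, 32)
    star_expansion: int = 2
    reg_max: int = 16
    num_classes: int = 2
    head_width: int = 32
    # stem stride then per-stage strides; product = C4 stride = 16
    strides: tuple = (2, 2, 2, 2, 1)

    def __post_init__(self):
        if self.stem_width <= 0 or any(w <= 0 for w in self.stage_widths):
            raise ValueError("all widths must be positive")
        if len(self.stage_widths) != 4 or len(self.strides) != 5:
            raise ValueError("plan needs 4 stages and 5 stride entries")
        if int(np.prod(self.strides)) != 16:
            raise ValueError("C4 stride must be 16")

    @property
    def c4_stride(self) -> int:
        return 16

    def widened(self, factor: int = 4) -> "ChannelPlan":
        """A teacher-sized plan with every width scaled by ``factor``."""
        return ChannelPlan(
            stem_width=self.stem_width * factor,
            stage_widths=tuple(w * factor for w in self.stage_widths),
            star_expansion=self.star_expansion,
            reg_max=self.reg_max,
            num_classes=self.num_classes,
            head_width=self.head_width * factor,
            strides=self.strides,
        )


@dataclass
class RawPrediction:
    """Per-grid-cell logits from the C4 head (numpy views, batch leading)."""

    cls_logits: np.ndarray  # (N, Hg, Wg, num_classes)
    box_logits: np.ndarray  # (N, Hg, Wg, 4*reg_max)
    stride: int = 16


@dataclass
class ModelSummary:
    layers: list = field(default_factory=list)  # (name, params, cin, cout, k, h, w, flops)
    parameters: int = 0
    flops: int = 0


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class ConvBN(nn.Module):
    """Conv (no bias) + BatchNorm + optional activation."""

    def __init__(self, cin, cout, k, stride=1, groups=1, act="silu", rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, groups=groups, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = {"silu": nn.SiLU(), "relu6": nn.ReLU6(), None: nn.Identity()}[act]

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


def star_operation(x: Tensor, f1: nn.Conv2d, f2: nn.Conv2d) -> Tensor:
    """Element-wise product of two linear projections of ``x``.

    ``f1``/``f2`` are 1×1 convolutions with bias, so per spatial position the
    result is the bilinear form ``Σᵢ Σⱼ m1ᵢ m2ⱼ f′ᵢ f′ⱼ`` over the
    bias-augmented feature f′ = (f, 1).
    """
    return f1(x) * f2(x)


class StarBlock(nn.Module):
    """Depthwise conv → star operation → fuse → depthwise conv, with residual.

    Shape preserving: output spatial size and channel count equal the input's.
    """

    def __init__(self, c: int, expansion: int = 2, rng=None):
        super().__init__()
        self.c = c
        e = expansion * c
        self.dw1 = ConvBN(c, c, 3, groups=c, act=None, rng=rng)
        # linear branches carry the +1 bias coordinate of the star operation
        self.f1 = nn.Conv2d(c, e, 1, bias=True, rng=rng)
        self.f2 = nn.Conv2d(c, e, 1, bias=True, rng=rng)
        self.fuse = ConvBN(e, c, 1, act=None, rng=rng)
        self.dw2 = ConvBN(c, c, 3, groups=c, act=None, rng=rng)

    def forward(self, x):
        if x.shape[1] != self.c:
            raise ValueError(f"StarBlock expects {self.c} channels, got {x.shape[1]}")
        y = self.dw1(x)
        y = star_operation(y, self.f1, self.f2)
        y = self.fuse(y.relu6())
        y = self.dw2(y)
        return x + y


class RepConv(nn.Module):
    """Reparameterizable 3×3 convolution.

    Training form: parallel 3×3+BN and 1×1+BN branches whose outputs are
    summed.  :meth:`merge` folds each batch-norm into its branch, zero-pads
    the 1×1 kernel into the 3×3 centre, and adds the branches, giving one
    biased 3×3 convolution with identical forward behaviour.
    """

    def __init__(self, c: int, rng=None):
        super().__init__()
        self.c = c
        self.conv3 = nn.Conv2d(c, c, 3, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(c)
        self.conv1 = nn.Conv2d(c, c, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(c)
        self.merged: nn.Conv2d | None = None

    def forward(self, x):
        if self.merged is not None:
            return self.merged(x)
        return self.bn3(self.conv3(x)) + self.bn1(self.conv1(x))

    @staticmethod
    def _fold(conv: nn.Conv2d, bn: nn.BatchNorm2d):
        gamma, beta = bn.weight.data, bn.bias.data
        mean, var = bn._buffers["running_mean"], bn._buffers["running_var"]
        scale = gamma / np.sqrt(var + bn.eps)
        return conv.weight.data * scale[:, None, None, None], beta - mean * scale

    def merge(self) -> nn.Conv2d:
        if self.merged is not None:
            raise RuntimeError("RepConv is already merged")
        w3, b3 = self._fold(self.conv3, self.bn3)
        w1, b1 = self._fold(self.conv1, self.bn1)
        w = w3.copy()
        w[:, :, 1:2, 1:2] += w1
        fused = nn.Conv2d(self.c, self.c, 3, bias=True)
        fused.weight = Parameter(w)
        fused.bias = Parameter(b3 + b1)
        self.merged = fused
        return fused


class MergedRepConv(nn.Module):
    """Inference form of :class:`RepConv`: a single biased 3×3 convolution."""

    def __init__(self, fused: nn.Conv2d):
        super().__init__()
        self.conv = fused

    def forward(self, x):
        return self.conv(x)


class DRHead(nn.Module):
    """Partially coupled detection head.

    A shared stack alternating a depthwise 3×3 convolution (with BN) and a
    Rep-Conv feeds two small branches: a 1×1 classification convolution
    (``num_classes`` sigmoid logits per cell) and a 1×1 box-regression
    convolution emitting ``4*reg_max`` discrete offset-bin logits.
    """

    def __init__(self, c: int, num_classes: int, reg_max: int, rng=None):
        super().__init__()
        self.c, self.num_classes, self.reg_max = c, num_classes, reg_max
        self.shared_dw = ConvBN(c, c, 3, groups=c, act="silu", rng=rng)
        self.shared_rep = RepConv(c, rng=rng)
        self.act = nn.SiLU()
        self.cls_conv = nn.Conv2d(c, num_classes, 1, bias=True, rng=rng)
        self.box_conv = nn.Conv2d(c, 4 * reg_max, 1, bias=True, rng=rng)
        # start with low objectness so the background-dominated BCE is stable
        self.cls_conv.bias.data -= 4.0

    def forward(self, x):
        if x.shape[1] != self.c:
            raise ValueError(f"DR-head expects {self.c} channels, got {x.shape[1]}")
        y = self.shared_dw(x)
        y = self.act(self.shared_rep(y))
        return self.cls_conv(y), self.box_conv(y)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class VetStar(nn.Module):
    def __init__(self, plan: ChannelPlan, seed: int = 0):
        super().__init__()
        self.plan = plan
        rng = np.random.default_rng(seed)
        widths = [plan.stem_width, *plan.stage_widths]
        self.stem = ConvBN(3, plan.stem_width, 3, stride=plan.strides[0], rng=rng)
        stages = []
        for i, (cin, cout) in enumerate(zip(widths[:-1], widths[1:])):
            s = plan.strides[i + 1]
            k = 3 if s > 1 else 1  # stage 4 keeps stride 16: 1×1 transition
            stages.append(
                nn.Sequential(
                    ConvBN(cin, cout, k, stride=s, rng=rng),
                    StarBlock(cout, plan.star_expansion, rng=rng),
                )
            )
        self.stages = nn.Sequential(*stages)
        if plan.stage_widths[-1] != plan.head_width:
            raise ValueError("C4 width must match head width")
        self.head = DRHead(plan.head_width, plan.num_classes, plan.reg_max, rng=rng)
        self.is_reparameterized = False

    def features(self, x: Tensor) -> Tensor:
        side = x.shape[-1]
        if x.shape[-2] != side or side % 16:
            raise ValueError("input must be square with side divisible by 16")
        return self.stages(self.stem(x))

    def forward(self, x: Tensor):
        """Return (cls_logits, box_logits) tensors on the C4 grid."""
        return self.head(self.features(x))

    def predict_raw(self, images: np.ndarray) -> RawPrediction:
        """Eval-mode forward on an (N,3,H,W) float array in [0,1]."""
        self.eval()
        with no_grad():
            cls, box = self.forward(Tensor(images))
        return RawPrediction(
            cls_logits=np.moveaxis(cls.data, 1, -1),
            box_logits=np.moveaxis(box.data, 1, -1),
            stride=self.plan.c4_stride,
        )


def build_vetstar(plan: ChannelPlan | None = None, seed: int = 0) -> VetStar:
    """Instantiate VetStar (training form) with seeded initialization."""
    return VetStar(plan or ChannelPlan(), seed=seed)


def build_teacher(plan_large: ChannelPlan | None = None, seed: int = 0) -> VetStar:
    """A widened VetStar-family teacher (same single C4 head, same grid)."""
    plan_large = plan_large or ChannelPlan().widened(4)
    return VetStar(plan_large, seed=seed)


def widen_student(student: VetStar, factor: int = 4, noise: float = 0.0,
                  seed: int = 0) -> VetStar:
    """Function-preserving widening of a trained student into a teacher.

    Every channel is replicated ``factor`` times (conv outputs, batch-norm
    statistics) and fan-in weights are divided by ``factor``, so the widened
    model computes the same function as the student — including through the
    channelwise star products — before ``noise`` (relative scale) breaks the
    replication symmetry for fine-tuning.
    """
    if student.is_reparameterized:
        raise RuntimeError("widen before reparameterization")
    teacher = VetStar(student.plan.widened(factor), seed=seed)
    f = factor

    def pair_walk(s_mod, t_mod):
        for name, s_sub in s_mod._modules.items():
            yield s_sub, t_mod._modules[name]
            yield from pair_walk(s_sub, t_mod._modules[name])

    for s_sub, t_sub in pair_walk(student, teacher):
        if isinstance(s_sub, nn.Conv2d):
            w = s_sub.weight.data
            grow_out = t_sub.cout == s_sub.cout * f
            grow_in = t_sub.weight.data.shape[1] == w.shape[1] * f
            if grow_out:
                w = np.repeat(w, f, axis=0)
            if grow_in:
                w = np.repeat(w, f, axis=1) / f
            t_sub.weight.data[...] = w
            if s_sub.bias is not None:
                t_sub.bias.data[...] = np.repeat(s_sub.bias.data, f) if grow_out \
                    else s_sub.bias.data
        elif isinstance(s_sub, nn.BatchNorm2d):
            for attr in ("weight", "bias"):
                getattr(t_sub, attr).data[...] = np.repeat(getattr(s_sub, attr).data, f)
            for key in ("running_mean", "running_var"):
                t_sub._buffers[key][...] = np.repeat(s_sub._buffers[key], f)
    if noise:
        rng = np.random.default_rng(seed)
        for p in teacher.parameters():
            scale = float(np.std(p.data)) or 1.0
            p.data += rng.normal(0, noise * scale, p.data.shape).astype(np.float32)
    return teacher


def reparameterize(model: VetStar) -> VetStar:
    """Merge every RepConv into a single 3×3 convolution, in place.

    Requires finalized batch-norm statistics; refuses to merge twice.
    """
    if model.is_reparameterized:
        raise RuntimeError("model is already reparameterized")
    for mod in model.modules():
        for name, sub in list(mod._modules.items()):
            if isinstance(sub, RepConv):
                setattr(mod, name, MergedRepConv(sub.merge()))
    model.is_reparameterized = True
    model.eval()
    return model


# ---------------------------------------------------------------------------
# star-operation accounting
# ---------------------------------------------------------------------------

def star_term_count(d: int) -> int:
    """Number of distinct monomials f′ᵢf′ⱼ produced by the star operation.

    With the bias coordinate the feature has d+1 entries, so the symmetric
    products number (d+2)(d+1)/2 ≈ d²/2.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    return (d + 2) * (d + 1) // 2


# ---------------------------------------------------------------------------
# parameter / FLOPs ledger
# ---------------------------------------------------------------------------

def count_parameters(model: nn.Module) -> int:
    """Sum of trainable scalars over all layers."""
    return model.num_parameters()


def model_summary(model: VetStar, input_side: int = 640) -> ModelSummary:
    """Per-layer Params/FLOPs ledger.

    FLOPs use the multiply-add-counts-as-two convention
    ``2 · Cin/g · Cout · K² · H · W`` per convolution (H, W the output map),
    evaluated by tracing a forward pass at ``input_side``.
    """
    if input_side % 16:
        raise ValueError("input_side must be divisible by 16")
    records = []

    convs: list[tuple[str, nn.Conv2d]] = []
    bns: list[tuple[str, nn.BatchNorm2d]] = []

    def walk(mod, prefix=""):
        for name, sub in mod._modules.items():
            full = f"{prefix}{name}"
            if isinstance(sub, nn.Conv2d):
                convs.append((full, sub))
            elif isinstance(sub, nn.BatchNorm2d):
                bns.append((full, sub))
            walk(sub, full + ".")

    walk(model)
    # trace output sizes
    shapes: dict[int, tuple] = {}
    orig_forwards = {}
    model.eval()
    with no_grad():
        for _, conv in convs:
            shapes[id(conv)] = None
        x = Tensor(np.zeros((1, 3, input_side, input_side), dtype=np.float32))

        def hooked(conv):
            fwd = type(conv).forward

            def f(x_in):
                out = fwd(conv, x_in)
                shapes[id(conv)] = out.shape
                return out

            return f

        for _, conv in convs:
            orig_forwards[id(conv)] = conv.forward
            conv.forward = hooked(conv)
        try:
            model.forward(x)
        finally:
            for _, conv in convs:
                conv.forward = orig_forwards[id(conv)]

    total_flops = 0
    for name, conv in convs:
        shp = shapes[id(conv)]
        h, w = (shp[2], shp[3]) if shp is not None else (0, 0)
        flops = 2 * (conv.cin // conv.groups) * conv.cout * conv.k**2 * h * w
        params = conv.num_parameters()
        records.append((name, params, conv.cin, conv.cout, conv.k, h, w, flops))
        total_flops += flops
    for name, bn in bns:  # affine scale/shift; no conv-style FLOPs term
        records.append((name, bn.num_parameters(), bn.c, bn.c, 0, 0, 0, 0))
    summary = ModelSummary(layers=records, parameters=count_parameters(model), flops=total_flops)
    assert summary.parameters == sum(r[1] for r in records)
    return summary


def count_flops(model: VetStar, input_side: int = 640) -> int:
    return model_summary(model, input_side).flops
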
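"""Architecture contracts: star operation, reparameterization, budgets."""

import itertools

import numpy as np
import pytest

from vetstar._core import nn
from vetstar._core.tensor import Tensor, no_grad
from vetstar.model import (
    ChannelPlan,
    RepConv,
    StarBlock,
    build_teacher,
    build_vetstar,
    count_flops,
    count_parameters,
    model_summary,
    reparameterize,
    star_operation,
    star_term_count,
    widen_student,
)


# ---------------------------------------------------------------------------
# star operation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("d,e", [(1, 1), (3, 2), (5, 3), (8, 2)])
def test_star_operation_matches_bilinear_double_sum(d, e, rng):
    """The channelwise product of two biased linear maps equals the explicit
    double sum over the bias-augmented feature, at every position."""
    f1 = nn.Conv2d(d, e, 1, bias=True, rng=rng)
    f2 = nn.Conv2d(d, e, 1, bias=True, rng=rng)
    x = rng.standard_normal((1, d, 2, 2)).astype(np.float32)
    out = star_operation(Tensor(x), f1, f2).data
    m1 = np.concatenate([f1.weight.data[:, :, 0, 0], f1.bias.data[:, None]], axis=1)
    m2 = np.concatenate([f2.weight.data[:, :, 0, 0], f2.bias.data[:, None]], axis=1)
    for h in range(2):
        for w in range(2):
            faug = np.append(x[0, :, h, w], 1.0)
            for c in range(e):
                expected = sum(
                    m1[c, i] * m2[c, j] * faug[i] * faug[j]
                    for i in range(d + 1)
                    for j in range(d + 1)
                )
                assert out[0, c, h, w] == pytest.approx(expected, rel=1e-4, abs=1e-5)


def test_star_zero_feature_zero_bias_gives_zero():
    f1 = nn.Conv2d(3, 2, 1, bias=True)
    f2 = nn.Conv2d(3, 2, 1, bias=True)
    f1.bias.data[:] = 0
    f2.bias.data[:] = 0
    out = star_operation(Tensor(np.zeros((1, 3, 4, 4), np.float32)), f1, f2)
    np.testing.assert_array_equal(out.data, 0)


@pytest.mark.parametrize("d", range(1, 9))
def test_star_term_count_matches_monomial_enumeration(d):
    """Count distinct f′ᵢf′ⱼ monomials by brute enumeration over index pairs."""
    monomials = {frozenset({i, j}) for i, j in
                 itertools.product(range(d + 1), repeat=2)}
    assert star_term_count(d) == len(monomials)


def test_star_term_count_examples_and_domain():
    assert star_term_count(3) == 10
    assert star_term_count(1) == 3
    with pytest.raises(ValueError):
        star_term_count(0)


def test_starblock_shape_preserving_and_channel_check(rng):
    blk = StarBlock(8, expansion=2, rng=rng)
    x = Tensor(rng.random((2, 8, 12, 12)).astype(np.float32))
    y = blk(x)
    assert y.shape == x.shape
    with pytest.raises(ValueError):
        blk(Tensor(np.zeros((1, 4, 12, 12), np.float32)))


# ---------------------------------------------------------------------------
# reparameterization
# ---------------------------------------------------------------------------

def _finalize_bn(module, rng):
    module.train()
    for _ in range(3):
        module(Tensor(rng.standard_normal((4, 32, 8, 8)).astype(np.float32)))
    module.eval()


def test_repconv_merge_equivalence(rng):
    rc = RepConv(32, rng=rng)
    _finalize_bn(rc, rng)
    x = Tensor(rng.standard_normal((2, 32, 9, 9)).astype(np.float32))
    with no_grad():
        y_train = rc(x)
        y_merged = rc.merge()(x)
    assert np.abs(y_train.data - y_merged.data).max() <= 1e-5


def test_repconv_zero_pointwise_branch_reduces_to_folded_3x3(rng):
    rc = RepConv(32, rng=rng)
    rc.conv1.weight.data[:] = 0
    _finalize_bn(rc, rng)
    merged = rc.merge()
    w3, b3 = RepConv._fold(rc.conv3, rc.bn3)
    _, b1 = RepConv._fold(rc.conv1, rc.bn1)
    np.testing.assert_allclose(merged.weight.data, w3, rtol=1e-6)
    np.testing.assert_allclose(merged.bias.data, b3 + b1, rtol=1e-6)


def test_merged_repconv_parameter_count():
    rc = RepConv(32)
    merged = rc.merge()
    assert merged.num_parameters() == 32 * 32 * 9 + 32  # 9248


def test_full_model_reparameterization_equivalence(rng):
    model = build_vetstar(seed=1)
    model.train()
    for _ in range(2):
        model(Tensor(rng.random((2, 3, 64, 64)).astype(np.float32)))
    model.eval()
    x = Tensor(rng.random((2, 3, 64, 64)).astype(np.float32))
    with no_grad():
        cls_a, box_a = model(x)
    reparameterize(model)
    with no_grad():
        cls_b, box_b = model(x)
    assert np.abs(cls_a.data - cls_b.data).max() <= 1e-5
    assert np.abs(box_a.data - box_b.data).max() <= 1e-5
    with pytest.raises(RuntimeError):
        reparameterize(model)


# ---------------------------------------------------------------------------
# parameter / FLOPs accounting
# ---------------------------------------------------------------------------

def test_shared_head_layer_parameter_counts():
    model = build_vetstar()
    assert model.head.shared_dw.num_parameters() == 352  # 32·9 + 2·32
    assert model.head.shared_rep.num_parameters() == 10368  # (9216+64)+(1024+64)


def test_parameter_counter_agrees_with_enumeration():
    model = build_vetstar()
    manual = sum(p.data.size for _, p in model.named_parameters())
    assert count_parameters(model) == manual


def test_flops_formula_on_single_conv():
    class One(nn.Module):
        def __init__(self):
            super().__init__()
            self.conv = nn.Conv2d(4, 4, 1, pad=0, bias=False)

        def forward(self, x):
            return self.conv(x)

    # 2·Cin·Cout·K²·H·W = 2·4·4·1·2·2 = 128
    m = One()
    x = Tensor(np.zeros((1, 4, 2, 2), np.float32))
    with no_grad():
        out = m(x)
    flops = 2 * 4 * 4 * 1 * out.shape[2] * out.shape[3]
    assert flops == 128


def test_flops_linear_in_resolution():
    model = reparameterize(build_vetstar())
    f320 = count_flops(model, 320)
    f640 = count_flops(model, 640)
    assert f640 == 4 * f320


def test_model_summary_totals_are_sums():
    s = model_summary(build_vetstar(), 256)
    assert s.parameters == sum(r[1] for r in s.layers)
    assert s.flops == sum(r[7] for r in s.layers)


# ---------------------------------------------------------------------------
# build contracts
# ---------------------------------------------------------------------------

def test_seeded_build_reproducible():
    a, b = build_vetstar(seed=7), build_vetstar(seed=7)
    for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert ka == kb
        np.testing.assert_array_equal(pa.data, pb.data)


def test_forward_grid_and_batch_contract(rng):
    model = build_vetstar().eval()
    raw = model.predict_raw(rng.random((3, 3, 512, 512)).astype(np.float32))
    assert raw.cls_logits.shape == (3, 32, 32, 2)
    assert raw.box_logits.shape == (3, 32, 32, 64)
    assert raw.stride == 16
    again = model.predict_raw(np.zeros((1, 3, 256, 256), np.float32))
    once_more = model.predict_raw(np.zeros((1, 3, 256, 256), np.float32))
    np.testing.assert_array_equal(again.cls_logits, once_more.cls_logits)


def test_forward_rejects_bad_geometry():
    model = build_vetstar()
    with pytest.raises(ValueError):
        model.features(Tensor(np.zeros((1, 3, 100, 100), np.float32)))
    with pytest.raises(ValueError):
        model.features(Tensor(np.zeros((1, 3, 128, 256), np.float32)))


def test_plan_validation():
    with pytest.raises(ValueError):
        ChannelPlan(stem_width=0)
    with pytest.raises(ValueError):
        ChannelPlan(strides=(2, 2, 2, 2, 2))  # C4 stride would be 32


def test_head_exclusivity_gradients_reach_backbone(rng):
    """A loss on the single head's outputs back-propagates into every stage."""
    model = build_vetstar(seed=0)
    cls_t, box_t = model(Tensor(rng.random((1, 3, 64, 64)).astype(np.float32)))
    (cls_t.sum() + box_t.sum()).backward()
    stem_grad = model.stem.conv.weight.grad
    assert stem_grad is not None and np.abs(stem_grad).sum() > 0
    for stage in model.stages:
        g = stage[0].conv.weight.grad
        assert g is not None and np.abs(g).sum() > 0
    heads = [m for m in model.modules() if type(m).__name__ == "DRHead"]
    assert len(heads) == 1


def test_teacher_is_wider_same_grid(rng):
    student = build_vetstar(seed=0)
    teacher = build_teacher(seed=0)
    assert count_parameters(teacher) > count_parameters(student)
    x = rng.random((1, 3, 128, 128)).astype(np.float32)
    rs, rt = student.predict_raw(x), teacher.predict_raw(x)
    assert rs.cls_logits.shape == rt.cls_logits.shape
    assert rs.box_logits.shape == rt.box_logits.shape


def test_widening_preserves_function(rng):
    student = build_vetstar(seed=3)
    student.train()
    student(Tensor(rng.random((2, 3, 64, 64)).astype(np.float32)))
    wide = widen_student(student, factor=4, noise=0.0)
    student.eval()
    wide.eval()
    x = rng.random((1, 3, 96, 96)).astype(np.float32)
    rs, rw = student.predict_raw(x), wide.predict_raw(x)
    np.testing.assert_allclose(rs.cls_logits, rw.cls_logits, atol=2e-4)
    np.testing.assert_allclose(rs.box_logits, rw.box_logits, atol=2e-4)


def test_checkpoint_roundtrip(tmp_path):
    model = build_vetstar(seed=2)
    path = tmp_path / "w.npz"
    model.save(path)
    other = build_vetstar(seed=9)
    other.load(path)
    for (_, pa), (_, pb) in zip(model.named_parameters(), other.named_parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)
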
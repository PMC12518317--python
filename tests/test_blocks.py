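"""Unit and property tests for the building blocks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnatnet.blocks import (ABlock, AnC2f, Bottleneck, C2f, C2S2, ConfigError,
                            ConvUnit, DWClassify, GhostBottleneck, GhostUnit,
                            ShapeError, c2s2_split)
from cnatnet.complexity import oracle_param_count
from cnatnet.nn import Identity, Module

from .helpers import naive_conv_unit_eval


def _x(rng, c, h=6, w=6, n=2):
    return rng.normal(size=(n, c, h, w)).astype(np.float32)


class Zero(Module):
    def forward(self, x):
        return np.zeros_like(x)

    def backward(self, dy):
        return np.zeros_like(dy)


# ---------------------------------------------------------------------------
# channel split
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("channels, expected", [(64, (32, 32)), (5, (3, 2)),
                                                (2, (1, 1)), (7, (4, 3))])
def test_split_widths_follow_ceil_floor_rule(rng, channels, expected):
    x1, x2 = c2s2_split(_x(rng, channels))
    assert (x1.shape[1], x2.shape[1]) == expected


@given(st.integers(min_value=2, max_value=33))
def test_split_concat_roundtrip_is_exact(channels):
    x = np.random.default_rng(channels).normal(
        size=(2, channels, 4, 4)).astype(np.float32)
    x1, x2 = c2s2_split(x)
    assert x1.shape[2:] == x.shape[2:] and x2.shape[2:] == x.shape[2:]
    assert np.array_equal(np.concatenate([x1, x2], axis=1), x)


def test_split_rejects_single_channel(rng):
    with pytest.raises(ConfigError):
        c2s2_split(_x(rng, 1))


# ---------------------------------------------------------------------------
# C2S2
# ---------------------------------------------------------------------------

def test_c2s2_identity_branches_reconcatenate_input(rng):
    block = C2S2(8, 8, n_units=1)
    block.cv_in = Identity()
    block.branch1 = Identity()
    block.branch2 = Identity()
    block.merge = Identity()
    x = _x(rng, 8)
    assert np.array_equal(block(x), x)


def test_c2s2_premerge_concat_conserves_branch_channels(rng):
    block = C2S2(8, 16, n_units=1, merge_channels=10).eval()
    x1, x2 = c2s2_split(block.cv_in(_x(rng, 8)))
    b1, b2 = block.branch1(x1), block.branch2(x2)
    assert b1.shape[1] + b2.shape[1] == block.merge_channels == 10
    assert block.merge.conv.c_in == 10


def test_c2s2_channel_mismatch_reports_both_counts(rng):
    block = C2S2(8, 8)
    with pytest.raises(ShapeError, match="8.*received 12"):
        block(_x(rng, 12))


@pytest.mark.parametrize("bad", [dict(n_units=0), dict(stride=3),
                                 dict(kernel=4), dict(merge_channels=99),
                                 dict(unit_kind="fancy")])
def test_c2s2_invalid_configuration(bad):
    with pytest.raises(ConfigError):
        C2S2(8, 8, **bad)


def test_c2s2_matches_straight_line_reference_composition(rng):
    """Forward pass equals an explicit split -> branch stacks -> concat ->
    merge composition done with naive per-pixel convolution arithmetic."""
    block = C2S2(16, 16, n_units=1, unit_kind="standard",
                 rng=np.random.default_rng(5)).eval()
    for p in block.parameters():
        p.data = p.data.astype(np.float64)
    x = rng.normal(size=(1, 16, 8, 8))
    got = block(x)

    xd = x.astype(np.float64)
    y = naive_conv_unit_eval(xd, block.cv_in)
    x1, x2 = y[:, :8], y[:, 8:]
    outs = []
    for half, branch in ((x1, block.branch1), (x2, block.branch2)):
        unit = branch[0]          # standard bottleneck, residual
        z = naive_conv_unit_eval(half, unit.cv1)
        z = naive_conv_unit_eval(z, unit.cv2)
        z = half + z
        outs.append(naive_conv_unit_eval(z, branch[1]))  # compression conv
    want = naive_conv_unit_eval(np.concatenate(outs, axis=1), block.merge)
    assert np.abs(got - want).max() < 1e-6


def test_c2s2_stride2_halves_spatial_dims(rng):
    block = C2S2(8, 8, stride=2).eval()
    assert block(_x(rng, 8, 8, 8)).shape == (2, 8, 4, 4)


# ---------------------------------------------------------------------------
# ABlock / AnC2f
# ---------------------------------------------------------------------------

def test_ablock_zero_gate_halves_input(rng):
    ab = ABlock(4)
    ab.gate.weight.data[...] = 0.0
    ab.gate.bias.data[...] = 0.0
    x = _x(rng, 4)
    assert np.allclose(ab(x), 0.5 * x, atol=0, rtol=0)


def test_ablock_saturated_gate_passes_input_through(rng):
    ab = ABlock(4)
    ab.gate.weight.data[...] = 0.0
    ab.gate.bias.data[...] = 20.0
    x = _x(rng, 4) + 1.0
    assert np.abs(ab(x) / x - 1.0).max() < 1e-6


def test_ablock_zero_input_gives_zero_output(rng):
    ab = ABlock(4, rng=rng)
    x = np.zeros((2, 4, 5, 5), np.float32)
    assert np.array_equal(ab(x), x)


def test_ablock_gate_strictly_inside_unit_interval(rng):
    ab = ABlock(6)
    ab.gate.weight.data[...] = rng.normal(size=ab.gate.weight.data.shape)
    a = ab.attention(_x(rng, 6) * 10)
    assert (a > 0).all() and (a < 1).all()
    assert a.std() > 0  # input-dependent, not a constant gate


def test_ablock_channel_mismatch_raises(rng):
    from cnatnet.nn import Conv2d
    ab = ABlock(4)
    ab.gate = Conv2d(4, 5, 1, bias=True)
    with pytest.raises(ShapeError):
        ab(_x(rng, 4))


def test_anc2f_zeroed_main_branch_is_identity(rng):
    unit = AnC2f(6, 6, n_ablocks=2)
    unit.blocks = Zero()
    x = _x(rng, 6)
    assert np.array_equal(unit(x), x)


def test_anc2f_single_zero_gate_gives_one_and_a_half_x(rng):
    unit = AnC2f(6, 6, n_ablocks=1)
    ab = unit.blocks[0]
    ab.gate.weight.data[...] = 0.0
    ab.gate.bias.data[...] = 0.0
    x = _x(rng, 6)
    assert np.allclose(unit(x), 1.5 * x, rtol=1e-6, atol=1e-7)


def test_anc2f_stride1_preserves_channel_count(rng):
    unit = AnC2f(6, 6, n_ablocks=2, rng=rng).eval()
    assert unit(_x(rng, 6)).shape == (2, 6, 6, 6)


def test_anc2f_requires_at_least_one_ablock():
    with pytest.raises(ConfigError):
        AnC2f(6, 6, n_ablocks=0)


# ---------------------------------------------------------------------------
# bottlenecks
# ---------------------------------------------------------------------------

def _zero_interior(module):
    for m in module.modules():
        if hasattr(m, "weight") and not isinstance(m, Identity):
            m.weight.data[...] = 0.0


def test_ghost_bottleneck_zeroed_interior_is_identity(rng):
    gb = GhostBottleneck(8, 8)
    _zero_interior(gb)
    x = _x(rng, 8)
    assert np.array_equal(gb(x), x)


def test_bottleneck_zeroed_interior_is_identity(rng):
    b = Bottleneck(8, 8)
    _zero_interior(b)
    x = _x(rng, 8)
    assert np.array_equal(b(x), x)


def test_ghost_unit_cheaper_than_standard_bottleneck():
    ghost = GhostBottleneck(16, 16)
    standard = Bottleneck(16, 16)
    assert oracle_param_count(ghost) < oracle_param_count(standard)


def test_ghost_bottleneck_shape_contract(rng):
    gb = GhostBottleneck(6, 10, rng=rng).eval()
    assert gb(_x(rng, 6)).shape[1] == 10
    with pytest.raises(ConfigError):
        GhostBottleneck(6, 10, stride=3)
    with pytest.raises(ConfigError):
        GhostUnit(6, 7)


# ---------------------------------------------------------------------------
# DWClassify
# ---------------------------------------------------------------------------

def test_dwclassify_logit_length_matches_classes(rng):
    head = DWClassify(8, 2, rng=rng).eval()
    assert head(_x(rng, 8)).shape == (2, 2)


def test_dwclassify_constant_input_pooling_invariance(rng):
    head = DWClassify(8, 3, rng=rng).eval()
    a = np.full((2, 8, 4, 4), 1.3, np.float32)
    b = np.full((2, 8, 12, 12), 1.3, np.float32)
    assert np.allclose(head(a), head(b), atol=1e-5)


def test_dwclassify_zero_network_gives_uniform_probabilities(rng):
    head = DWClassify(8, 4)
    for p in head.parameters():
        p.data[...] = 0.0
    logits = head(_x(rng, 8))
    assert np.array_equal(logits, np.zeros_like(logits))
    probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    assert np.allclose(probs, 0.25)


def test_dwclassify_rejects_single_class():
    with pytest.raises(ConfigError):
        DWClassify(8, 1)


# ---------------------------------------------------------------------------
# cross-block invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("factory", [
    lambda r: ConvUnit(8, 8, 3, rng=r),
    lambda r: Bottleneck(8, 8, rng=r),
    lambda r: GhostBottleneck(8, 8, rng=r),
    lambda r: C2S2(8, 8, n_units=2, rng=r),
    lambda r: C2f(8, 8, n=2, n_ablocks=2, rng=r),
    lambda r: AnC2f(8, 8, n_ablocks=3, rng=r),
    lambda r: DWClassify(8, 2, rng=r),
], ids=["conv", "bottleneck", "ghost", "c2s2", "c2f_attn", "anc2f", "dwc"])
def test_forward_outputs_finite_on_gaussian_inputs(factory, rng):
    block = factory(np.random.default_rng(9))
    x = _x(rng, 8)
    for mode in (True, False):
        block.train(mode)
        assert np.isfinite(block(x)).all()


def test_gradients_match_finite_differences(rng):
    """Backward passes of the composite blocks agree with central
    finite differences (double precision, random probes)."""
    probes = np.random.default_rng(31)
    for factory in (lambda r: C2S2(8, 8, n_units=1, rng=r),
                    lambda r: C2f(8, 8, n=1, n_ablocks=1, rng=r),
                    lambda r: DWClassify(6, 3, rng=r)):
        block = factory(np.random.default_rng(17))
        for p in block.parameters():
            p.data = p.data.astype(np.float64)
            p.grad = p.grad.astype(np.float64)
        c = 6 if isinstance(block, DWClassify) else 8
        x = probes.normal(size=(2, c, 5, 5))
        y = block(x)
        dy = probes.normal(size=y.shape)
        block.zero_grad()
        dx = block.backward(dy)
        eps = 1e-5
        flat = x.reshape(-1)
        for idx in probes.choice(flat.size, size=5, replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = float((block(x) * dy).sum())
            flat[idx] = orig - eps
            down = float((block(x) * dy).sum())
            flat[idx] = orig
            num = (up - down) / (2 * eps)
            ana = dx.reshape(-1)[idx]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num))
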
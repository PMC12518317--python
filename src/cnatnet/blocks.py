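"""Building blocks of the convolution-attention hybrid classifier.

Three bespoke blocks form the contribution:

* :class:`C2S2` — cascaded split-and-concatenate extractor: a stem conv, a
  two-way channel split, per-branch stacks of (Ghost)Bottleneck units, a
  per-branch compression conv, concatenation, and a 1x1 merge projection.
* :class:`ABlock` / :class:`AnC2f` — sigmoid-gated spatial attention
  ``sigma(Conv1x1(F)) * F`` stacked n times on a main branch and fused with an
  identity shortcut by element-wise addition.
* :class:`DWClassify` — depthwise k x k filtering, pointwise 1x1 mixing down
  to class logits, then global average pooling (pool last).

:class:`C2f` is the attention-free cross-stage-partial fusion block of the
lineage these designs extend; with ``n_ablocks > 0`` each of its bottlenecks
is followed by a residual attention stack, giving the attention-enhanced
fusion stage.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Identity, Linear, Module,
                 Sequential, SiLU, Sigmoid, _sigmoid)

__all__ = [
    "ConfigError", "ShapeError", "c2s2_split", "ConvUnit", "Bottleneck",
    "GhostUnit", "GhostBottleneck", "C2S2", "ABlock", "AnC2f", "C2f",
    "DWClassify", "DenseHead",
]


class ConfigError(ValueError):
    """Raised for structurally invalid block configurations."""


class ShapeError(ValueError):
    """Raised when an input's shape contradicts a block's configuration."""


def _default_rng(rng):
    return rng if rng is not None else np.random.default_rng(0)


def c2s2_split(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Channel-wise split into two branches.

    Odd channel counts give the extra channel to the first branch
    (ceil/floor rule); concatenating the halves recovers the input exactly.
    """
    c = x.shape[1]
    if c < 2:
        raise ConfigError(f"cannot split {c} channel(s) into two branches")
    c1 = math.ceil(c / 2)
    return x[:, :c1].copy(), x[:, c1:].copy()


class ConvUnit(Module):
    """conv -> batch norm -> SiLU, the standard unit of the backbone.

    ``fuse()`` folds the batch norm into the convolution (which then gains a
    bias), the usual deployment-time transformation; the activation is kept.
    """

    def __init__(self, c_in, c_out, k=1, stride=1, groups=1, act=True,
                 pad_mode="zeros", rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride=stride, groups=groups,
                           bias=False, pad_mode=pad_mode,
                           rng=_default_rng(rng))
        self.bn = BatchNorm2d(c_out)
        self.act = SiLU() if act else Identity()
        self.fused = False

    def forward(self, x):
        if self.fused:
            return self.act(self.conv(x))
        return self.act(self.bn(self.conv(x)))

    def backward(self, dy):
        dy = self.act.backward(dy)
        if not self.fused:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy)

    def fuse(self) -> None:
        if self.fused:
            return
        bn = self.bn
        scale = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
        self.conv.weight.data *= scale[:, None, None, None]
        from .nn import Parameter
        self.conv.bias = Parameter(bn.beta.data - bn.running_mean * scale)
        del self._modules["bn"]
        object.__setattr__(self, "bn", None)
        self.fused = True


class Bottleneck(Module):
    """Two 3x3 conv units with an optional residual connection."""

    def __init__(self, c_in, c_out, shortcut=True, k=3, rng=None):
        super().__init__()
        rng = _default_rng(rng)
        self.cv1 = ConvUnit(c_in, c_out, k, rng=rng)
        self.cv2 = ConvUnit(c_out, c_out, k, rng=rng)
        self.add = bool(shortcut and c_in == c_out)

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def backward(self, dy):
        dx = self.cv1.backward(self.cv2.backward(dy))
        return dx + dy if self.add else dx


class GhostUnit(Module):
    """Ghost convolution: half the output channels come from a primary conv,
    the other half from a cheap depthwise 3x3 transform of that primary half.
    """

    def __init__(self, c_in, c_out, k=1, rng=None):
        super().__init__()
        if c_out % 2:
            raise ConfigError(f"ghost unit needs an even output width, "
                              f"got {c_out}")
        rng = _default_rng(rng)
        half = c_out // 2
        self.primary = ConvUnit(c_in, half, k, rng=rng)
        self.cheap = ConvUnit(half, half, 3, groups=half, rng=rng)
        self.half = half

    def forward(self, x):
        p = self.primary(x)
        q = self.cheap(p)
        return np.concatenate([p, q], axis=1)

    def backward(self, dy):
        dp, dq = dy[:, :self.half], dy[:, self.half:]
        dp = dp + self.cheap.backward(dq)
        return self.primary.backward(dp)


class GhostBottleneck(Module):
    """Ghost expansion (3x3) then ghost projection (1x1), with a residual
    connection at stride 1 and matching widths. Cheaper than a standard
    bottleneck at the same widths.
    """

    def __init__(self, c_in, c_out, stride=1, rng=None):
        super().__init__()
        if stride not in (1, 2):
            raise ConfigError(f"stride must be 1 or 2, got {stride}")
        rng = _default_rng(rng)
        self.g1 = GhostUnit(c_in, c_out, 3, rng=rng)
        self.down = (ConvUnit(c_out, c_out, 3, stride=2, groups=c_out,
                              rng=rng) if stride == 2 else None)
        self.g2 = GhostUnit(c_out, c_out, 1, rng=rng)
        self.add = bool(stride == 1 and c_in == c_out)

    def forward(self, x):
        y = self.g1(x)
        if self.down is not None:
            y = self.down(y)
        y = self.g2(y)
        return x + y if self.add else y

    def backward(self, dy):
        d = self.g2.backward(dy)
        if self.down is not None:
            d = self.down.backward(d)
        dx = self.g1.backward(d)
        return dx + dy if self.add else dx


def _make_unit(kind: str, width: int, rng) -> Module:
    if kind == "ghost":
        return GhostBottleneck(width, width, rng=rng)
    if kind == "standard":
        return Bottleneck(width, width, rng=rng)
    raise ConfigError(f"unknown unit kind {kind!r}; expected ghost|standard")


class C2S2(Module):
    """Cascaded split-and-concatenate block.

    stem conv (1x1, or 3x3/stride-2 for the downsampling variant) ->
    ceil/floor channel split -> per-branch unit stacks -> per-branch
    compression to half the merge width -> concat -> 1x1 merge projection.
    """

    def __init__(self, in_channels, out_channels, n_units=1,
                 unit_kind="ghost", merge_channels=None, kernel=3,
                 stride=1, rng=None):
        super().__init__()
        if n_units < 1:
            raise ConfigError(f"n_units must be >= 1, got {n_units}")
        if stride not in (1, 2):
            raise ConfigError(f"stride must be 1 or 2, got {stride}")
        if kernel % 2 == 0:
            raise ConfigError(f"kernel must be odd, got {kernel}")
        rng = _default_rng(rng)
        merge_channels = (out_channels // 2 if merge_channels is None
                          else merge_channels)
        if merge_channels > out_channels:
            raise ConfigError(f"merge_channels {merge_channels} exceeds "
                              f"out_channels {out_channels}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.merge_channels = merge_channels
        # stem: standard conv extracting base features before the split
        self.cv_in = ConvUnit(in_channels, out_channels,
                              3 if stride == 2 else 1, stride=stride, rng=rng)
        c1 = math.ceil(out_channels / 2)
        c2 = out_channels - c1
        m1 = math.ceil(merge_channels / 2)
        m2 = merge_channels - m1
        self.split_widths = (c1, c2)
        self.branch1 = Sequential(
            *[_make_unit(unit_kind, c1, rng) for _ in range(n_units)],
            ConvUnit(c1, m1, 1, rng=rng))
        self.branch2 = Sequential(
            *[_make_unit(unit_kind, c2, rng) for _ in range(n_units)],
            ConvUnit(c2, m2, 1, rng=rng))
        self.merge = ConvUnit(merge_channels, out_channels, 1, rng=rng)

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} input channels, "
                             f"received {x.shape[1]}")
        y = self.cv_in(x)
        x1, x2 = c2s2_split(y)
        b1 = self.branch1(x1)
        b2 = self.branch2(x2)
        self._split_at = b1.shape[1]
        return self.merge(np.concatenate([b1, b2], axis=1))

    def backward(self, dy):
        dcat = self.merge.backward(dy)
        d1 = self.branch1.backward(dcat[:, :self._split_at])
        d2 = self.branch2.backward(dcat[:, self._split_at:])
        return self.cv_in.backward(np.concatenate([d1, d2], axis=1))


class ABlock(Module):
    """Sigmoid-gated spatial attention: ``sigma(gate(x)) * x``.

    The gate is a 1x1 convolution (with bias) producing one weight per
    position and channel, so the modulation is spatially adaptive and every
    attention weight lies strictly in (0, 1).
    """

    def __init__(self, channels, gate_bias_init: float = 1.5, rng=None):
        super().__init__()
        self.gate = Conv2d(channels, channels, 1, bias=True,
                           rng=_default_rng(rng))
        # near-pass-through start: zero gate weights with a positive bias
        # open the gates (~0.82), so the stack does not inject random
        # multiplicative noise before training shapes it
        self.gate.weight.data[...] = 0.0
        self.gate.bias.data[...] = gate_bias_init

    @staticmethod
    def _gate_values(a: np.ndarray) -> np.ndarray:
        # keep the weights strictly inside (0, 1) even where the sigmoid
        # saturates at working precision
        info = np.finfo(a.dtype)
        return np.clip(_sigmoid(a), info.tiny, 1.0 - info.epsneg)

    def attention(self, x: np.ndarray) -> np.ndarray:
        """The gate values for ``x`` (no caching; for inspection)."""
        return self._gate_values(self.gate(x))

    def forward(self, x):
        a = self.gate(x)
        if a.shape[1] != x.shape[1]:
            raise ShapeError(f"gate produced {a.shape[1]} channels for a "
                             f"{x.shape[1]}-channel input")
        s = self._gate_values(a)
        self._cache = (x, s)
        return s * x

    def backward(self, dy):
        x, s = self._cache
        da = dy * x * s * (1.0 - s)
        return dy * s + self.gate.backward(da)


class AnC2f(Module):
    """Residual attention unit: shortcut + n stacked ABlocks on a main branch.

    When ``in_channels != out_channels`` a 1x1 conv unit first projects the
    input; the shortcut then carries the projected features, so main-branch
    and shortcut shapes always agree.
    """

    def __init__(self, in_channels, out_channels, n_ablocks=2,
                 use_shortcut=True, rng=None):
        super().__init__()
        if n_ablocks < 1:
            raise ConfigError(f"n_ablocks must be >= 1, got {n_ablocks}")
        rng = _default_rng(rng)
        self.in_channels = in_channels
        self.use_shortcut = use_shortcut
        self.proj = (Identity() if in_channels == out_channels
                     else ConvUnit(in_channels, out_channels, 1, rng=rng))
        self.blocks = Sequential(*[ABlock(out_channels, rng=rng)
                                   for _ in range(n_ablocks)])

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} input channels, "
                             f"received {x.shape[1]}")
        f = self.proj(x)
        main = self.blocks(f)
        return f + main if self.use_shortcut else main

    def backward(self, dy):
        df = self.blocks.backward(dy)
        if self.use_shortcut:
            df = df + dy
        return self.proj.backward(df)


class _AttnUnit(Module):
    """Bottleneck followed by a residual attention stack (fusion stage unit)."""

    def __init__(self, c, n_ablocks, rng=None):
        super().__init__()
        self.bottleneck = Bottleneck(c, c, rng=rng)
        self.attn = AnC2f(c, c, n_ablocks=n_ablocks, rng=rng)

    def forward(self, x):
        return self.attn(self.bottleneck(x))

    def backward(self, dy):
        return self.bottleneck.backward(self.attn.backward(dy))


class C2f(Module):
    """Cross-stage-partial fusion: split after a 1x1 conv, chain n units on
    one path, concatenate every intermediate, project back down.

    ``n_ablocks=0`` is the plain attention-free block; ``n_ablocks>=1``
    follows every bottleneck with a residual sigmoid-gated attention stack,
    which is the attention-enhanced fusion stage of the full network.
    """

    def __init__(self, c_in, c_out, n=1, shortcut=True, n_ablocks=0,
                 rng=None):
        super().__init__()
        rng = _default_rng(rng)
        c = c_out // 2
        self.c = c
        self.cv1 = ConvUnit(c_in, 2 * c, 1, rng=rng)
        if n_ablocks > 0:
            units = [_AttnUnit(c, n_ablocks, rng=rng) for _ in range(n)]
        else:
            units = [Bottleneck(c, c, shortcut=shortcut, rng=rng)
                     for _ in range(n)]
        self.units = Sequential(*units)
        self.cv2 = ConvUnit((2 + n) * c, c_out, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        ys = [y[:, :self.c].copy(), y[:, self.c:].copy()]
        for u in self.units.layers:
            ys.append(u(ys[-1]))
        return self.cv2(np.concatenate(ys, axis=1))

    def backward(self, dy):
        dcat = self.cv2.backward(dy)
        c = self.c
        grads = [dcat[:, i * c:(i + 1) * c].copy()
                 for i in range(2 + len(self.units))]
        for i in range(len(self.units) - 1, -1, -1):
            grads[i + 1] += self.units[i].backward(grads[i + 2])
        dy1 = np.concatenate(grads[:2], axis=1)
        return self.cv1.backward(dy1)


class DWClassify(Module):
    """Depthwise-separable classification head.

    depthwise k x k (per-channel spatial filtering) -> norm/act ->
    pointwise 1x1 down to ``num_classes`` -> global average pool, returning
    one logit vector per batch item. Pooling last keeps the pointwise stage
    operating on the full H x W map.
    """

    def __init__(self, in_channels, num_classes, kernel=3, rng=None):
        super().__init__()
        if num_classes < 2:
            raise ConfigError(f"num_classes must be >= 2, got {num_classes}")
        if kernel % 2 == 0:
            raise ConfigError(f"kernel must be odd, got {kernel}")
        rng = _default_rng(rng)
        self.in_channels = in_channels
        self.num_classes = num_classes
        # replicate padding keeps spatially constant maps constant, so the
        # pooled logits are independent of the input's H x W in that case
        self.dw = ConvUnit(in_channels, in_channels, kernel,
                           groups=in_channels, pad_mode="replicate", rng=rng)
        self.pw = Conv2d(in_channels, num_classes, 1, bias=True, rng=rng)
        self.pool = GlobalAvgPool()

    def forward(self, x):
        if x.shape[1] != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} input channels, "
                             f"received {x.shape[1]}")
        return self.pool(self.pw(self.dw(x)))

    def backward(self, dy):
        return self.dw.backward(self.pw.backward(self.pool.backward(dy)))


class DenseHead(Module):
    """Dense convolutional classification head of the baseline: a 1x1 conv
    unit widening to ``hidden`` channels, global average pooling, and a fully
    connected layer to the class logits.
    """

    def __init__(self, in_channels, num_classes, hidden=1280, rng=None):
        super().__init__()
        if num_classes < 2:
            raise ConfigError(f"num_classes must be >= 2, got {num_classes}")
        rng = _default_rng(rng)
        self.conv = ConvUnit(in_channels, hidden, 1, rng=rng)
        self.pool = GlobalAvgPool()
        self.fc = Linear(hidden, num_classes, bias=True, rng=rng)

    def forward(self, x):
        return self.fc(self.pool(self.conv(x)))

    def backward(self, dy):
        return self.conv.backward(self.pool.backward(self.fc.backward(dy)))
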
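"""Analytic parameter and FLOP accounting, with a brute-force oracle.

The closed-form counts cover convolution weights (plus declared biases);
normalisation scale/shift parameters are deliberately excluded from the
analytic formulas, matching the usual way such budgets are quoted. The
enumeration oracle (:func:`oracle_param_count`) instead counts *every*
learnable scalar of an assembled network, so the two agree exactly only in
the bias-free, normalisation-free regime — :func:`profile_network` reports
both side by side.

FLOPs are counted as multiply-accumulates (products only, no factor 2) and
rendered in B = 1e9; parameters in M = 1e6, both to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .nn import Conv2d, Linear, Module

__all__ = [
    "LayerSpec", "C2S2ParamSpec", "ComplexityReport",
    "params_c2s2", "params_dw", "flops_dw", "params_model", "flops_model",
    "oracle_param_count", "profile_network",
    "format_millions", "format_billions",
]


def _check_positive(**kwargs: int) -> None:
    for name, v in kwargs.items():
        if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class LayerSpec:
    """One convolutional layer for whole-model accounting.

    ``h``/``w`` are the *output* spatial dimensions of the layer.
    """

    c_in: int
    c_out: int
    k: int
    h: int = 1
    w: int = 1
    has_bias: bool = False

    def __post_init__(self):
        _check_positive(c_in=self.c_in, c_out=self.c_out, k=self.k,
                        h=self.h, w=self.w)


@dataclass(frozen=True)
class C2S2ParamSpec:
    """Widths entering the split-and-concatenate block's parameter formula."""

    c_split: int
    k: int
    c_merge: int
    c_out: int

    def __post_init__(self):
        _check_positive(c_split=self.c_split, k=self.k,
                        c_merge=self.c_merge, c_out=self.c_out)


def params_c2s2(spec: C2S2ParamSpec) -> int:
    """Parameter complexity of the split-and-concatenate block:
    ``sum_{i=1..2}(C_split * K^2 * C_split) + C_merge * C_out``.
    """
    branch = spec.c_split * spec.k * spec.k * spec.c_split
    return 2 * branch + spec.c_merge * spec.c_out


def params_dw(c_in: int, k: int, c_out: int) -> int:
    """Parameters of a depthwise-separable pair:
    ``C_in * K^2`` (depthwise) ``+ C_in * C_out`` (pointwise).
    """
    _check_positive(c_in=c_in, k=k, c_out=c_out)
    return c_in * k * k + c_in * c_out


def flops_dw(h: int, w: int, c_in: int, k: int, c_out: int) -> int:
    """Multiply-accumulates of the depthwise-separable pair over an
    ``H x W`` map; identically ``H * W * params_dw``.
    """
    _check_positive(h=h, w=w)
    return h * w * params_dw(c_in, k, c_out)


def params_model(layers: list[LayerSpec]) -> int:
    """Total learnable parameters over conv layers: weights plus declared
    biases, ``sum_l C_in K^2 C_out + [has_bias] C_out``.
    """
    total = 0
    for l in layers:
        total += l.c_in * l.k * l.k * l.c_out
        if l.has_bias:
            total += l.c_out
    return total


def flops_model(layers: list[LayerSpec]) -> int:
    """Total multiply-accumulates: ``sum_l H_l W_l C_in K^2 C_out``."""
    return sum(l.h * l.w * l.c_in * l.k * l.k * l.c_out for l in layers)


def oracle_param_count(network: Module) -> int:
    """Exact learnable-scalar count by exhaustive enumeration of every
    parameter tensor of an assembled network (weights, biases, norm
    scale/shift — everything the optimiser would update).
    """
    return sum(p.size for p in network.parameters())


# ---------------------------------------------------------------------------
# Whole-network profiling
# ---------------------------------------------------------------------------

@dataclass
class BlockCost:
    name: str
    params: int
    flops: int


@dataclass
class ComplexityReport:
    params_analytic: int
    params_oracle: int
    flops_analytic: int
    per_block: list[BlockCost] = field(default_factory=list)

    @property
    def params_m(self) -> float:
        return round(self.params_analytic / 1e6, 1)

    @property
    def flops_b(self) -> float:
        return round(self.flops_analytic / 1e9, 1)

    def as_dict(self) -> dict:
        return {
            "params_analytic": self.params_analytic,
            "params_oracle": self.params_oracle,
            "flops_analytic": self.flops_analytic,
            "params_rendered": format_millions(self.params_analytic),
            "flops_rendered": format_billions(self.flops_analytic),
            "per_block": [
                {"name": b.name, "params": b.params, "flops": b.flops}
                for b in self.per_block
            ],
        }

    def table(self) -> str:
        lines = [f"{'block':<12} {'params':>12} {'flops':>14}"]
        for b in self.per_block:
            lines.append(f"{b.name:<12} {b.params:>12,} {b.flops:>14,}")
        lines.append(f"{'total':<12} {self.params_analytic:>12,} "
                     f"{self.flops_analytic:>14,}")
        lines.append(f"analytic {format_millions(self.params_analytic)} / "
                     f"{format_billions(self.flops_analytic)}; oracle "
                     f"{self.params_oracle:,} learnable scalars")
        return "\n".join(lines)


def format_millions(n: int) -> str:
    return f"{round(n / 1e6, 1)} M"


def format_billions(n: int) -> str:
    return f"{round(n / 1e9, 1)} B"


def _module_layer_specs(module: Module) -> list[LayerSpec]:
    specs = []
    for m in module.modules():
        if isinstance(m, Conv2d):
            if m.last_output_hw is None:
                raise RuntimeError("run a forward pass before profiling")
            h, w = m.last_output_hw
            specs.append(LayerSpec(c_in=m.c_in // m.groups, c_out=m.c_out,
                                   k=m.k, h=h, w=w,
                                   has_bias=m.bias is not None))
        elif isinstance(m, Linear):
            specs.append(LayerSpec(c_in=m.c_in, c_out=m.c_out, k=1,
                                   h=1, w=1, has_bias=m.bias is not None))
    return specs


def profile_network(network: Module, input_size: int = 224,
                    batch: int = 1) -> ComplexityReport:
    """Profile an assembled network at a given input resolution.

    Runs one forward pass in eval mode to record per-layer output sizes,
    then applies the closed-form conv accounting per top-level block and the
    enumeration oracle over the whole network.
    """
    import numpy as np

    if input_size < 1:
        raise ValueError(f"input_size must be positive, got {input_size}")
    was_training = network.training
    network.eval()
    x = np.zeros((batch, 3, input_size, input_size), dtype=np.float32)
    network(x)
    per_block = []
    for name, child in network.named_children():
        specs = _module_layer_specs(child)
        per_block.append(BlockCost(name=name, params=params_model(specs),
                                   flops=flops_model(specs)))
    report = ComplexityReport(
        params_analytic=sum(b.params for b in per_block),
        params_oracle=oracle_param_count(network),
        flops_analytic=sum(b.flops for b in per_block),
        per_block=per_block,
    )
    network.train(was_training)
    return report
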
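"""Network assembly: stem, four downsampling stages, classification head.

The layout follows the cross-stage-partial classification lineage: a stride-2
stem conv, then four stages, each a stride-2 conv followed by a fusion block,
with base widths 64/128/256/512/1024 and base stage depths 3/6/6/3 resolved
through the scale preset's depth/width multipliers. Three structural flags
select the contributed blocks:

* ``use_c2s2`` — stages 1-2 use the split-and-concatenate block (ghost
  units) instead of plain cross-stage fusion;
* ``use_anc2f`` — stages 3-4 use attention-enhanced fusion (stacked
  sigmoid-gated ABlocks) instead of attention-free fusion;
* ``use_dwclassify`` — the head is the depthwise-separable classifier
  instead of the dense conv + linear baseline head.

The eight ablation variants M1..M9 (M5 is not defined) map onto these flags;
M1 is the attention-free baseline, M9 the full network.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .blocks import C2f, C2S2, ConfigError, ConvUnit, DenseHead, DWClassify
from .nn import Module, Parameter

__all__ = [
    "NetworkConfig", "Network", "scale_preset", "build_cnatnet",
    "build_variant", "VARIANT_FLAGS", "save_checkpoint", "load_checkpoint",
]

_BASE_WIDTHS = (64, 128, 256, 512, 1024)
_BASE_DEPTHS = (3, 6, 6, 3)

_SCALE_PRESETS = {
    "n": (0.33, 0.25, 1024),
    "s": (0.33, 0.50, 1024),
    "m": (0.67, 0.75, 768),
}

# variant -> (use_c2s2, use_anc2f, use_dwclassify); M5 intentionally absent
VARIANT_FLAGS: dict[str, tuple[bool, bool, bool]] = {
    "M1": (False, False, False),
    "M2": (True, False, False),
    "M3": (False, True, False),
    "M4": (False, False, True),
    "M6": (True, True, False),
    "M7": (True, False, True),
    "M8": (False, True, True),
    "M9": (True, True, True),
}


def scale_preset(scale: str) -> tuple[float, float, int]:
    """(depth multiplier, width multiplier, max channels) for a scale tag."""
    try:
        return _SCALE_PRESETS[scale]
    except KeyError:
        raise ConfigError(f"unknown scale {scale!r}; expected one of "
                          f"{sorted(_SCALE_PRESETS)}") from None


@dataclass
class NetworkConfig:
    scale: str = "s"
    depth_mult: float | None = None
    width_mult: float | None = None
    max_channels: int | None = None
    num_classes: int = 2
    input_size: int = 224
    use_c2s2: bool = False
    use_anc2f: bool = False
    use_dwclassify: bool = False
    n_ablocks: int = 2
    merge_ratio: float = 0.5  # C_merge / C_out in the split-concat block

    def __post_init__(self):
        dm, wm, mc = scale_preset(self.scale)
        if self.depth_mult is None:
            self.depth_mult = dm
        if self.width_mult is None:
            self.width_mult = wm
        if self.max_channels is None:
            self.max_channels = mc
        if self.depth_mult <= 0 or self.width_mult <= 0:
            raise ConfigError("multipliers must be positive")
        if self.n_ablocks < 1:
            raise ConfigError(f"n_ablocks must be >= 1, got {self.n_ablocks}")

    # resolved architecture ------------------------------------------------
    def widths(self) -> list[int]:
        out = []
        for c in _BASE_WIDTHS:
            w = min(c * self.width_mult, self.max_channels)
            out.append(int(math.ceil(w / 8) * 8))
        return out

    def depths(self) -> list[int]:
        return [max(round(n * self.depth_mult), 1) for n in _BASE_DEPTHS]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class Network(Module):
    """The assembled classifier. Total stride 32; the forward pass maps a
    ``(N, 3, S, S)`` batch to ``(N, num_classes)`` logits.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        w = cfg.widths()
        d = cfg.depths()
        self.stem = ConvUnit(3, w[0], 3, stride=2, rng=rng)
        self._stage_names: list[str] = []
        prev = w[0]
        for i in range(4):
            down = ConvUnit(prev, w[i + 1], 3, stride=2, rng=rng)
            if i < 2 and cfg.use_c2s2:
                merge = int(max(round(w[i + 1] * cfg.merge_ratio), 2))
                block = C2S2(w[i + 1], w[i + 1], n_units=d[i],
                             unit_kind="ghost", merge_channels=merge,
                             rng=rng)
            else:
                n_ab = cfg.n_ablocks if (i >= 2 and cfg.use_anc2f) else 0
                block = C2f(w[i + 1], w[i + 1], n=d[i], shortcut=True,
                            n_ablocks=n_ab, rng=rng)
            setattr(self, f"down{i + 1}", down)
            setattr(self, f"stage{i + 1}", block)
            self._stage_names += [f"down{i + 1}", f"stage{i + 1}"]
            prev = w[i + 1]
        if cfg.use_dwclassify:
            self.head = DWClassify(prev, cfg.num_classes, rng=rng)
        else:
            self.head = DenseHead(prev, cfg.num_classes, rng=rng)

    @property
    def num_classes(self) -> int:
        return self.cfg.num_classes

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ConfigError(f"input size {h}x{w} not divisible by the "
                              f"total stride 32")
        y = self.stem(x)
        for name in self._stage_names:
            y = getattr(self, name)(y)
        return self.head(y)

    def backward(self, dy):
        dy = self.head.backward(dy)
        for name in reversed(self._stage_names):
            dy = getattr(self, name).backward(dy)
        return self.stem.backward(dy)

    def fuse(self) -> "Network":
        """Fold every batch norm into its convolution (deployment form).

        The fused network computes the same eval-mode function with
        conv-plus-bias layers only; reported deployment parameter budgets
        refer to this form.
        """
        for m in self.modules():
            if isinstance(m, ConvUnit):
                m.fuse()
        return self


def build_cnatnet(cfg: NetworkConfig, seed: int = 0) -> Network:
    """Assemble a network from a config record."""
    return Network(cfg, seed=seed)


def build_variant(variant: str, scale: str = "s", num_classes: int = 2,
                  seed: int = 0, **cfg_kwargs) -> Network:
    """Assemble one of the ablation variants M1..M9 at a scale preset."""
    try:
        c2s2, anc2f, dwc = VARIANT_FLAGS[variant]
    except KeyError:
        raise ConfigError(
            f"unknown variant {variant!r}; valid ids: "
            f"{', '.join(sorted(VARIANT_FLAGS))}") from None
    cfg = NetworkConfig(scale=scale, num_classes=num_classes,
                        use_c2s2=c2s2, use_anc2f=anc2f, use_dwclassify=dwc,
                        **cfg_kwargs)
    return Network(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(network: Network, path) -> None:
    """Save weights, buffers and the architecture config to one npz file."""
    state = network.state_dict()
    meta = json.dumps({"config": network.cfg.to_dict(),
                       "seed": network.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> Network:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        net = Network(NetworkConfig.from_dict(meta["config"]),
                      seed=meta["seed"])
        net.load_state_dict({k: data[k] for k in data.files
                             if k != "__meta__"})
    return net
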
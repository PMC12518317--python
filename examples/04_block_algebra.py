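"""The algebraic identities of the bespoke blocks, demonstrated numerically.

The attention block computes sigma(Conv1x1(F)) * F: with a zeroed gate the
sigmoid is exactly 1/2, with a saturated gate the block passes its input
through. The residual attention unit adds an identity shortcut, and the
split-and-concatenate block's channel split is exactly invertible.
"""

import numpy as np

from cnatnet import ABlock, AnC2f, c2s2_split, params_c2s2, params_dw
from cnatnet.complexity import C2S2ParamSpec

rng = np.random.default_rng(0)
x = rng.normal(size=(1, 8, 6, 6)).astype(np.float32)

ab = ABlock(8)
ab.gate.weight.data[...] = 0.0
ab.gate.bias.data[...] = 0.0
print("zero gate -> output is 0.5*x:", np.allclose(ab(x), 0.5 * x))

unit = AnC2f(8, 8, n_ablocks=1)
unit.blocks[0].gate.weight.data[...] = 0.0
unit.blocks[0].gate.bias.data[...] = 0.0
print("shortcut + one half-open gate -> 1.5*x:",
      np.allclose(unit(x), 1.5 * x, rtol=1e-6))

x1, x2 = c2s2_split(x)
print("split/concat round trip exact:",
      np.array_equal(np.concatenate([x1, x2], axis=1), x))
print(f"split widths for 8 channels: {x1.shape[1]} + {x2.shape[1]}")

print("\nclosed-form parameter counts:")
print("  split-concat block (32 ch/branch, k=3, merge 64->128):",
      params_c2s2(C2S2ParamSpec(32, 3, 64, 128)), "(= 2*32*9*32 + 64*128)")
print("  depthwise head (64 ch, k=3, 2 classes):",
      params_dw(64, 3, 2), "(= 64*9 + 64*2)")
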
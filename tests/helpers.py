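"""Independent straight-line reference operations for oracle tests.

Deliberately naive (explicit loops, no im2col, no Module machinery) so they
share no code path with the package's layers.
"""

import numpy as np


def naive_conv2d(x, weight, bias=None, stride=1, padding=0, groups=1):
    n, c_in, h, w = x.shape
    c_out, cg, k, _ = weight.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding),
                       (padding, padding)))
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    y = np.zeros((n, c_out, ho, wo), dtype=np.float64)
    cpg_out = c_out // groups
    for b in range(n):
        for co in range(c_out):
            g = co // cpg_out
            for i in range(ho):
                for j in range(wo):
                    patch = x[b, g * cg:(g + 1) * cg,
                              i * stride:i * stride + k,
                              j * stride:j * stride + k]
                    y[b, co, i, j] = (patch * weight[co]).sum()
            if bias is not None:
                y[b, co] += bias[co]
    return y


def naive_bn_eval(x, gamma, beta, mean, var, eps=1e-3):
    inv = 1.0 / np.sqrt(var + eps)
    return (gamma * (x.transpose(0, 2, 3, 1) - mean) * inv
            + beta).transpose(0, 3, 1, 2)


def naive_silu(x):
    return x / (1.0 + np.exp(-x))


def naive_conv_unit_eval(x, unit):
    """Straight-line eval-mode conv->bn->silu using the unit's weights."""
    y = naive_conv2d(x, unit.conv.weight.data.astype(np.float64),
                     bias=(unit.conv.bias.data if unit.conv.bias is not None
                           else None),
                     stride=unit.conv.stride, padding=unit.conv.padding,
                     groups=unit.conv.groups)
    if unit.bn is not None:
        y = naive_bn_eval(y, unit.bn.gamma.data, unit.bn.beta.data,
                          unit.bn.running_mean, unit.bn.running_var,
                          eps=unit.bn.eps)
    return naive_silu(y)
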
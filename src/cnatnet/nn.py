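"""Minimal feed-forward/back-propagation layer framework on numpy.

Every layer is a :class:`Module` exposing ``forward`` (which caches what the
gradient needs) and ``backward`` (which accumulates parameter gradients and
returns the gradient with respect to its input). Composite blocks route
gradients through their children explicitly, so the whole network trains
without an autodiff engine.

Shapes follow the channels-first convention: feature maps are
``(batch, channels, height, width)`` float arrays.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "SiLU",
    "Sigmoid",
    "Identity",
    "Linear",
    "GlobalAvgPool",
]


class Parameter:
    """A learnable tensor with an accumulated gradient."""

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter(shape={self.data.shape})"


class Module:
    """Base class: tracks child modules, parameters and non-learnable buffers."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- introspection -------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield (f"{prefix}{name}", getattr(self, name))
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{name}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_children(self) -> Iterator[tuple[str, "Module"]]:
        yield from self._modules.items()

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = True
        object.__setattr__(self, name, value)

    # -- state ---------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in state.items():
            if k in own:
                if own[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: "
                                     f"{own[k].data.shape} vs {v.shape}")
                own[k].data[...] = v
            elif k in bufs:
                bufs[k][...] = v
            else:
                raise KeyError(f"unexpected entry in state dict: {k}")

    # -- computation ---------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def __len__(self):
        return len(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, k, k, ho, wo) patch view copy."""
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride,
                                  j:j + stride * wo:stride]
    return cols


def _col2im(dcols: np.ndarray, xp_shape: tuple, k: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * ho:stride,
                j:j + stride * wo:stride] += dcols[:, :, i, j]
    return dxp


class Conv2d(Module):
    """2-D convolution with optional grouping (``groups=c_in`` is depthwise).

    Weights are He-initialised; ``padding=None`` means "same" padding k//2.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 padding: int | None = None, groups: int = 1,
                 bias: bool = False, pad_mode: str = "zeros",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c_in % groups or c_out % groups:
            raise ValueError(f"channels ({c_in}->{c_out}) not divisible by "
                             f"groups={groups}")
        if pad_mode not in ("zeros", "replicate"):
            raise ValueError(f"pad_mode must be zeros|replicate, "
                             f"got {pad_mode!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.pad_mode = pad_mode
        self.groups = groups
        fan_in = (c_in // groups) * k * k
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(
            rng.normal(0.0, std, size=(c_out, c_in // groups, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.last_output_hw: tuple[int, int] | None = None  # for profiling

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p, s, k, g = self.padding, self.stride, self.k, self.groups
        if p:
            mode = "edge" if self.pad_mode == "replicate" else "constant"
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode=mode)
        else:
            xp = x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, ho, wo)
        # (N, G, Cg*k*k, L) @ (G, co_g, Cg*k*k)^T
        l = ho * wo
        cols_g = cols.reshape(n, g, (c // g) * k * k, l)
        w_g = self.weight.data.reshape(g, self.c_out // g, (c // g) * k * k)
        y = np.matmul(w_g[None], cols_g)           # (N, G, co_g, L)
        y = y.reshape(n, self.c_out, ho, wo)
        if self.bias is not None:
            y = y + self.bias.data[None, :, None, None]
        self._cache = (cols_g, xp.shape, (ho, wo))
        self.last_output_hw = (ho, wo)
        return y

    def backward(self, dy):
        cols_g, xp_shape, (ho, wo) = self._cache
        n = dy.shape[0]
        g, k, s, p = self.groups, self.k, self.stride, self.padding
        cg = self.c_in // g
        dy_g = dy.reshape(n, g, self.c_out // g, ho * wo)
        dw = np.matmul(dy_g, cols_g.transpose(0, 1, 3, 2)).sum(axis=0)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        w_g = self.weight.data.reshape(g, self.c_out // g, cg * k * k)
        dcols = np.matmul(w_g.transpose(0, 2, 1)[None], dy_g)
        dcols = dcols.reshape(n, self.c_in, k, k, ho, wo)
        dxp = _col2im(dcols, xp_shape, k, s, ho, wo)
        if not p:
            return dxp
        if self.pad_mode == "replicate":
            # fold padded-border gradients back into the edge pixels they
            # replicate (rows first, then columns — corners land correctly)
            dxp[:, :, p, :] += dxp[:, :, :p, :].sum(axis=2)
            dxp[:, :, -p - 1, :] += dxp[:, :, -p:, :].sum(axis=2)
            dxp[:, :, :, p] += dxp[:, :, :, :p].sum(axis=3)
            dxp[:, :, :, -p - 1] += dxp[:, :, :, -p:].sum(axis=3)
        return dxp[:, :, p:-p, p:-p]


class BatchNorm2d(Module):
    """Per-channel batch normalisation with learnable scale and shift.

    Uses the small-epsilon/low-momentum convention common in modern
    classification backbones (eps 1e-3, momentum 0.03).
    """

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mean)
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = (self.gamma.data[None, :, None, None] * xhat
             + self.beta.data[None, :, None, None])
        self._cache = (xhat, inv_std, self.training)
        return y

    def backward(self, dy):
        xhat, inv_std, was_training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        if not was_training:
            return dxhat * inv_std[None, :, None, None]
        n, _, h, w = dy.shape
        m = n * h * w
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std[None, :, None, None] / m
              * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat))
        return dx


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SiLU(Module):
    """x * sigmoid(x)."""

    def forward(self, x):
        s = _sigmoid(x)
        self._cache = (x, s)
        return x * s

    def backward(self, dy):
        x, s = self._cache
        return dy * (s * (1.0 + x * (1.0 - s)))


class Sigmoid(Module):
    def forward(self, x):
        s = _sigmoid(x)
        self._cache = s
        return s

    def backward(self, dy):
        s = self._cache
        return dy * s * (1.0 - s)


class Identity(Module):
    def forward(self, x):
        return x

    def backward(self, dy):
        return dy


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        bound = float(1.0 / np.sqrt(c_in))
        self.c_in, self.c_out = c_in, c_out
        self.weight = Parameter(rng.uniform(-bound, bound, size=(c_out, c_in)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        self._cache = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y = y + self.bias.data[None, :]
        return y

    def backward(self, dy):
        x = self._cache
        self.weight.grad += dy.T @ x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x):
        self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._cache
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               (n, c, h, w)).copy()
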
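"""Transformer and convolutional building blocks on the autodiff engine."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, conv3d


class Module:
    """Minimal parameter container with recursive discovery."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own = dict(self.named_parameters())
        missing = sorted(set(own) - set(state))
        extra = sorted(set(state) - set(own))
        if strict and (missing or extra):
            raise ValueError(f"state mismatch: missing={missing}, unexpected={extra}")
        mismatched = [
            f"{k}: have {own[k].shape}, got {state[k].shape}"
            for k in own
            if k in state and own[k].shape != state[k].shape
        ]
        if mismatched:
            raise ValueError("incompatible parameter shapes: " + "; ".join(mismatched))
        for k, p in own.items():
            if k in state:
                p.data = state[k].astype(np.float32).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, rng=None, dropout: float = 0.0, training: bool = False) -> Tensor:
        B, N, D = x.shape
        h, dh = self.heads, D // self.heads
        qkv = self.qkv(x).reshape(B, N, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3,B,h,N,dh)
        qkv_flat = qkv.reshape(3, B * h, N, dh)
        q = qkv_flat.index_axis0(0)
        k = qkv_flat.index_axis0(1)
        v = qkv_flat.index_axis0(2)
        att = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(dh))
        att = att.softmax()
        if training and dropout > 0.0 and rng is not None:
            att = att.dropout(dropout, rng, training)
        out = att @ v  # (B*h, N, dh)
        out = out.reshape(B, h, N, dh).transpose(0, 2, 1, 3).reshape(B, N, D)
        out = self.proj(out)
        if training and dropout > 0.0 and rng is not None:
            out = out.dropout(dropout, rng, training)
        return out


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor, rng=None, dropout: float = 0.0, training: bool = False) -> Tensor:
        h = self.fc1(x).gelu()
        if training and dropout > 0.0 and rng is not None:
            h = h.dropout(dropout, rng, training)
        out = self.fc2(h)
        if training and dropout > 0.0 and rng is not None:
            out = out.dropout(dropout, rng, training)
        return out


class Block(Module):
    """Pre-norm transformer block with optional dropout and drop-path."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, mlp_ratio: float = 4.0):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), rng)

    @staticmethod
    def _drop_path(branch: Tensor, p: float, rng, training: bool) -> Tensor:
        if not training or p <= 0.0 or rng is None:
            return branch
        B = branch.shape[0]
        keep = (rng.random((B,) + (1,) * (branch.ndim - 1)) >= p).astype(np.float32) / (1.0 - p)
        return branch * Tensor(keep)

    def __call__(
        self,
        x: Tensor,
        rng=None,
        dropout: float = 0.0,
        drop_path: float = 0.0,
        training: bool = False,
    ) -> Tensor:
        a = self.attn(self.norm1(x), rng=rng, dropout=dropout, training=training)
        x = x + self._drop_path(a, drop_path, rng, training)
        m = self.mlp(self.norm2(x), rng=rng, dropout=dropout, training=training)
        return x + self._drop_path(m, drop_path, rng, training)


class ViTEncoder(Module):
    """A stack of transformer blocks with a final layer norm.

    ``__call__`` returns the normed output; ``forward_with_taps`` also
    returns the raw output of every block (for UNETR skip connections).
    """

    def __init__(self, depth: int, dim: int, heads: int, rng: np.random.Generator):
        self.blocks = [Block(dim, heads, rng) for _ in range(depth)]
        self.norm = LayerNorm(dim)
        self.depth = depth
        self.dim = dim
        self.heads = heads

    def __call__(self, x: Tensor, **kw) -> Tensor:
        for blk in self.blocks:
            x = blk(x, **kw)
        return self.norm(x)

    def forward_with_taps(self, x: Tensor, **kw) -> tuple[Tensor, list[Tensor]]:
        taps = []
        for blk in self.blocks:
            x = blk(x, **kw)
            taps.append(x)
        return self.norm(x), taps


class Conv3dLayer(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int, int],
        rng: np.random.Generator,
    ):
        fan_in = c_in * kernel[0] * kernel[1] * kernel[2]
        std = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(c_out, c_in) + tuple(kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class PixelShuffleUp(Module):
    """Learned 2x in-plane upsampling: 1x1x1 conv to 4C then sub-pixel rearrange.

    Equivalent in expressive power to a stride-2 transposed convolution with
    a 2x2 kernel, but expressed with dense ops.  z is left untouched — the
    anisotropic tokenization never downsampled it.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv = Conv3dLayer(c_in, 4 * c_out, (1, 1, 1), rng)
        self.c_out = c_out

    def __call__(self, x: Tensor) -> Tensor:
        B, _, Z, Y, X = x.shape
        h = self.conv(x)  # (B, 4C, Z, Y, X)
        h = h.reshape(B, self.c_out, 2, 2, Z, Y, X)
        h = h.transpose(0, 1, 4, 5, 2, 6, 3)  # (B, C, Z, Y, ry, X, rx)
        return h.reshape(B, self.c_out, Z, 2 * Y, 2 * X)
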
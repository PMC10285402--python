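"""A compact reverse-mode automatic-differentiation engine over numpy arrays.

Just enough machinery for transformer encoders/decoders and small
convolutional heads: broadcasting elementwise arithmetic, (batched)
matmul, softmax, row gather/scatter for token masking, a 3D "same"
convolution, nearest-neighbor in-plane upsampling, and dropout.  Gradients
are float32 throughout; correctness is checked against finite differences
in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- constructors ---------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _node(data, parents, backward, requires_grad) -> "Tensor":
        out = Tensor(data)
        if requires_grad:
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # ---- elementwise arithmetic ----------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        need = self.requires_grad or other.requires_grad

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), back, need)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        need = self.requires_grad or other.requires_grad

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), back, need)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        assert isinstance(p, (int, float)), "only scalar exponents"

        def back(g):
            self._accumulate(_unbroadcast(g * p * self.data ** (p - 1), self.shape))

        return self._node(self.data ** p, (self,), back, self.requires_grad)

    # ---- reductions & shape ops ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).astype(np.float32))

        return self._node(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), back, self.requires_grad
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = math.prod(self.shape[a] for a in axes)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def back(g):
            self._accumulate(g.reshape(self.shape))

        return self._node(self.data.reshape(shape), (self,), back, self.requires_grad)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def back(g):
            self._accumulate(g.transpose(inv))

        return self._node(self.data.transpose(axes), (self,), back, self.requires_grad)

    # ---- matmul ---------------------------------------------------------
    def __matmul__(self, other):
        other = self._wrap(other)
        need = self.requires_grad or other.requires_grad

        def back(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._node(np.matmul(self.data, other.data), (self, other), back, need)

    # ---- nonlinearities -------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            self._accumulate(g * out_data)

        return self._node(out_data, (self,), back, self.requires_grad)

    def log(self):
        def back(g):
            self._accumulate(g / self.data)

        return self._node(np.log(self.data), (self,), back, self.requires_grad)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            self._accumulate(g * (1.0 - out_data**2))

        return self._node(out_data, (self,), back, self.requires_grad)

    def sigmoid(self):
        out_data = special.expit(self.data)

        def back(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._node(out_data, (self,), back, self.requires_grad)

    def softplus(self):
        # log(1 + e^x), computed stably
        out_data = np.logaddexp(0.0, self.data)

        def back(g):
            self._accumulate(g * special.expit(self.data))

        return self._node(out_data, (self,), back, self.requires_grad)

    def gelu(self):
        # exact (erf-based) GELU, evaluated in float32
        x = self.data
        cdf = 0.5 * (1.0 + special.erf(x * np.float32(1.0 / math.sqrt(2.0))))
        cdf = cdf.astype(np.float32, copy=False)
        out_data = x * cdf

        def back(g):
            pdf = np.exp(np.float32(-0.5) * x * x) * np.float32(
                1.0 / math.sqrt(2.0 * math.pi)
            )
            self._accumulate(g * (cdf + x * pdf))

        return self._node(out_data, (self,), back, self.requires_grad)

    def relu(self):
        mask = self.data > 0

        def back(g):
            self._accumulate(g * mask)

        return self._node(self.data * mask, (self,), back, self.requires_grad)

    def softmax(self):
        """Softmax along the last axis."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=-1, keepdims=True)

        def back(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            self._accumulate(s * (g - dot))

        return self._node(s, (self,), back, self.requires_grad)

    # ---- indexing ops for token masking ---------------------------------
    def gather_rows(self, idx: np.ndarray):
        """Select rows along axis 1: ``out[b, i] = self[b, idx[b, i]]``.

        ``self`` is (B, N, D); ``idx`` is (B, K) or (K,).
        """
        idx = np.asarray(idx, dtype=np.int64)
        if idx.ndim == 1:
            idx = np.broadcast_to(idx, (self.shape[0], idx.shape[0]))
        bidx = np.arange(self.shape[0])[:, None]
        out_data = self.data[bidx, idx]

        def back(g):
            g0 = np.zeros_like(self.data)
            np.add.at(g0, (bidx, idx), g)
            self._accumulate(g0)

        return self._node(out_data, (self,), back, self.requires_grad)

    def scatter_rows(self, idx: np.ndarray, rows: "Tensor"):
        """Copy of ``self`` with ``out[b, idx[b, i]] = rows[b, i]``."""
        idx = np.asarray(idx, dtype=np.int64)
        if idx.ndim == 1:
            idx = np.broadcast_to(idx, (self.shape[0], idx.shape[0]))
        rows = self._wrap(rows)
        bidx = np.arange(self.shape[0])[:, None]
        out_data = self.data.copy()
        out_data[bidx, idx] = rows.data
        need = self.requires_grad or rows.requires_grad

        def back(g):
            if rows.requires_grad:
                rows._accumulate(g[bidx, idx])
            if self.requires_grad:
                gs = g.copy()
                gs[bidx, idx] = 0.0
                self._accumulate(gs)

        return self._node(out_data, (self, rows), back, need)

    def index_axis0(self, i: int):
        """Select a single index along axis 0 (differentiable)."""

        def back(g):
            g0 = np.zeros_like(self.data)
            g0[i] = g
            self._accumulate(g0)

        return self._node(self.data[i], (self,), back, self.requires_grad)

    def index_axis1(self, i: int):
        """Select a single index along axis 1 (differentiable)."""

        def back(g):
            g0 = np.zeros_like(self.data)
            g0[:, i] = g
            self._accumulate(g0)

        return self._node(self.data[:, i], (self,), back, self.requires_grad)

    # ---- spatial ops -----------------------------------------------------
    def upsample_yx(self, k: int):
        """Nearest-neighbor upsampling by ``k`` along the last two axes."""
        out_data = np.repeat(np.repeat(self.data, k, axis=-2), k, axis=-1)

        def back(g):
            lead = g.shape[:-2]
            y, x = self.shape[-2], self.shape[-1]
            gg = g.reshape(*lead, y, k, x, k).sum(axis=(-3, -1))
            self._accumulate(gg)

        return self._node(out_data, (self,), back, self.requires_grad)

    def dropout(self, p: float, rng: np.random.Generator, training: bool = True):
        if not training or p <= 0.0:
            return self
        keep = (rng.random(self.shape) >= p).astype(np.float32) / (1.0 - p)
        return self * Tensor(keep)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3D "same" convolution with odd kernels.

    ``x`` is (B, Cin, Z, Y, X); ``w`` is (Cout, Cin, kz, ky, kx) with odd
    kernel extents; zero padding keeps the spatial shape.  Implemented as a
    sum of shifted (Cout, Cin) tensor contractions — faster than im2col at
    the narrow channel widths these decoders use, and copy-free.
    """
    B, Cin, Z, Y, X = x.shape
    Cout, Cin_w, kz, ky, kx = w.shape
    assert Cin == Cin_w, f"channel mismatch: {Cin} vs {Cin_w}"
    assert kz % 2 == 1 and ky % 2 == 1 and kx % 2 == 1, "odd kernels only"
    pz, py, px = kz // 2, ky // 2, kx // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))
    out_data = np.zeros((B, Cout, Z, Y, X), dtype=np.float32)
    for i in range(kz):
        for j in range(ky):
            for k in range(kx):
                sl = xp[:, :, i : i + Z, j : j + Y, k : k + X]
                # (Cout, Cin) x (B, Cin, Z, Y, X) -> (Cout, B, Z, Y, X)
                out_data += np.tensordot(
                    w.data[:, :, i, j, k], sl, axes=([1], [1])
                ).transpose(1, 0, 2, 3, 4)
    need = x.requires_grad or w.requires_grad

    def back(g):
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kz):
                for j in range(ky):
                    for k in range(kx):
                        sl = xp[:, :, i : i + Z, j : j + Y, k : k + X]
                        gw[:, :, i, j, k] = np.tensordot(
                            g, sl, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                        )
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kz):
                for j in range(ky):
                    for k in range(kx):
                        # (Cin, Cout) x (B, Cout, Z, Y, X) -> (Cin, B, Z, Y, X)
                        gxp[:, :, i : i + Z, j : j + Y, k : k + X] += np.tensordot(
                            w.data[:, :, i, j, k], g, axes=([0], [1])
                        ).transpose(1, 0, 2, 3, 4)
            x._accumulate(
                gxp[:, :, pz : pz + Z, py : py + Y, px : px + X]
                if (pz or py or px)
                else gxp
            )

    out = Tensor._node(out_data, (x, w), back, need)
    if b is not None:
        out = out + b.reshape(1, Cout, 1, 1, 1)
    return out


def bce_with_logits(logits: Tensor, target: np.ndarray | Tensor) -> Tensor:
    """Mean binary cross-entropy on logits: mean(softplus(x) - x * t)."""
    t = target.data if isinstance(target, Tensor) else np.asarray(target, dtype=np.float32)
    return (logits.softplus() - logits * Tensor(t)).mean()
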
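"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the package's own compact neural-network engine: a ``Tensor``
wrapper with a dynamically built computation graph, the primitive ops the
interaction-GNN architecture needs (matmul with broadcasting, elementwise
math, reductions, reshaping, 2-D/3-D convolution, max-pooling, indexed
max), layer modules (linear, batch norm, masked self-attention) and an
Adam optimizer.  Network compute defaults to float32; gradient checking is
done in float64 by passing float64 arrays in.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

DEFAULT_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- graph mechanics ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (post-order: root ends up last)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if not node.requires_grad:
                continue
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) * self**-1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- elementwise -------------------------------------------------------
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y)

        out._backward = bw
        return out

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient goes to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        y = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_data = y if keepdims else np.squeeze(y, axis=axis)
        out = Tensor(out_data, _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            dx = np.zeros_like(self.data)
            np.put_along_axis(dx, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(dx)

        out._backward = bw
        return out

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                dx = np.zeros_like(self.data)
                np.add.at(dx, key, g)
                self._accum(dx)

        out._backward = bw
        return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def bw(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, k, axis=axis))

    out._backward = bw
    return out


def scatter_rows(x: Tensor, idx: np.ndarray, total: int) -> Tensor:
    """Place rows of x at positions ``idx`` of a zero array of ``total`` rows."""
    data = np.zeros((total,) + x.shape[1:], dtype=x.data.dtype)
    data[idx] = x.data
    out = Tensor(data, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g[idx])

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shift is treated as a constant)."""
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def sqrt(x: Tensor) -> Tensor:
    return x**0.5


# ---------------------------------------------------------------------------
# convolution / pooling primitives
# ---------------------------------------------------------------------------

def _convnd(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int,
            nd: int) -> Tensor:
    """Shift-and-accumulate n-D convolution (n = 2 or 3).

    x (B, C, *spatial), w (O, C, *kernel).  Implemented as a sum over
    kernel offsets of strided views — no im2col materialization, which is
    what makes small-kernel convolutions over many rows affordable here.
    """
    s, p = stride, padding
    B, C = x.shape[:2]
    spatial = x.shape[2:]
    O = w.shape[0]
    kernel = w.shape[2:]
    pad = ((0, 0), (0, 0)) + ((p, p),) * nd
    xp = np.pad(x.data, pad) if p else x.data
    out_sp = tuple(
        (spatial[i] + 2 * p - kernel[i]) // s + 1 for i in range(nd)
    )
    out_data = np.zeros((B, O) + out_sp, dtype=x.data.dtype)
    offsets = list(np.ndindex(*kernel))

    def view(arr, off):
        sl = (slice(None), slice(None)) + tuple(
            slice(off[i], off[i] + out_sp[i] * s, s) for i in range(nd)
        )
        return arr[sl]

    for off in offsets:
        # (O, C) x (B, C, *out) -> (B, O, *out)
        out_data += np.tensordot(view(xp, off), w.data[(...,) + off],
                                 axes=([1], [1])).transpose(
            (0, nd + 1) + tuple(range(1, nd + 1))
        )
    if b is not None:
        out_data += b.data.reshape((1, O) + (1,) * nd)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        for off in offsets:
            xv = view(xp, off)
            if w.requires_grad:
                # (B, O, *out) x (B, C, *out) -> (O, C)
                axes_b = [0] + list(range(2, 2 + nd))
                dw[(...,) + off] += np.tensordot(g, xv, axes=(axes_b, axes_b))
            if need_dx:
                view(dxp, off)[...] += np.tensordot(
                    g, w.data[(...,) + off], axes=([1], [0])
                ).transpose((0, nd + 1) + tuple(range(1, nd + 1)))
        if w.requires_grad:
            w._accum(dw)
        if need_dx:
            if p:
                crop = (slice(None), slice(None)) + tuple(
                    slice(p, p + spatial[i]) for i in range(nd)
                )
                x._accum(dxp[crop])
            else:
                x._accum(dxp)

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution, x (B,C,H,W), w (O,C,kh,kw) -> (B,O,H',W')."""
    return _convnd(x, w, b, stride, padding, nd=2)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """3-D convolution, x (B,C,D,H,W), w (O,C,kd,kh,kw) -> (B,O,D',H',W')."""
    return _convnd(x, w, b, stride, padding, nd=3)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping 2-D max pool; trailing cells beyond a multiple of k
    are cropped (floor semantics)."""
    B, C, H, W = x.shape
    Ho, Wo = H // k, W // k
    xc = x.data[:, :, : Ho * k, : Wo * k]
    r = xc.reshape(B, C, Ho, k, Wo, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Ho, Wo, k * k
    )
    idx = np.argmax(r, axis=-1)
    out = Tensor(np.take_along_axis(r, idx[..., None], axis=-1)[..., 0], _parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dr = np.zeros_like(r)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dxc = dr.reshape(B, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, Ho * k, Wo * k
        )
        dx = np.zeros_like(x.data)
        dx[:, :, : Ho * k, : Wo * k] = dxc
        x._accum(dx)

    out._backward = bw
    return out


def maxpool3d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping 3-D max pool with floor semantics."""
    B, C, D, H, W = x.shape
    Do, Ho, Wo = D // k, H // k, W // k
    xc = x.data[:, :, : Do * k, : Ho * k, : Wo * k]
    r = (
        xc.reshape(B, C, Do, k, Ho, k, Wo, k)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(B, C, Do, Ho, Wo, k**3)
    )
    idx = np.argmax(r, axis=-1)
    out = Tensor(np.take_along_axis(r, idx[..., None], axis=-1)[..., 0], _parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dr = np.zeros_like(r)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dxc = (
            dr.reshape(B, C, Do, Ho, Wo, k, k, k)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(B, C, Do * k, Ho * k, Wo * k)
        )
        dx = np.zeros_like(x.data)
        dx[:, :, : Do * k, : Ho * k, : Wo * k] = dxc
        x._accum(dx)

    out._backward = bw
    return out


class GridConvPlan:
    """Index plan mapping a small-kernel convolution onto one dense matmul.

    For single-channel input grids processed row-wise (one row per atom),
    a k^n convolution is a sparse linear map R^Din -> R^(O*Dout); at the
    sizes used here, materializing it densely and multiplying with BLAS is
    far faster than window extraction.  The plan precomputes the scatter
    indices from kernel weights into the dense matrix.
    """

    def __init__(self, spatial: tuple[int, ...], c_out: int, kernel: int = 3,
                 stride: int = 1, padding: int = 1):
        nd = len(spatial)
        self.spatial = spatial
        self.c_out = c_out
        self.kernel = kernel
        self.out_spatial = tuple(
            (spatial[i] + 2 * padding - kernel) // stride + 1 for i in range(nd)
        )
        din = int(np.prod(spatial))
        dout = int(np.prod(self.out_spatial))
        self.din, self.dout = din, dout
        k_total = kernel**nd
        q_grid = np.stack(
            [a.ravel() for a in np.meshgrid(
                *[np.arange(s) for s in self.out_spatial], indexing="ij")],
            axis=1,
        )  # (dout, nd)
        t_grid = np.stack(
            [a.ravel() for a in np.meshgrid(
                *[np.arange(kernel)] * nd, indexing="ij")],
            axis=1,
        )  # (k_total, nd)
        p = q_grid[:, None, :] * stride + t_grid[None, :, :] - padding
        valid = np.all((p >= 0) & (p < np.array(spatial)[None, None, :]), axis=-1)
        p_flat = np.zeros(p.shape[:2], dtype=np.int64)
        for i in range(nd):
            p_flat = p_flat * spatial[i] + np.clip(p[..., i], 0, spatial[i] - 1)
        qq, tt = np.nonzero(valid)
        o = np.repeat(np.arange(c_out), len(qq))
        self.rows_idx = np.tile(p_flat[qq, tt], c_out)
        self.cols_idx = (o * dout + np.tile(qq, c_out)).astype(np.int64)
        self.k_idx = (o * k_total + np.tile(tt, c_out)).astype(np.int64)
        self.k_total = k_total


def grid_conv(rows: Tensor, kernel: Tensor, bias: Tensor, plan: GridConvPlan
              ) -> Tensor:
    """Apply a planned convolution to row-wise grids.

    rows (R, Din) -> (R, O*Dout); ``kernel`` has shape (O, k, ..., k) and
    ``bias`` (O,).
    """
    kflat = kernel.data.reshape(-1)
    W = np.zeros((plan.din, plan.c_out * plan.dout), dtype=rows.data.dtype)
    W[plan.rows_idx, plan.cols_idx] = kflat[plan.k_idx]
    out_data = rows.data @ W + np.repeat(bias.data, plan.dout)[None, :]
    out = Tensor(out_data, _parents=(rows, kernel, bias))

    def bw(g):
        if rows.requires_grad:
            rows._accum(g @ W.T)
        if kernel.requires_grad:
            dW = rows.data.T @ g
            dk = np.zeros(plan.c_out * plan.k_total, dtype=np.float64)
            np.add.at(dk, plan.k_idx, dW[plan.rows_idx, plan.cols_idx])
            kernel._accum(dk.reshape(kernel.shape).astype(kernel.data.dtype))
        if bias.requires_grad:
            bias._accum(
                g.reshape(-1, plan.c_out, plan.dout).sum(axis=(0, 2))
            )

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        """Self plus all nested modules, in stable attribute order."""
        found = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                found.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        found.extend(item.modules())
        return found

    def _buffers(self) -> list[tuple["Module", str]]:
        out = []
        for mod in self.modules():
            for name, v in mod.__dict__.items():
                # "last_*" attributes are forward-pass introspection caches,
                # not model state
                if isinstance(v, np.ndarray) and not name.startswith("last"):
                    out.append((mod, name))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers
        (running statistics), for checkpoints."""
        out = {}
        for k, p in enumerate(self.parameters()):
            out[f"p{k}"] = p.data
        for k, (mod, name) in enumerate(self._buffers()):
            out[f"b{k}"] = getattr(mod, name)
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"p{k}"], dtype=p.data.dtype)
        for k, (mod, name) in enumerate(self._buffers()):
            if f"b{k}" in state:
                setattr(mod, name, np.asarray(state[f"b{k}"]))


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...], dtype=DEFAULT_DTYPE) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        self.w = glorot(rng, n_in, n_out, (n_in, n_out), dtype)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class BatchNorm(Module):
    """Batch normalization over the last axis of (rows, features) input.

    An optional constant row weight (0/1 mask) restricts the batch
    statistics to valid rows.  Running statistics are kept for eval mode.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=DEFAULT_DTYPE):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(dim, dtype=np.float64)
        self.running_var = np.ones(dim, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool, row_weight: np.ndarray | None = None
                 ) -> Tensor:
        if train:
            if row_weight is None:
                count = x.shape[0]
                w = None
            else:
                w = Tensor(row_weight.reshape(-1, 1).astype(x.data.dtype))
                count = float(row_weight.sum())
            xw = x if w is None else x * w
            mean = xw.sum(axis=0, keepdims=True) * (1.0 / count)
            centered = x - mean
            cw = centered if w is None else centered * w
            var = (cw * cw).sum(axis=0, keepdims=True) * (1.0 / count)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data[0]
            self.running_var = (1 - m) * self.running_var + m * var.data[0]
            inv = (var + self.eps) ** -0.5
            return centered * inv * self.gamma + self.beta
        mean = Tensor(self.running_mean.astype(x.data.dtype)[None, :])
        inv = Tensor(
            (1.0 / np.sqrt(self.running_var + self.eps)).astype(x.data.dtype)[None, :]
        )
        return (x - mean) * inv * self.gamma + self.beta


class SelfAttention(Module):
    """Masked scaled dot-product self-attention over a token axis.

    Input (B, T, D) with an optional boolean key mask (B, T); padded keys
    receive zero weight.  The most recent attention matrix is kept on
    ``last_attention`` (B, T, T) for interpretation.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 d_key: int = 16, dtype=DEFAULT_DTYPE):
        self.wq = glorot(rng, d_in, d_key, (d_in, d_key), dtype)
        self.wk = glorot(rng, d_in, d_key, (d_in, d_key), dtype)
        self.wv = glorot(rng, d_in, d_out, (d_in, d_out), dtype)
        self.d_key = d_key
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        q = x @ self.wq
        k = x @ self.wk
        v = x @ self.wv
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.d_key))
        if mask is not None:
            bias = np.where(mask[:, None, :], 0.0, -1e9).astype(x.data.dtype)
            scores = scores + Tensor(bias)
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        return attn @ v


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
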
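"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network needs only a small operator vocabulary — temporal (grouped)
convolutions, 1x1 channel mixing, pooling, nearest-neighbor up-sampling,
GELU, softmax and elementwise arithmetic — so the package carries its own
compact tape-based autodiff engine rather than a framework dependency.
Convolutions are lowered to im2col + batched matrix products so the heavy
lifting runs through BLAS; gradients of every primitive are closed-form and
are validated end-to-end by finite differences in the test suite.

Array layout convention throughout: (N, C, T) — batch, channels, time.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy import special

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- bookkeeping --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Accumulate gradients of a scalar (or supplied-cotangent) output."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad
                else:
                    parent.grad = parent.grad + pgrad

    # -- elementwise arithmetic --------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            # scalar fast path: no dtype promotion, no extra graph node
            return Tensor._node(self.data + other, (self,), lambda g: (g,))
        a, b = self, self._lift(other)
        return Tensor._node(
            a.data + b.data, (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._node(self.data - other, (self,), lambda g: (g,))
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._node(self.data * other, (self,), lambda g: (g * other,))
        a, b = self, self._lift(other)
        return Tensor._node(
            a.data * b.data, (a, b),
            lambda g: (_unbroadcast(g * b.data, a.shape),
                       _unbroadcast(g * a.data, b.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        a, b = self, self._lift(other)
        return Tensor._node(
            a.data / b.data, (a, b),
            lambda g: (_unbroadcast(g / b.data, a.shape),
                       _unbroadcast(-g * a.data / b.data**2, b.shape)),
        )

    def pow(self, p: float):
        return Tensor._node(
            self.data**p, (self,),
            lambda g: (g * p * self.data ** (p - 1),),
        )

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + special.erf(x / math.sqrt(2.0)))
        out_data = x * cdf

        def back(g):
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            return (g * (cdf + x * pdf),)

        return Tensor._node(out_data, (self,), back)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._node(out_data, (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._node(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._node(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def back(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)

        return Tensor._node(self.data[idx], (self,), back)

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(z, out=z)
        out_data = z
        out_data /= out_data.sum(axis=axis, keepdims=True)

        def back(g):
            return (out_data * (g - (g * out_data).sum(axis=axis, keepdims=True)),)

        return Tensor._node(out_data, (self,), back)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = np.log(s) + m
        soft = e / s

        def back(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (g * soft,)

        return Tensor._node(out_data if keepdims else np.squeeze(out_data, axis),
                            (self,), back)

    # -- temporal/structural primitives ------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               groups: int = 1) -> "Tensor":
        """Grouped temporal convolution, stride 1, zero same-padding.

        ``self``: (N, C, T); ``weight``: (C_out, C//groups, k) with k odd;
        ``bias``: (C_out,) or None.  Cross-correlation convention (kernels
        are not flipped), matching standard deep-learning convolutions.
        Lowered to k shifted batched matrix products so no im2col copy is
        materialized.
        """
        x, w = self, weight
        n, c, t = x.shape
        c_out, c_g, k = w.shape
        if k % 2 != 1:
            raise ValueError("conv1d requires an odd kernel length")
        if c != c_g * groups or c_out % groups != 0:
            raise ValueError(
                f"shape mismatch: input C={c}, weight {w.shape}, groups={groups}"
            )
        og = c_out // groups
        p = (k - 1) // 2
        depthwise = c_g == 1 and og == 1
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p))) if p else x.data
        if depthwise:
            # (C, k) kernels applied per channel: pure shifted elementwise sums
            wd = w.data[:, 0, :]
            y = wd[:, 0][None, :, None] * xp[:, :, :t]
            for kk in range(1, k):
                y += wd[:, kk][None, :, None] * xp[:, :, kk:kk + t]
        else:
            xg = xp.reshape(n, groups, c_g, t + 2 * p)
            wg = w.data.reshape(groups, og, c_g, k)
            y4 = wg[:, :, :, 0] @ xg[:, :, :, :t]
            for kk in range(1, k):
                y4 += wg[:, :, :, kk] @ xg[:, :, :, kk:kk + t]
            y = y4.reshape(n, c_out, t)
        if bias is not None:
            y = y + bias.data[:, None]

        def back(grad):
            gxp = np.zeros_like(xp)
            gw = np.empty_like(w.data)
            if depthwise:
                for kk in range(k):
                    xs = xp[:, :, kk:kk + t]
                    gw[:, 0, kk] = np.einsum("nct,nct->c", grad, xs)
                    gxp[:, :, kk:kk + t] += wd[:, kk][None, :, None] * grad
            else:
                gy = grad.reshape(n, groups, og, t)
                gxg = gxp.reshape(n, groups, c_g, t + 2 * p)
                gwg = gw.reshape(groups, og, c_g, k)
                wg_t = w.data.reshape(groups, og, c_g, k).transpose(3, 0, 2, 1)
                for kk in range(k):
                    xs = xg[:, :, :, kk:kk + t]
                    gwg[:, :, :, kk] = np.einsum("ngot,ngct->goc", gy, xs, optimize=True)
                    gxg[:, :, :, kk:kk + t] += wg_t[kk] @ gy
            gx = gxp[:, :, p:p + t] if p else gxp
            gb = grad.sum(axis=(0, 2)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

        parents = (x, w, bias) if bias is not None else (x, w)
        return Tensor._node(y, parents, back)

    def unfold1d(self, k: int) -> "Tensor":
        """Zero same-padded sliding windows: (N, C, T) -> (N, C, k, T)."""
        n, c, t = self.shape
        if k % 2 != 1:
            raise ValueError("unfold1d requires an odd window length")
        p = (k - 1) // 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (p, p)))
        sn, sc, st = xp.strides
        win = as_strided(xp, (n, c, k, t), (sn, sc, st, st)).copy()

        def back(g):
            gxp = np.zeros_like(xp)
            for kk in range(k):
                gxp[:, :, kk:kk + t] += g[:, :, kk, :]
            return (gxp[:, :, p:p + t] if p else gxp,)

        return Tensor._node(win, (self,), back)

    def maxpool1d(self, size: int) -> "Tensor":
        """Non-overlapping temporal max pooling; trailing remainder dropped."""
        n, c, t = self.shape
        if size < 1 or t < size:
            raise ValueError(f"cannot max-pool T={t} by {size}")
        t2 = t // size
        xr = self.data[:, :, :t2 * size].reshape(n, c, t2, size)
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def back(g):
            gx = np.zeros((n, c, t), dtype=g.dtype)
            gr = gx[:, :, :t2 * size].reshape(n, c, t2, size)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            return (gx,)

        return Tensor._node(out_data, (self,), back)

    def avgpool1d(self, size: int) -> "Tensor":
        n, c, t = self.shape
        if size < 1 or t < size:
            raise ValueError(f"cannot avg-pool T={t} by {size}")
        t2 = t // size
        out_data = self.data[:, :, :t2 * size].reshape(n, c, t2, size).mean(axis=-1)

        def back(g):
            gx = np.zeros((n, c, t), dtype=g.dtype)
            gx[:, :, :t2 * size] = np.repeat(g / size, size, axis=-1)
            return (gx,)

        return Tensor._node(out_data, (self,), back)

    def upsample_nearest(self, factor: int) -> "Tensor":
        """Nearest-neighbor temporal up-sampling by integer repetition."""
        n, c, t = self.shape
        out_data = np.repeat(self.data, factor, axis=-1)

        def back(g):
            return (g.reshape(n, c, t, factor).sum(axis=-1),)

        return Tensor._node(out_data, (self,), back)

    def pad_right_edge(self, amount: int) -> "Tensor":
        """Edge-replicate the last time sample ``amount`` times."""
        if amount == 0:
            return self
        t = self.shape[-1]
        out_data = np.concatenate(
            [self.data, np.repeat(self.data[..., -1:], amount, axis=-1)], axis=-1
        )

        def back(g):
            gx = g[..., :t].copy()
            gx[..., -1] += g[..., t:].sum(axis=-1)
            return (gx,)

        return Tensor._node(out_data, (self,), back)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along an axis (differentiable)."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(np.concatenate(datas, axis=axis), tuple(tensors), back)


class Adam:
    """Standard Adam first-order optimizer over a name -> array mapping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, g in grads.items():
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
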
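"""Reverse-mode automatic differentiation over numpy arrays.

A ``Tensor`` wraps a float32 ndarray and records a closure that accumulates
gradients into its parents; ``backward()`` runs the closures in reverse
topological order.  Only the operations used by the segmentation network are
implemented, each with an exact vector-Jacobian product (verified against
finite differences in the test suite).  Leaves with ``requires_grad=False``
(inputs, frozen parameters) accumulate nothing, so a frozen parameter's
gradient norm is identically zero.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _needs(t: "Tensor") -> bool:
    return t.requires_grad or bool(t._prev)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad and not self._prev:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE)
        else:
            self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     _prev=(self, other))

        def _bw(g):
            if _needs(self):
                self._accum(_unbroadcast(g, self.data.shape))
            if _needs(other):
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if _needs(self):
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if _needs(other):
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** DTYPE(p), _prev=(self,))
        out._backward = lambda g: self._accum(
            g * DTYPE(p) * self.data ** DTYPE(p - 1.0))
        return out

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _prev=(self,))

        def _bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = (self.data.size if axis is None
             else np.prod([self.data.shape[a]
                           for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(self.data.swapaxes(a, b), _prev=(self,))
        out._backward = lambda g: self._accum(g.swapaxes(a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            full[idx] += g      # basic (slice/int) indexing only: no duplicates
            self._accum(full)
        out._backward = _bw
        return out

    def repeat_interleave(self, reps: int, axis: int):
        """Nearest-neighbour upsampling along ``axis``."""
        out = Tensor(np.repeat(self.data, reps, axis=axis), _prev=(self,))

        def _bw(g):
            shp = list(self.data.shape)
            new = g.reshape(shp[:axis] + [shp[axis], reps] + shp[axis + 1:])
            self._accum(new.sum(axis=axis + 1))
        out._backward = _bw
        return out

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0):
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                     _prev=tuple(tensors))
        sizes = [t.data.shape[axis] for t in tensors]

        def _bw(g):
            pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
            for t, piece in zip(tensors, pieces):
                if _needs(t):
                    t._accum(piece)
        out._backward = _bw
        return out

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if _needs(self):
                self._accum(_unbroadcast(g @ other.data.swapaxes(-1, -2),
                                         self.data.shape))
            if _needs(other):
                other._accum(_unbroadcast(self.data.swapaxes(-1, -2) @ g,
                                          other.data.shape))
        out._backward = _bw
        return out

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sigmoid(self):
        with np.errstate(over="ignore"):   # saturates cleanly in float32
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def swish(self):
        """x * sigmoid(x)."""
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _prev=(self,))
        out._backward = lambda g: self._accum(
            g * (s + self.data * (s - s * s)))
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))
        out._backward = _bw
        return out

    def normalize(self, axis, eps: float = 1e-5):
        """Zero-mean unit-variance standardization over ``axis`` (fused).

        Returns (xhat, mean, var) where mean/var are plain arrays over the
        reduction axes -- the building block for batch/layer normalization.
        """
        axis = tuple(np.atleast_1d(axis))
        mu = self.data.mean(axis=axis, keepdims=True)
        xc = self.data - mu
        var = np.mean(xc * xc, axis=axis, keepdims=True)
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = xc * invstd
        out = Tensor(xhat, _prev=(self,))

        def _bw(g):
            gm = g.mean(axis=axis, keepdims=True)
            gx = np.mean(g * xhat, axis=axis, keepdims=True)
            self._accum(invstd * (g - gm - xhat * gx))
        out._backward = _bw
        return out, mu, var

    # -- convolution -------------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, dilation: int = 1):
        """1D convolution on (N, C_in, L) with 'same'-style padding.

        weight is (C_out, C_in, K); output length is ceil(L / stride).
        """
        x, w = self, weight
        N, C, L = x.data.shape
        Co, Ci, K = w.data.shape
        if Ci != C:
            raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
        L_out = -(-L // stride)
        ke = (K - 1) * dilation + 1
        total_pad = max((L_out - 1) * stride + ke - L, 0)
        pl = total_pad // 2
        xp = (np.pad(x.data, ((0, 0), (0, 0), (pl, total_pad - pl)))
              if total_pad else x.data)

        out_data = np.zeros((N, Co, L_out), dtype=DTYPE)
        slices = []
        for k in range(K):
            off = k * dilation
            sl = xp[:, :, off:off + (L_out - 1) * stride + 1:stride]
            slices.append(sl)
            out_data += np.einsum("oc,ncl->nol", w.data[:, :, k], sl,
                                  optimize=True)
        if bias is not None:
            out_data += bias.data[None, :, None]
        parents = (x, w) if bias is None else (x, w, bias)
        out = Tensor(out_data, _prev=parents)

        def _bw(g):
            need_x = _needs(x)
            need_w = _needs(w)
            gw = np.empty_like(w.data) if need_w else None
            gxp = np.zeros_like(xp) if need_x else None
            for k in range(K):
                if need_w:
                    gw[:, :, k] = np.einsum("nol,ncl->oc", g, slices[k],
                                            optimize=True)
                if need_x:
                    off = k * dilation
                    gxp[:, :, off:off + (L_out - 1) * stride + 1:stride] += \
                        np.einsum("oc,nol->ncl", w.data[:, :, k], g,
                                  optimize=True)
            if need_w:
                w._accum(gw)
            if need_x:
                x._accum(gxp[:, :, pl:pl + L] if total_pad else gxp)
            if bias is not None and _needs(bias):
                bias._accum(g.sum(axis=(0, 2)))
        out._backward = _bw
        return out

    def __repr__(self):
        return (f"Tensor(shape={self.data.shape}, "
                f"requires_grad={self.requires_grad})")
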
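"""Minimal reverse-mode automatic differentiation on numpy arrays.

The translation networks in this package are small (segments are 64 time
samples by tens of sensors), so they run comfortably on a compact tape-based
autodiff engine rather than a full deep-learning framework.  The engine
supports exactly the operations the encoder, generator, discriminator and
classifier need: broadcasting arithmetic, matmul, strided temporal
convolution (plus depthwise temporal/spatial variants), pooling, upsampling,
slicing/concatenation and the usual pointwise nonlinearities.

All data is float64; every forward computation is a pure deterministic
function of its inputs, which the training-determinism contracts rely on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "astensor", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo, seen = [], set()
        stack = [self]
        while stack:  # iterative DFS; graphs include 64-step LSTM chains
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out = _node(np.exp(self.data), (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        out = _node(np.sqrt(self.data), (self,))
        out._backward = lambda g: self._accum(g * 0.5 / out.data)
        return out

    def tanh(self):
        out = _node(np.tanh(self.data), (self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = _node(1.0 / (1.0 + np.exp(-self.data)), (self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def abs(self):
        out = _node(np.abs(self.data), (self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        out = _node(out_data, (self,))
        out._backward = lambda g: self._accum(g * np.where(pos, 1.0, out_data + alpha))
        return out

    def clip_min(self, lo: float):
        mask = self.data > lo
        out = _node(np.maximum(self.data, lo), (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = _node(self.data[key], (self,))

        def bw(g):
            gx = np.zeros_like(self.data)
            gx[key] += g  # basic (slice) indexing only: regions never overlap
            self._accum(gx)

        out._backward = bw
        return out

    # -- structured ops ----------------------------------------------------
    def conv_time(self, w: "Tensor", b: "Tensor | None" = None, stride: int = 1,
                  padding="same"):
        """Convolution along the time axis.

        input (B, Cin, L, M) * weight (Cout, Cin, k) -> (B, Cout, L', M).
        The sensor axis M is untouched (kernels of shape k x 1).
        """
        B, Ci, L, M = self.shape
        Co, Ci2, k = w.shape
        if Ci2 != Ci:
            raise ValueError(f"conv_time: {Ci} input channels but weight expects {Ci2}")
        if padding == "same":
            Lout = -(-L // stride)
            pad_total = max((Lout - 1) * stride + k - L, 0)
        elif padding == "valid":
            pad_total = 0
            Lout = (L - k) // stride + 1
        else:
            pad_total = 2 * int(padding)
            Lout = (L + pad_total - k) // stride + 1
        pl, pr = pad_total // 2, pad_total - pad_total // 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, k, axis=2)[:, :, ::stride]  # (B,Ci,Lout,M,k)
        out_data = np.einsum("bilmk,oik->bolm", win, w.data, optimize=True)
        if b is not None:
            out_data = out_data + b.data[None, :, None, None]
        parents = (self, w) if b is None else (self, w, b)
        out = _node(out_data, parents)

        def bw(g):
            w._accum(np.einsum("bolm,bilmk->oik", g, win, optimize=True))
            if b is not None:
                b._accum(g.sum(axis=(0, 2, 3)))
            gcols = np.einsum("bolm,oik->bilmk", g, w.data, optimize=True)
            gxp = np.zeros_like(xp)
            span = stride * Lout
            for j in range(k):
                gxp[:, :, j:j + span:stride, :] += gcols[..., j]
            self._accum(gxp[:, :, pl:pl + L, :])

        out._backward = bw
        return out

    def depthwise_conv_time(self, w: "Tensor", b: "Tensor | None" = None):
        """Per-channel temporal convolution: (B,C,L,M) * (C,k) -> (B,C,L,M), same pad."""
        B, C, L, M = self.shape
        C2, k = w.shape
        if C2 != C:
            raise ValueError("depthwise_conv_time: channel mismatch")
        pl, pr = (k - 1) // 2, k // 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, k, axis=2)  # (B,C,L,M,k)
        out_data = np.einsum("bclmk,ck->bclm", win, w.data, optimize=True)
        if b is not None:
            out_data = out_data + b.data[None, :, None, None]
        out = _node(out_data, (self, w) if b is None else (self, w, b))

        def bw(g):
            w._accum(np.einsum("bclm,bclmk->ck", g, win, optimize=True))
            if b is not None:
                b._accum(g.sum(axis=(0, 2, 3)))
            gcols = np.einsum("bclm,ck->bclmk", g, w.data, optimize=True)
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, :, j:j + L, :] += gcols[..., j]
            self._accum(gxp[:, :, pl:pl + L, :])

        out._backward = bw
        return out

    def depthwise_spatial(self, w: "Tensor", b: "Tensor | None" = None):
        """Depthwise conv spanning the whole sensor axis.

        input (B, F, L, M) * weight (F, D, M) -> (B, F*D, L, 1); each of the F
        input channels gets D spatial filters (depth multiplier D).
        """
        B, F, L, M = self.shape
        F2, D, M2 = w.shape
        if (F2, M2) != (F, M):
            raise ValueError("depthwise_spatial: shape mismatch")
        out_data = np.einsum("bflm,fdm->bfdl", self.data, w.data, optimize=True)
        out_data = out_data.reshape(B, F * D, L, 1)
        if b is not None:
            out_data = out_data + b.data[None, :, None, None]
        out = _node(out_data, (self, w) if b is None else (self, w, b))

        def bw(g):
            if b is not None:
                b._accum(g.sum(axis=(0, 2, 3)))
            gr = g.reshape(B, F, D, L)
            w._accum(np.einsum("bfdl,bflm->fdm", gr, self.data, optimize=True))
            self._accum(np.einsum("bfdl,fdm->bflm", gr, w.data, optimize=True))

        out._backward = bw
        return out

    def maxpool_time(self, size: int):
        """Non-overlapping max pooling along time: (B,C,L,M) -> (B,C,L//size,M)."""
        B, C, L, M = self.shape
        if L % size:
            raise ValueError(f"maxpool_time: L={L} not divisible by {size}")
        xr = self.data.reshape(B, C, L // size, size, M)
        idx = xr.argmax(axis=3)
        out = _node(np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :],
                    (self,))

        def bw(g):
            gx = np.zeros_like(xr)
            np.put_along_axis(gx, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
            self._accum(gx.reshape(self.shape))

        out._backward = bw
        return out

    def avgpool_time(self, factor: int):
        B, C, L, M = self.shape
        if L % factor:
            raise ValueError("avgpool_time: length not divisible by factor")
        out = _node(self.data.reshape(B, C, L // factor, factor, M).mean(axis=3), (self,))

        def bw(g):
            self._accum(np.repeat(g, factor, axis=2) / factor)

        out._backward = bw
        return out

    def upsample_time(self, factor: int):
        """Nearest-neighbour repeat along time: (B,C,L,M) -> (B,C,L*factor,M)."""
        B, C, L, M = self.shape
        out = _node(np.repeat(self.data, factor, axis=2), (self,))

        def bw(g):
            self._accum(g.reshape(B, C, L, factor, M).sum(axis=3))

        out._backward = bw
        return out

    def dropout(self, p: float, rng: np.random.Generator | None):
        """Inverted dropout; pass rng=None to disable (evaluation mode)."""
        if rng is None or p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _node(data: np.ndarray, parents) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(parents)
    return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.shape[axis] for t in tensors]

    def bw(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, pieces):
            t._accum(piece)

    out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = _node(np.stack([t.data for t in tensors], axis=axis), tensors)

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
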
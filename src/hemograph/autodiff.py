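"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the graph-network surrogate and its
training losses need: dense matmul, bias add, ReLU, layer normalization,
concatenation, row gather / segment-sum (message passing), elementwise
arithmetic, fixed sparse-matrix products (the discrete physics operators),
and scalar reductions.  Tensors record their parents and a backward
closure; ``backward()`` runs a topological sweep.

Gradient tracking is global (:func:`no_grad` disables the tape), so pure
inference builds no graph and frees intermediates eagerly.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    old = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = old


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad",
                 "retain_grad", "_grad_owned")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents) if _GRAD_ENABLED else ()
        self._backward = backward if _GRAD_ENABLED else None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )
        self.retain_grad = False
        self._grad_owned = False

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g, own: bool = True):
        """Accumulate an incoming gradient.

        ``own=False`` marks a buffer that may be shared with another tensor
        (a pass-through gradient); it is adopted without copying and
        reallocated lazily on the first in-place addition.
        """
        if g.dtype != self.data.dtype or g.shape != self.data.shape:
            g = np.broadcast_to(g, self.data.shape).astype(self.data.dtype)
            own = True
        if self.grad is None:
            self.grad = g
            self._grad_owned = own
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad=None):
        """Reverse sweep from this tensor (default seed: ones)."""
        topo, seen = [], set()
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data) if grad is None else grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # break tensor <-> closure reference cycles so the tape is freed
        # promptly; leaf parameters keep their accumulated gradients
        for node in topo:
            node._backward = None
            node._parents = ()
            if not isinstance(node, Parameter) and not node.retain_grad:
                node.grad = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape), own=False)
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape), own=False)

        out._backward = bwd if _GRAD_ENABLED else None
        return out

    __radd__ = __add__

    def __sub__(self, other):
        return self + (_wrap(other) * -1.0)

    def __rsub__(self, other):
        return _wrap(other) + (self * -1.0)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd if _GRAD_ENABLED else None
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd if _GRAD_ENABLED else None
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (out.data > 0))

        out._backward = bwd if _GRAD_ENABLED else None
        return out

    def square(self):
        out = Tensor(self.data**2, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(2.0 * g * self.data)

        out._backward = bwd if _GRAD_ENABLED else None
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s)

        out._backward = bwd if _GRAD_ENABLED else None
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g))

        out._backward = bwd if _GRAD_ENABLED else None
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g / n))

        out._backward = bwd if _GRAD_ENABLED else None
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g, shape):
    """Sum gradient g down to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------------

def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Fused affine map x @ W + b (single tape node)."""
    out = Tensor(x.data @ W.data + b.data, (x, W, b))

    def bwd(g):
        if x.requires_grad:
            x._accum(g @ W.data.T)
        if W.requires_grad:
            W._accum(x.data.T @ g)
        if b.requires_grad:
            b._accum(g.sum(axis=0))

    out._backward = bwd if _GRAD_ENABLED else None
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece, own=False)

    out._backward = bwd if _GRAD_ENABLED else None
    return out


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather: out[k] = x[idx[k]]."""
    out = Tensor(x.data[idx], (x,))

    def bwd(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            x._accum(acc)

    out._backward = bwd if _GRAD_ENABLED else None
    return out


def segment_sum(x: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Sum rows of x into n bins: out[i] = sum_{k: idx[k]=i} x[k]."""
    acc = np.zeros((n,) + x.data.shape[1:], dtype=x.data.dtype)
    np.add.at(acc, idx, x.data)
    out = Tensor(acc, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g[idx])

    out._backward = bwd if _GRAD_ENABLED else None
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Row-wise layer normalization with learned gain and bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data, (x, gain, bias))

    def bwd(g):
        if gain.requires_grad:
            gain._accum(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accum(_unbroadcast(g, bias.data.shape))
        if x.requires_grad:
            d = x.data.shape[-1]
            gx = g * gain.data
            term1 = gx
            term2 = gx.mean(axis=-1, keepdims=True)
            term3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (term1 - term2 - term3))

    out._backward = bwd if _GRAD_ENABLED else None
    return out


def spmm(S, x: Tensor) -> Tensor:
    """Fixed sparse matrix times tracked dense tensor: S @ x."""
    out = Tensor(S @ x.data, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum((S.T @ g).astype(x.data.dtype))

    out._backward = bwd if _GRAD_ENABLED else None
    return out


def column(x: Tensor, j: int) -> Tensor:
    out = Tensor(np.ascontiguousarray(x.data[:, j]), (x,))

    def bwd(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            acc[:, j] = g
            x._accum(acc)

    out._backward = bwd if _GRAD_ENABLED else None
    return out


def stack_columns(cols: list[Tensor]) -> Tensor:
    cols = [_wrap(c) for c in cols]
    out = Tensor(np.stack([c.data for c in cols], axis=1), cols)

    def bwd(g):
        for j, c in enumerate(cols):
            if c.requires_grad:
                c._accum(g[:, j])

    out._backward = bwd if _GRAD_ENABLED else None
    return out


# ---------------------------------------------------------------------------
# parameters and optimizer
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)

    def zero_grad(self):
        self.grad = None


class Adam:
    """Adaptive-moment gradient descent (default betas/eps)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, clip_norm: float | None = 1.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in self.params
        ]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
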
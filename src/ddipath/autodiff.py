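"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine sufficient for training the hierarchical
recurrent extractor on CPU: elementwise arithmetic with broadcasting,
2-D matrix products, the usual saturating nonlinearities, reductions,
concatenation/slicing, embedding-row gathers with scatter-add gradients,
and a fused softmax cross-entropy.  Gradients are plain ``float`` arrays
accumulated on :class:`Tensor` objects; :meth:`Tensor.backward` walks the
tape in reverse topological order.

Every operation is exercised by numerical gradient checks in the test
suite, which is what makes hand-derived recurrent gradients unnecessary.
"""

from __future__ import annotations

import numpy as np

#: Working dtype for model parameters and constants.  Plain :class:`Tensor`
#: construction preserves an explicit float64 array, which the numerical
#: gradient checks rely on.
DTYPE = np.float32

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "zeros",
    "concat",
    "stack",
    "embedding",
    "batch_gather",
    "gather2d",
    "scatter_rows",
    "softmax_cross_entropy",
    "dropout",
    "RMSProp",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
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
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_n_uses")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float64)
        if data.dtype.kind != "f":
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None
        self._n_uses = 0

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph bookkeeping ---------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            if self._n_uses <= 1:
                # sole consumer: no further accumulation can happen, so the
                # incoming array can be borrowed (it is only ever read)
                self.grad = g if g.dtype == self.data.dtype else g.astype(self.data.dtype)
            else:
                self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def exp(self):
        return exp(self)

    def tanh(self):
        return tanh(self)

    def sigmoid(self):
        return sigmoid(self)


def _wrap(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, (int, float)):
        # keep python scalars at the working dtype so they never upcast
        return Tensor(np.asarray(x, dtype=DTYPE))
    return Tensor(x)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=False)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape, dtype=DTYPE), requires_grad=False)


def _make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward(out)
        for p in parents:
            if p.requires_grad:
                p._n_uses += 1
    return out


# -- arithmetic ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad, b.data.shape))
        return run

    return _make(a.data + b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad * a.data, b.data.shape))
        return run

    return _make(a.data * b.data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-out.grad * a.data / (b.data ** 2), b.data.shape))
        return run

    return _make(a.data / b.data, (a, b), bw)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only; reshape first")

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(out.grad @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ out.grad)
        return run

    return _make(a.data @ b.data, (a, b), bw)


# -- nonlinearities -------------------------------------------------------

def exp(a) -> Tensor:
    a = _wrap(a)
    val = np.exp(a.data)

    def bw(out):
        def run():
            a._accumulate(out.grad * out.data)
        return run

    return _make(val, (a,), bw)


def log(a) -> Tensor:
    a = _wrap(a)

    def bw(out):
        def run():
            a._accumulate(out.grad / a.data)
        return run

    return _make(np.log(a.data), (a,), bw)


def tanh(a) -> Tensor:
    a = _wrap(a)
    val = np.tanh(a.data)

    def bw(out):
        def run():
            a._accumulate(out.grad * (1.0 - out.data ** 2))
        return run

    return _make(val, (a,), bw)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    val = 1.0 / (1.0 + np.exp(-a.data))

    def bw(out):
        def run():
            a._accumulate(out.grad * out.data * (1.0 - out.data))
        return run

    return _make(val, (a,), bw)


def maximum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    take_a = a.data >= b.data  # ties route to the first argument

    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad * take_a, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad * (~take_a), b.data.shape))
        return run

    return _make(np.maximum(a.data, b.data), (a, b), bw)


# -- shape / reduction ----------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)

    def bw(out):
        def run():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        return run

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.data.shape

    def bw(out):
        def run():
            a._accumulate(out.grad.reshape(old))
        return run

    return _make(a.data.reshape(shape), (a,), bw)


def getitem(a, idx) -> Tensor:
    """Basic (non-repeating) indexing: ints and slices.

    The gradient is written in place into one shared buffer per source
    tensor, so slicing a tensor into many views (e.g. per-time-step inputs)
    costs a single allocation.
    """
    a = _wrap(a)

    def bw(out):
        def run():
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            a.grad[idx] += out.grad
        return run

    return _make(a.data[idx], (a,), bw)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        def run():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(out.grad[tuple(sl)])
        return run

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def stack(tensors, axis=1) -> Tensor:
    """Stack equal-shape tensors along a new axis (via reshape+concat)."""
    expanded = []
    for t in tensors:
        t = _wrap(t)
        shp = list(t.data.shape)
        shp.insert(axis, 1)
        expanded.append(reshape(t, tuple(shp)))
    return concat(expanded, axis=axis)


# -- gathers --------------------------------------------------------------

def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup `table[ids]`; gradient scatter-adds into the table."""
    ids = np.asarray(ids)

    def bw(out):
        def run():
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            np.add.at(table.grad, ids.reshape(-1),
                      out.grad.reshape(-1, table.data.shape[1]))
        return run

    return _make(table.data[ids], (table,), bw)


def gather2d(x: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """out[k] = x[rows[k], cols[k]] for a 2-D tensor; scatter-add gradient."""

    def bw(out):
        def run():
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            np.add.at(x.grad, (rows, cols), out.grad)
        return run

    return _make(x.data[rows, cols], (x,), bw)


def scatter_rows(src: Tensor, rows: np.ndarray, cols: np.ndarray,
                 shape: tuple[int, int]) -> Tensor:
    """Place packed rows ``src[k]`` at ``out[rows[k], cols[k], :]`` of a
    zero-initialized (R, L, D) tensor.  (rows, cols) pairs must be unique."""

    data = np.zeros((*shape, src.data.shape[1]), dtype=src.data.dtype)
    data[rows, cols] = src.data

    def bw(out):
        def run():
            src._accumulate(out.grad[rows, cols])
        return run

    return _make(data, (src,), bw)


def batch_gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """out[b, t] = x[b, idx[b, t]] for a (B, M, ...) tensor."""
    idx = np.asarray(idx)
    bidx = np.arange(x.data.shape[0])[:, None]

    def bw(out):
        def run():
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            np.add.at(x.grad, (bidx, idx), out.grad)
        return run

    return _make(x.data[bidx, idx], (x,), bw)


# -- losses / regularization ----------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()

    def bw(out):
        def run():
            g = probs.copy()
            g[np.arange(n), labels] -= 1.0
            logits._accumulate(out.grad * g / n)
        return run

    return _make(np.asarray(loss), (logits,), bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when `train` is false or rate is 0."""
    if not train or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / x.data.dtype.type(keep)
    return mul(x, Tensor(mask))


# -- optimizer --------------------------------------------------------------

class RMSProp:
    """Root-mean-square propagation with Keras-style defaults."""

    def __init__(self, params, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._cache = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, c in zip(self.params, self._cache):
            if p.grad is None:
                continue
            c *= self.rho
            c += (1.0 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)
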
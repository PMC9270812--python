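"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph networks in this package need:
dense linear algebra, elementwise nonlinearities, row gathering, segment
reductions over sorted-or-unsorted integer ids, and concatenation. Gradients
are accumulated in float64 for run-to-run reproducibility on a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Adam",
    "concat",
    "transpose",
    "gather",
    "segment_sum",
    "segment_max",
    "segment_softmax",
    "masked_row_softmax",
    "relu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "softplus",
    "bce_with_logits",
    "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ---------------------------------------------------
    def backward(self):
        order, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            order.append(node)

        visit(self)
        for node in order:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def back(g):
            self._accum(g)
            other._accum(g)

        return Tensor(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accum(-g)

        return Tensor(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def back(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def back(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        return Tensor(self.data / other.data, (self, other), back)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def back(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, (self, other), back)

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                g = np.asarray(g)
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self):
        return self.sum() * (1.0 / self.data.size)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities ---------------------------------------------

def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def back(g):
        t._accum(g * mask)

    return Tensor(t.data * mask, (t,), back)


def sigmoid(t: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(t.data, -60, 60)))

    def back(g):
        t._accum(g * out * (1.0 - out))

    return Tensor(out, (t,), back)


def tanh(t: Tensor) -> Tensor:
    out = np.tanh(t.data)

    def back(g):
        t._accum(g * (1.0 - out ** 2))

    return Tensor(out, (t,), back)


def exp(t: Tensor) -> Tensor:
    out = np.exp(np.clip(t.data, -700, 700))

    def back(g):
        t._accum(g * out)

    return Tensor(out, (t,), back)


def log(t: Tensor) -> Tensor:
    def back(g):
        t._accum(g / t.data)

    return Tensor(np.log(t.data), (t,), back)


def softplus(t: Tensor) -> Tensor:
    out = np.logaddexp(0.0, t.data)
    sig = 1.0 / (1.0 + np.exp(-np.clip(t.data, -60, 60)))

    def back(g):
        t._accum(g * sig)

    return Tensor(out, (t,), back)


# -- structural ops ----------------------------------------------------------

def gather(t: Tensor, idx) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def back(g):
        gx = np.zeros_like(t.data)
        np.add.at(gx, idx, g)
        t._accum(gx)

    return Tensor(t.data[idx], (t,), back)


def segment_sum(t: Tensor, seg_ids, num_segments: int) -> Tensor:
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out, seg_ids, t.data)

    def back(g):
        t._accum(g[seg_ids])

    return Tensor(out, (t,), back)


def segment_max(t: Tensor, seg_ids, num_segments: int) -> Tensor:
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out = np.full((num_segments,) + t.data.shape[1:], -np.inf, dtype=np.float64)
    np.maximum.at(out, seg_ids, t.data)
    # tie-share: gradient splits evenly across positions attaining the max
    hit = (t.data == out[seg_ids]).astype(np.float64)
    counts = np.zeros_like(out)
    np.add.at(counts, seg_ids, hit)

    def back(g):
        t._accum(g[seg_ids] * hit / np.maximum(counts[seg_ids], 1.0))

    return Tensor(out, (t,), back)


def segment_softmax(t: Tensor, seg_ids, num_segments: int) -> Tensor:
    """Softmax of a column vector within each segment; weights sum to 1."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    m = np.full((num_segments,) + t.data.shape[1:], -np.inf)
    np.maximum.at(m, seg_ids, t.data)
    shifted = t - Tensor(m[seg_ids])
    e = exp(shifted)
    denom = segment_sum(e, seg_ids, num_segments)
    return e / gather(denom, seg_ids)


def masked_row_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax of `scores + mask`; mask uses large negatives to
    exclude cross-block attention. Rows of the result sum to 1."""
    masked = scores + Tensor(mask)
    m = masked.data.max(axis=1, keepdims=True)
    e = exp(masked - Tensor(m))
    denom = e.sum(axis=1, keepdims=True)
    return e / denom


def transpose(t: Tensor) -> Tensor:
    def back(g):
        t._accum(g.T)

    return Tensor(t.data.T, (t,), back)


def concat(tensors, axis=1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back)


def bce_with_logits(logits: Tensor, targets) -> Tensor:
    """Mean binary cross-entropy from raw logits (numerically stable)."""
    y = Tensor(np.asarray(targets, dtype=np.float64).reshape(logits.data.shape))
    return (softplus(logits) - logits * y).mean()


# -- parameters and optimization ---------------------------------------------

def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)), requires_grad=True)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
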
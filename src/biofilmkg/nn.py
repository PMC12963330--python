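"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph models in this package need:
broadcasted arithmetic, 2-D matmul, the usual activations, row
gather/scatter, and a per-segment softmax used for neighborhood
attention.  Everything is float64 and CPU-only; the models here have a
few thousand parameters, so clarity wins over speed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    """A numpy array plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(p for p in _parents if p.requires_grad)
        self._backward = _backward if self.requires_grad else None

    # -- shape helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff machinery -------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        _accumulate(self, np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _coerce(other)
        out_data = self.data + other.data

        def bw(g):
            _accumulate(self, g)
            _accumulate(other, g)

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            _accumulate(self, -g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-_coerce(other))

    def __rsub__(self, other):
        return _coerce(other) + (-self)

    def __mul__(self, other):
        other = _coerce(other)
        out_data = self.data * other.data

        def bw(g):
            _accumulate(self, g * other.data)
            _accumulate(other, g * self.data)

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Tensor):
            return self * (1.0 / np.asarray(other, dtype=np.float64))
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def bw(g):
            _accumulate(self, g * e * self.data ** (e - 1.0))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def __matmul__(self, other):
        other = _coerce(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bw(g):
            _accumulate(self, g @ b.T)
            _accumulate(other, a.T @ g)

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    # -- reductions / reshaping ---------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            _accumulate(self, np.broadcast_to(gg, self.data.shape))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            _accumulate(self, g.reshape(orig))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    # -- elementwise nonlinearities -----------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            _accumulate(self, g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def leaky_relu(self, negative_slope: float = 0.2):
        mask = self.data > 0
        slope = np.where(mask, 1.0, negative_slope)

        def bw(g):
            _accumulate(self, g * slope)

        return Tensor(self.data * slope, _parents=(self,), _backward=bw)

    def sigmoid(self):
        s = expit(self.data)

        def bw(g):
            _accumulate(self, g * s * (1.0 - s))

        return Tensor(s, _parents=(self,), _backward=bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            _accumulate(self, g * e)

        return Tensor(e, _parents=(self,), _backward=bw)

    def log(self):
        def bw(g):
            _accumulate(self, g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    # -- indexing ------------------------------------------------------
    def gather(self, idx):
        idx = np.asarray(idx, dtype=np.intp)

        def bw(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                _accumulate(self, buf)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)

    @staticmethod
    def cat(tensors: Sequence["Tensor"], axis: int = 0):
        tensors = [_coerce(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _accumulate(t, g[tuple(sl)])

        return Tensor(out_data, _parents=tuple(tensors), _backward=bw)


def _coerce(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _unbroadcast(np.asarray(g, dtype=np.float64), t.data.shape)
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad = t.grad + g


# ---------------------------------------------------------------------
# graph-specific primitives
# ---------------------------------------------------------------------

def segment_softmax(logits: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a 1-D logit vector within groups given by ``segments``.

    Used to normalize attention coefficients over each node's incoming
    edges.  Entries whose segment has a single member get weight 1.
    """
    segments = np.asarray(segments, dtype=np.intp)
    x = logits.data
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, segments, x)
    ex = np.exp(x - seg_max[segments])
    seg_sum = np.zeros(n_segments)
    np.add.at(seg_sum, segments, ex)
    alpha = ex / seg_sum[segments]

    def bw(g):
        dot = np.zeros(n_segments)
        np.add.at(dot, segments, alpha * g)
        _accumulate(logits, alpha * (g - dot[segments]))

    return Tensor(alpha, _parents=(logits,), _backward=bw)


def scatter_sum(values: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``values`` (E x d) into ``n_segments`` output rows."""
    segments = np.asarray(segments, dtype=np.intp)
    out_data = np.zeros((n_segments,) + values.data.shape[1:])
    np.add.at(out_data, segments, values.data)

    def bw(g):
        _accumulate(values, g[segments])

    return Tensor(out_data, _parents=(values,), _backward=bw)


def log_softmax(logits: Tensor) -> Tensor:
    """Row-wise log-softmax (stable; the max shift is treated as constant)."""
    m = logits.data.max(axis=1, keepdims=True)
    z = logits - m
    lse = z.exp().sum(axis=1, keepdims=True).log()
    return z - lse


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or no rng is supplied."""
    if not training or rng is None or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * mask


class BatchNorm1d:
    """Batch normalization over axis 0 with running statistics.

    Training here is full-batch, so the batch statistics are already the
    full-data statistics; momentum defaults to 1.0 (running stats track
    the latest full batch exactly), which keeps eval-mode outputs
    consistent with the state the optimizer actually saw.
    """

    def __init__(self, dim: int, momentum: float = 1.0, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * ((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def set_buffers(self, bufs):
        self.running_mean, self.running_var = [np.array(b) for b in bufs]


class Adam:
    """Adam with (classic) L2 weight decay added to the gradient."""

    def __init__(self, params: Iterable[Tensor], lr: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
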
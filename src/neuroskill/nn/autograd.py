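"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

Only the operations the skill classifier needs are implemented: broadcasting
arithmetic, batched matmul, pointwise nonlinearities, slicing/stacking, a
time-distributed 1-D convolution and max-pool, a masked softmax (for
attention over padded sequences) and a class-weighted softmax cross-entropy.
Gradients are exact (verified against central differences in the test
suite).  float32 throughout; graphs are built per call and freed after
``backward``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph machinery ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
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
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            node._backward = None
            node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32).copy()
        else:
            self.grad += g

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        return Tensor(self.data + other.data, _parents=(self, other),
                      _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        return Tensor(self.data * other.data, _parents=(self, other),
                      _backward=bw)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._wrap(other)
        out = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        return Tensor(out, _parents=(self, other), _backward=bw)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------
    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1 - out * out))
        return Tensor(out, _parents=(self,), _backward=bw)

    def sigmoid(self):
        x = np.clip(self.data, -60.0, 60.0)   # saturates anyway; avoids overflow
        out = 1.0 / (1.0 + np.exp(-x))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out * (1 - out))
        return Tensor(out, _parents=(self,), _backward=bw)

    def relu(self):
        pos = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * pos)
        return Tensor(self.data * pos, _parents=(self,), _backward=bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))
        return Tensor(self.data.reshape(*shape), _parents=(self,),
                      _backward=bw)

    def __getitem__(self, key):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)
        return Tensor(self.data[key], _parents=(self,), _backward=bw)

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())
        return Tensor(out, _parents=(self,), _backward=bw)

    def square_sum(self) -> "Tensor":
        """sum(x**2) — used for L2 penalties."""
        def bw(g):
            if self.requires_grad:
                self._accum(2.0 * g * self.data)
        return Tensor(np.sum(self.data**2), _parents=(self,), _backward=bw)


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))
    return Tensor(out, _parents=tuple(tensors), _backward=bw)


def conv1d_timedist(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1-D convolution along the sample axis, per temporal step.

    x: (N, T, L, F); w: (K, F, M); b: (M,) -> (N, T, L-K+1, M).
    Implemented as K shifted matmuls to avoid materializing an im2col
    buffer.
    """
    k = w.data.shape[0]
    lo = x.data.shape[2] - k + 1
    out = np.zeros(x.data.shape[:2] + (lo, w.data.shape[2]), dtype=np.float32)
    for j in range(k):
        out += x.data[:, :, j:j + lo, :] @ w.data[j]
    out += b.data

    def bw(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for j in range(k):
                gw[j] = np.tensordot(x.data[:, :, j:j + lo, :], g,
                                     axes=([0, 1, 2], [0, 1, 2]))
            w._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for j in range(k):
                gx[:, :, j:j + lo, :] += g @ w.data[j].T
            x._accum(gx)
    return Tensor(out, _parents=(x, w, b), _backward=bw)


def maxpool1d_timedist(x: Tensor, pool: int) -> Tensor:
    """Max-pool along the sample axis per temporal step; trims the remainder.

    x: (N, T, L, M) -> (N, T, L // pool, M).
    """
    n, t, L, m = x.data.shape
    lo = L // pool
    xr = x.data[:, :, :lo * pool, :].reshape(n, t, lo, pool, m)
    arg = xr.argmax(axis=3)
    out = np.take_along_axis(xr, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros((n, t, lo, pool, m), dtype=np.float32)
        np.put_along_axis(gx, arg[:, :, :, None, :], g[:, :, :, None, :],
                          axis=3)
        full = np.zeros_like(x.data)
        full[:, :, :lo * pool, :] = gx.reshape(n, t, lo * pool, m)
        x._accum(full)
    return Tensor(out, _parents=(x,), _backward=bw)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis with masked positions forced to weight 0.

    ``mask`` is a boolean array broadcastable to ``scores``; False positions
    get probability exactly 0 (their score is treated as -inf).
    """
    s = np.where(mask, scores.data, -np.inf)
    smax = s.max(axis=-1, keepdims=True)
    smax = np.where(np.isfinite(smax), smax, 0.0)
    e = np.exp(s - smax)
    z = e.sum(axis=-1, keepdims=True)
    out = np.where(z > 0, e / np.maximum(z, 1e-30), 0.0)

    def bw(g):
        if scores.requires_grad:
            dot = (g * out).sum(axis=-1, keepdims=True)
            scores._accum(out * (g - dot))
    return Tensor(out.astype(np.float32), _parents=(scores,), _backward=bw)


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray,
                           sample_weights: np.ndarray) -> Tensor:
    """Weighted-mean softmax cross-entropy (weights normalized to sum 1).

    loss = sum_i w_i * (-log p_{i, y_i}) / sum_i w_i.  With all weights
    equal this reduces exactly to the unweighted mean cross-entropy, and
    rescaling all weights by a constant leaves the loss (and gradient)
    unchanged.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    w = np.asarray(sample_weights, dtype=np.float64)
    wsum = w.sum()
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    loss = float((w * nll).sum() / wsum)

    def bw(g):
        if logits.requires_grad:
            onehot = np.zeros_like(p)
            onehot[np.arange(n), labels] = 1.0
            glog = (w[:, None] / wsum) * (p - onehot) * g
            logits._accum(glog.astype(np.float32))
    return Tensor(loss, _parents=(logits,), _backward=bw)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adaptive-moment optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
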
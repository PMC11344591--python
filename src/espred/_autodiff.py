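"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the package's lightweight neural-network engine: a tape-based
``Tensor`` supporting the operations the spectral predictors need
(dense affine maps, ReLU/sigmoid/softmax nonlinearities, segment
reductions for message passing over molecular graphs, gathers for the
neutral-loss re-indexing of the bidirectional head), plus an Adam
optimizer. Gradients follow the standard chain rule on a topologically
sorted tape; broadcasting is handled by summing gradients over
broadcast axes.

Everything is float64 by default for reproducibility; training code may
pass float32 arrays for speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "relu", "sigmoid", "softmax", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if not isinstance(data, np.ndarray) else data.dtype)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinear -----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        val = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * val * (1.0 - val))

        out._backward = bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        val = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                dot = (g * val).sum(axis=axis, keepdims=True)
                self._accum(val * (g - dot))

        out._backward = bw
        return out

    def clip_min(self, lo: float) -> "Tensor":
        """max(x, lo); subgradient passes where x > lo."""
        mask = self.data > lo
        out = Tensor(np.where(mask, self.data, lo), self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    # -- shape / indexing ----------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        out._backward = bw
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g.T)

        out._backward = bw
        return out

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        out = Tensor(self.data[:, start:stop], self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, start:stop] = g
                self._accum(full)

        out._backward = bw
        return out

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Select rows ``self[index]`` (index may repeat)."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accum(full)

        out._backward = bw
        return out

    def gather2d(self, index: np.ndarray) -> "Tensor":
        """Per-row gather along axis 1: out[i, j] = self[i, index[i, j]]."""
        index = np.asarray(index, dtype=np.intp)
        rows = np.arange(self.data.shape[0])[:, None]
        out = Tensor(self.data[rows, index], self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, (np.broadcast_to(rows, index.shape), index), g)
                self._accum(full)

        out._backward = bw
        return out

    def segment_sum(self, index: np.ndarray, n_segments: int) -> "Tensor":
        """Sum rows into ``n_segments`` buckets: out[s] = sum over i with index[i]==s."""
        index = np.asarray(index, dtype=np.intp)
        val = np.zeros((n_segments,) + self.data.shape[1:], dtype=self.data.dtype)
        np.add.at(val, index, self.data)
        out = Tensor(val, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accum(g[index])

        out._backward = bw
        return out

    # -- backward ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return x.softmax(axis=axis)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), any(t.requires_grad for t in tensors))
    out._parents = tuple(tensors)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

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
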
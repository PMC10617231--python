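"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the primitives the label-embedding transformer needs:
broadcast-aware arithmetic, batched matmul, softmax, sigmoid, reductions,
shape ops, slicing and concatenation. Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward`, which topologically sorts the
recorded graph. All computation is float64.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True
_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the float dtype newly created tensors use (float64 default;
    float32 roughly halves training time at desk scale)."""
    global _DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = dtype.type


def get_default_dtype():
    return _DTYPE


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily switch the tensor dtype (e.g. float32 for big runs)."""
    global _DTYPE
    prev = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        _DTYPE = prev


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (inference / evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_owns_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self._owns_grad = False

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        # First contribution is stored by reference (possibly aliasing the
        # child's grad or a broadcast view); a second contribution forces a
        # fresh owned array, so shared buffers are never mutated in place.
        if self.grad is None:
            self.grad = g
            self._owns_grad = False
        elif self._owns_grad:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._owns_grad = True

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        self._owns_grad = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (Tensor._lift(other) ** -1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * (self ** -1.0)

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._make(a.data ** p, (a,), bwd)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bwd)

    def relu(self):
        a = self
        m = a.data > 0

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * m)

        return Tensor._make(a.data * m, (a,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclipped."""
        a = self
        inside = (a.data >= lo) & (a.data <= hi)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * inside)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bwd)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if a.requires_grad:
                inner = (g * s).sum(axis=axis, keepdims=True)
                a._accumulate(s * (g - inner))

        return Tensor._make(s, (a,), bwd)

    # -- reductions & shape ops ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        old = a.shape

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bwd)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), bwd)

    def __getitem__(self, idx):
        a = self
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple) and all(isinstance(k, (int, slice)) for k in idx))

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                if basic:
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bwd)

    def sqrt(self):
        return self ** 0.5


def concatenate(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, bwd)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class AdamW:
    """Decoupled-weight-decay Adam over a list of :class:`Parameter`."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                g = np.zeros_like(p.data)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)
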
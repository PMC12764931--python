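"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients.  The op set is exactly what the encoders,
the heterogeneous aggregator and the training objectives need: broadcasted
arithmetic, (batched) matmul, the usual pointwise nonlinearities, softmax
with additive biases, row gather/scatter, segment softmax/sum for edgewise
attention, layer norm and dropout.  Everything is float32 and deterministic
given the seeds handed to the stochastic ops.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _as_array(x) -> np.ndarray:
    # float arrays keep their precision (float64 inputs stay float64, e.g.
    # for high-tolerance oracle checks); everything else becomes float32
    if isinstance(x, np.ndarray) and np.issubdtype(x.dtype, np.floating):
        return x
    if isinstance(x, np.floating):  # 0-d reduction results keep their dtype
        return np.asarray(x)
    return np.asarray(x, dtype=np.float32)


def _scatter_plan(index: np.ndarray):
    """Precompute a sorted-reduce plan for scatter-add on repeated indices.

    Returns (None, None, None) when indices are distinct (plain assignment
    suffices), else (argsort order, reduceat starts, unique indices)."""
    if len(index) == 0:
        return None, None, None
    order = np.argsort(index, kind="stable")
    s = index[order]
    if len(s) == len(np.unique(s)):
        return None, None, None
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    return order, starts, s[starts]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 stretched by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name
        self._grad_owned = False

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None
        self._grad_owned = False

    def _accumulate(self, g: np.ndarray):
        # first contribution is stored by reference (never mutated in place);
        # later contributions allocate once and accumulate in the owned buffer
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS postorder (graphs can be deep at K layers x epochs)
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents, backward):
        requires = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=requires)
        if requires:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        if isinstance(other, (int, float)):  # weak scalar: dtype preserved
            out_data = self.data + other

            def backward(g):
                self._accumulate(g)

            return Tensor._make(out_data, (self,), backward)
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):  # weak scalar: dtype preserved
            out_data = self.data * other

            def backward(g):
                self._accumulate(g * other)

            return Tensor._make(out_data, (self,), backward)
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            self._accumulate(g * (self.data > 0.0))

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        out_data = np.where(self.data > 0.0, self.data, slope * self.data)

        def backward(g):
            self._accumulate(g * np.where(self.data > 0.0, 1.0, slope))

        return Tensor._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        out_data = np.where(self.data > 0.0, self.data, alpha * (np.exp(self.data) - 1.0))

        def backward(g):
            self._accumulate(g * np.where(self.data > 0.0, 1.0, out_data + alpha))

        return Tensor._make(out_data, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- shape / view
    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(out_data, (self,), backward)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    def gather_rows(self, index: np.ndarray):
        """Rows along axis 0 by integer index (embedding lookup)."""
        index = np.asarray(index, dtype=np.int64)
        out_data = self.data[index]
        order, starts, uniq = _scatter_plan(index)

        def backward(g):
            full = np.zeros_like(self.data)
            if order is None:
                full[index] = g
            else:
                full[uniq] = np.add.reduceat(g[order], starts, axis=0)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    # --------------------------------------------------------------- softmax
    def softmax(self, axis: int = -1, mask: np.ndarray | None = None):
        """Softmax along `axis`; `mask` (bool, True = valid) zeroes invalid slots."""
        x = self.data
        if mask is not None:
            x = np.where(mask, x, -1e30)
        x = x - x.max(axis=axis, keepdims=True)
        e = np.exp(x)
        if mask is not None:
            e = np.where(mask, e, 0.0)
        denom = e.sum(axis=axis, keepdims=True)
        out_data = e / np.maximum(denom, 1e-30)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        x = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
        out_data = x - lse

        def backward(g):
            sm = np.exp(out_data)
            self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), backward)

    # ------------------------------------------------------- segment ops (GAT)
    def segment_softmax(self, segments: np.ndarray, n_segments: int):
        """Softmax over entries sharing a segment id (axis 0); extra axes ride along."""
        seg = np.asarray(segments, dtype=np.int64)
        x = self.data
        order, starts, uniq = _scatter_plan(seg)

        def seg_reduce(values, ufunc, fill):
            out = np.full((n_segments,) + values.shape[1:], fill, dtype=np.float32)
            if order is None:
                out[seg] = values
            else:
                out[uniq] = ufunc.reduceat(values[order], starts, axis=0)
            return out

        mx = seg_reduce(x, np.maximum, -np.inf)
        e = np.exp(x - mx[seg])
        denom = seg_reduce(e, np.add, 0.0)
        out_data = e / np.maximum(denom[seg], 1e-30)

        def backward(g):
            dot = seg_reduce(g * out_data, np.add, 0.0)
            self._accumulate(out_data * (g - dot[seg]))

        return Tensor._make(out_data, (self,), backward)

    def segment_sum(self, segments: np.ndarray, n_segments: int):
        """Sum entries (axis 0) into `n_segments` buckets."""
        seg = np.asarray(segments, dtype=np.int64)
        order, starts, uniq = _scatter_plan(seg)
        out_data = np.zeros((n_segments,) + self.data.shape[1:], dtype=np.float32)
        if order is None:
            out_data[seg] = self.data
        elif len(seg):
            out_data[uniq] = np.add.reduceat(self.data[order], starts, axis=0)

        def backward(g):
            self._accumulate(g[seg])

        return Tensor._make(out_data, (self,), backward)

    # ------------------------------------------------------------- norm/drop
    def layer_norm(self, eps: float = 1e-5):
        """Normalize the last axis to zero mean, unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out_data = xc * inv

        def backward(g):
            n = self.data.shape[-1]
            gm = g.mean(axis=-1, keepdims=True)
            gxhat = (g * out_data).mean(axis=-1, keepdims=True)
            self._accumulate(inv * (g - gm - out_data * gxhat))

        return Tensor._make(out_data, (self,), backward)

    def dropout(self, rate: float, rng: np.random.Generator, training: bool):
        if not training or rate <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
        return self * Tensor(keep)


def concat(tensors: list, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list, axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
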
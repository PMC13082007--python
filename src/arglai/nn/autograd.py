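"""Reverse-mode automatic differentiation on numpy arrays.

A small tape: each :class:`Tensor` records its parents and a closure that
accumulates gradients into them.  ``backward()`` runs the closures in
reverse topological order.  The op set is exactly what the attention
blocks and MLPs in this package need — broadcasting elementwise
arithmetic, two-operand einsum, table gather (embeddings and
relative-position rows), exp/log/relu/sqrt-via-pow, axis reductions and
shape ops.  Gradient correctness is enforced by finite-difference tests.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "einsum", "gather", "relu", "softmax", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _backward: Optional[Callable[[np.ndarray], None]] = None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(grad, self.data.shape),
                                 dtype=self.data.dtype)
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        if isinstance(other, (int, float)):   # scalar path keeps dtype
            out = Tensor(self.data + float(other), _parents=(self,))

            def bw_s(g):
                if self.requires_grad:
                    self._accumulate(g)
            out._backward = bw_s
            return out
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):   # scalar path keeps dtype
            other = float(other)
            out = Tensor(self.data * other, _parents=(self,))

            def bw_s(g):
                if self.requires_grad:
                    self._accumulate(g * other)
            out._backward = bw_s
            return out
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))
        out._backward = bw
        return out

    # -- reductions and shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))
        out._backward = bw
        return out

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        data = np.exp(self.data)
        out = Tensor(data, _parents=(self,))

        # closure must not capture ``out`` (reference cycle -> gc pressure)
        def bw(g):
            if self.requires_grad:
                self._accumulate(g * data)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = bw
        return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))
    out._backward = bw
    return out


def einsum(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with autodiff.

    Requires explicit subscripts with no index repeated inside one operand
    and every input index present in the other operand or the output —
    true for projections, attention scores and value aggregation.
    """
    lhs, out_sub = subscripts.split("->")
    a_sub, b_sub = lhs.split(",")
    out = Tensor(np.einsum(subscripts, a.data, b.data, optimize=True),
                 _parents=(a, b))

    def grad_operand(other_sub, other_data, target_sub, target_shape, g):
        # An operand without "..." needs its broadcast dims summed out.
        # Flatten the batch dims into one contracted index so the whole
        # reduction is a single GEMM instead of a materialized outer
        # product summed afterwards.
        if "..." not in target_sub and "..." in out_sub \
                and "..." in other_sub:
            g_core = out_sub.replace("...", "")
            o_core = other_sub.replace("...", "")
            nb = g.ndim - len(g_core)
            g2 = g.reshape(-1, *g.shape[nb:])
            o2 = np.broadcast_to(
                other_data, g.shape[:nb] + other_data.shape[
                    other_data.ndim - len(o_core):]).reshape(
                -1, *other_data.shape[other_data.ndim - len(o_core):])
            used = set(g_core + o_core + target_sub)
            batch = next(c for c in "zyxwvutsrq" if c not in used)
            return np.einsum(f"{batch}{g_core},{batch}{o_core}->{target_sub}",
                             g2, o2, optimize=True)
        if "..." not in target_sub and ("..." in out_sub
                                        or "..." in other_sub):
            res = np.einsum(f"{out_sub},{other_sub}->...{target_sub}",
                            g, other_data, optimize=True)
            extra = res.ndim - len(target_shape)
            if extra:
                res = res.sum(axis=tuple(range(extra)))
            return res
        return np.einsum(f"{out_sub},{other_sub}->{target_sub}", g,
                         other_data, optimize=True)

    def bw(g):
        if a.requires_grad:
            a._accumulate(grad_operand(b_sub, b.data, a_sub, a.data.shape, g))
        if b.requires_grad:
            b._accumulate(grad_operand(a_sub, a.data, b_sub, b.data.shape, g))
    out._backward = bw
    return out


def gather(table: Tensor, index: np.ndarray) -> Tensor:
    """``table[index]`` for a 2-D table and integer index array.

    Output shape is ``index.shape + (table.shape[1],)``.  Backward
    scatter-adds into the selected rows (np.add.at handles duplicates).
    """
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(table.data[index], _parents=(table,))

    def bw(g):
        if table.requires_grad:
            L, d = table.data.shape
            flat_idx = index.ravel()
            flat_g = g.reshape(-1, d)
            acc = np.empty_like(table.data)
            for c in range(d):    # bincount is far faster than np.add.at
                acc[:, c] = np.bincount(flat_idx, weights=flat_g[:, c],
                                        minlength=L)
            table._accumulate(acc)
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row softmax with max-subtraction (the max is a stopped gradient)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = bw
    return out
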
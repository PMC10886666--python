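"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's neural components (identity encoder, attention MIL, MISL) are
small enough that a compact tape-based engine is sufficient: tensors record
their parents and a per-edge gradient function, and ``backward`` walks the
tape in reverse topological order. Only the operations those models need are
implemented (broadcasting arithmetic, matmul, strided 2-D convolution,
elementwise nonlinearities, reductions, gather, cumulative sum).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "precision", "DTYPE"]

#: dtype used for newly created tensors; float32 roughly halves CNN cost
DTYPE = np.float64


class precision:
    """Context manager switching the working dtype (e.g. ``precision("float32")``)."""

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        global DTYPE
        self._saved = DTYPE
        DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global DTYPE
        DTYPE = self._saved
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # sequence of (parent_tensor, grad_fn) edges
        self._parents = tuple(_parents)

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent, _ in it:
                    if id(parent) not in seen:
                        seen.add(id(parent))
                        stack.append((parent, iter(parent._parents)))
                        advanced = True
                        break
                if not advanced:
                    order.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, grad_fn in node._parents:
                contrib = grad_fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data + other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor(
            a * b,
            _parents=(
                (self, lambda g: _unbroadcast(g * b, a.shape)),
                (other, lambda g: _unbroadcast(g * a, b.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor(
            a / b,
            _parents=(
                (self, lambda g: _unbroadcast(g / b, a.shape)),
                (other, lambda g: _unbroadcast(-g * a / (b * b), b.shape)),
            ),
        )

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor(
            a @ b,
            _parents=(
                (self, lambda g: g @ b.swapaxes(-1, -2)),
                (other, lambda g: a.swapaxes(-1, -2) @ g),
            ),
        )

    # -- elementwise ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, _parents=((self, lambda g: g * out_data),))

    def log(self):
        return Tensor(np.log(self.data), _parents=((self, lambda g: g / self.data),))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, _parents=((self, lambda g: g * mask),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor(out_data, _parents=((self, lambda g: g * (1.0 - out_data**2)),))

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor(
            out_data, _parents=((self, lambda g: g * out_data * (1.0 - out_data)),)
        )

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g_exp, shape).copy()

        return Tensor(out_data, _parents=((self, grad_fn),))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor(
            self.data.reshape(*shape),
            _parents=((self, lambda g: g.reshape(orig)),),
        )

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            _parents=((self, lambda g: g.transpose(inv)),),
        )

    def take(self, indices, axis: int = 0):
        """Gather along ``axis``; backward scatter-adds."""
        indices = np.asarray(indices)
        out_data = np.take(self.data, indices, axis=axis)
        shape = self.data.shape

        def grad_fn(g):
            out = np.zeros(shape, dtype=g.dtype)
            if axis == 0:
                np.add.at(out, indices, g)
            else:  # pragma: no cover - only axis 0 used by the models
                sl = [slice(None)] * len(shape)
                for k, idx in enumerate(indices):
                    sl[axis] = idx
                    out[tuple(sl)] += np.take(g, k, axis=axis)
            return out

        return Tensor(out_data, _parents=((self, grad_fn),))

    def cumsum(self, axis: int = 0):
        return Tensor(
            np.cumsum(self.data, axis=axis),
            _parents=(
                (
                    self,
                    lambda g: np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis),
                ),
            ),
        )

    # -- composite helpers ---------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = Tensor(self.data.max(axis=axis, keepdims=True))
        out = (self - m).exp().sum(axis=axis, keepdims=True).log() + m
        if not keepdims:
            out = out.reshape(*np.squeeze(out.data, axis=axis).shape)
        return out

    # -- convolution ----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1):
        """2-D convolution, NCHW layout, VALID padding."""
        x, w, b = self.data, weight.data, bias.data
        n, c, h, wd = x.shape
        f, _, k, _ = w.shape
        oh = (h - k) // stride + 1
        ow = (wd - k) // stride + 1
        cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = x[
                    :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
                ]
        cols2 = cols.reshape(n, c * k * k, oh * ow)
        wf = w.reshape(f, c * k * k)
        out_data = (wf @ cols2).reshape(n, f, oh, ow) + b.reshape(1, f, 1, 1)

        def grad_x(g):
            gf = g.reshape(n, f, oh * ow)
            dcols = (wf.T @ gf).reshape(n, c, k, k, oh, ow)
            dx = np.zeros_like(x)
            for i in range(k):
                for j in range(k):
                    dx[
                        :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
                    ] += dcols[:, :, i, j]
            return dx

        def grad_w(g):
            gf = g.reshape(n, f, oh * ow)
            return np.einsum("nfp,ncp->fc", gf, cols2).reshape(w.shape)

        def grad_b(g):
            return g.sum(axis=(0, 2, 3))

        return Tensor(
            out_data,
            _parents=((self, grad_x), (weight, grad_w), (bias, grad_b)),
        )


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_grad_fn(lo, hi):
        def grad_fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        return grad_fn

    parents = tuple(
        (t, make_grad_fn(offsets[i], offsets[i + 1])) for i, t in enumerate(tensors)
    )
    return Tensor(np.concatenate(datas, axis=axis), _parents=parents)
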
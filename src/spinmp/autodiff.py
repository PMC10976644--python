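"""Minimal reverse-mode automatic differentiation on numpy arrays.

The potentials in this package are small dense networks (feature widths of a
few dozen, molecules of tens of atoms), so a compact tape-based engine is all
that is required: elementwise arithmetic with numpy broadcasting, matrix
products, softplus, reductions, row gather/scatter, and row concatenation.
Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.

Only gradients with respect to *parameters* are ever needed (energies are the
sole prediction target; forces are out of scope), so geometric quantities —
distances, radial basis values, Ewald phase matrices — enter the tape as
constants.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softplus", "concat_rows", "segment_sum", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction -----------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(np.array(data, dtype=float), requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            return _unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)

        return Tensor(self.data - other.data, parents=(self, other), backward=bwd)

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            return g @ other.data.T, self.data.T @ g

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def square(self):
        return self * self

    # -- reductions & reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bwd(g):
            return (g.reshape(self.shape),)

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def take_rows(self, indices):
        """Gather rows (axis 0); gradient scatter-adds back."""
        indices = np.asarray(indices, dtype=int)

        def bwd(g):
            out = np.zeros_like(self.data)
            np.add.at(out, indices, g)
            return (out,)

        return Tensor(self.data[indices], parents=(self,), backward=bwd)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def softplus(x: Tensor | np.ndarray):
    """Numerically stable log(1 + exp(x))."""
    if not isinstance(x, Tensor):
        x = np.asarray(x, dtype=float)
        return np.logaddexp(0.0, x)
    val = np.logaddexp(0.0, x.data)

    def bwd(g):
        return (g / (1.0 + np.exp(-x.data)),)

    return Tensor(val, parents=(x,), backward=bwd)


def segment_sum(x: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets (scatter-add)."""
    segment_ids = np.asarray(segment_ids, dtype=int)
    out = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out, segment_ids, x.data)

    def bwd(g):
        return (g[segment_ids],)

    return Tensor(out, parents=(x,), backward=bwd)


def concat_rows(tensors: list[Tensor]) -> Tensor:
    """Concatenate along axis 0; gradient slices back."""
    sizes = [t.data.shape[0] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        return tuple(g[offsets[i] : offsets[i + 1]] for i in range(len(tensors)))

    return Tensor(np.concatenate([t.data for t in tensors], axis=0),
                  parents=tuple(tensors), backward=bwd)


class AdamW:
    """AdamW (decoupled weight decay) over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr_factor: float = 1.0):
        self.t += 1
        lr = self.lr * lr_factor
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
            self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g * g
            mhat = self._m[i] / (1 - self.beta1**self.t)
            vhat = self._v[i] / (1 - self.beta2**self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)
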
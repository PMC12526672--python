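"""A minimal reverse-mode automatic-differentiation core on NumPy arrays.

Just enough machinery for a transformer encoder: broadcast-aware elementwise
arithmetic, (batched) matmul, reshape/transpose/slice/concat, reductions,
softmax/log-softmax, ReLU, and an AdamW optimiser. Gradients are accumulated
by a topological backward sweep over the recorded tape.

The implementation favours clarity over generality; every operation used by
the model is covered by a finite-difference gradient check in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray, fresh: bool = False) -> None:
        """Add ``grad`` to this node's gradient.

        ``fresh`` promises the array is newly allocated and unshared, so it
        may be adopted without a defensive copy.
        """
        if self.grad is None:
            if grad.dtype != self.data.dtype:
                grad = grad.astype(self.data.dtype)
            elif not fresh:
                grad = grad.copy()
            self.grad = grad
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def _lift(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0:
            # keep python scalars from upcasting float32 graphs to float64
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape),
                                 fresh=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape),
                                  fresh=True)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        return self * self._lift(other) ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, parents=(self,))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0),
                                 fresh=True)

        out._backward = back
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        if self.ndim > 2 and self.shape[:-2] != other.shape[:-2]:
            raise ValueError("batched matmul requires identical batch shapes")
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2), fresh=True)
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g, fresh=True)

        out._backward = back
        return out

    # --------------------------------------------------------------- reshapes
    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = back
        return out

    def transpose(self, *axes: int) -> "Tensor":
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inverse = tuple(np.argsort(axes))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        out._backward = back
        return out

    def broadcast_to(self, shape: tuple[int, ...]) -> "Tensor":
        out = Tensor(np.broadcast_to(self.data, shape).copy(), parents=(self,))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))

        out._backward = back
        return out

    def __getitem__(self, index) -> "Tensor":
        out = Tensor(self.data[index], parents=(self,))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accumulate(full, fresh=True)

        out._backward = back
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis: int | tuple[int, ...] | None = None,
            keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def back(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy(),
                                 fresh=True)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy(),
                             fresh=True)

        out._backward = back
        return out

    def mean(self, axis: int | tuple[int, ...] | None = None,
             keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ activations
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0), parents=(self,))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (self.data > 0), fresh=True)

        out._backward = back
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out.data, fresh=True)

        out._backward = back
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        y = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(y, out=y)
        y /= y.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                if axis == -1:
                    inner = np.einsum("...i,...i->...", g, y)[..., None]
                else:
                    inner = (g * y).sum(axis=axis, keepdims=True)
                dx = g - inner
                dx *= y
                self._accumulate(dx, fresh=True)

        out._backward = back
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = Tensor(z - lse, parents=(self,))
        soft = np.exp(z - lse)

        def back(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g - soft * g.sum(axis=axis, keepdims=True),
                                 fresh=True)

        out._backward = back
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    parts = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis),
                 parents=tuple(parts))
    sizes = [p.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def back(g: np.ndarray) -> None:
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                p._accumulate(g[tuple(idx)])

    out._backward = back
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gamma + beta


def dropout(x: Tensor, p: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode needs an rng")
    mask = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(mask)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer class labels against (n, n_classes) logits."""
    n, c = logits.shape
    onehot = np.zeros((n, c), dtype=logits.data.dtype)
    onehot[np.arange(n), labels] = 1.0
    return -(logits.log_softmax(axis=-1) * Tensor(onehot)).sum() * (1.0 / n)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class AdamW:
    """Decoupled-weight-decay Adam on a list of :class:`Parameter`."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= (self.lr * update).astype(p.data.dtype)
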
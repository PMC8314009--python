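"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine sized to the models in this package: dense,
recurrent and 1-D convolutional layers over float64 arrays. Every operation
records a closure computing vector-Jacobian products; :meth:`Tensor.backward`
runs them in reverse topological order. Gradients are checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "maximum",
    "conv1d",
    "maxpool1d",
    "embedding_lookup",
    "softmax_cross_entropy",
    "sigmoid_binary_cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _child(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return self._child(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self.grad += -g

        return self._child(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return self._child(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += g @ np.swapaxes(other.data, -1, -2)
            if other.requires_grad:
                gw = np.swapaxes(self.data, -1, -2) @ g
                other.grad += _unbroadcast(gw, other.data.shape)

        return self._child(self.data @ other.data, (self, other), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                self.grad[key] += g

        return self._child(self.data[key], (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return self._child(self.data.reshape(*shape), (self,), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self.grad += g * mask

        return self._child(self.data * mask, (self,), backward)

    def elu(self, alpha: float = 1.0):
        out_data = np.where(self.data > 0, self.data, alpha * np.expm1(self.data))

        def backward(g):
            if self.requires_grad:
                self.grad += g * np.where(self.data > 0, 1.0, out_data + alpha)

        return self._child(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out_data**2)

        return self._child(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            if self.requires_grad:
                self.grad += g * out_data * (1.0 - out_data)

        return self._child(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, shape)

        return self._child(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.grad += g[tuple(idx)]

    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; ties route the gradient to the first argument."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    take_a = a.data >= b.data

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * take_a, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * ~take_a, b.data.shape)

    return a._child(np.where(take_a, a.data, b.data), (a, b), backward)


def embedding_lookup(table: Tensor, indices: np.ndarray) -> Tensor:
    indices = np.asarray(indices)

    def backward(g):
        if table.requires_grad:
            np.add.at(table.grad, indices, g)

    return table._child(table.data[indices], (table,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """'Same'-padded 1-D convolution along the time axis.

    x: (batch, length, c_in); weight: (kernel, c_in, c_out); bias: (c_out,).
    Output: (batch, length, c_out).
    """
    k = weight.data.shape[0]
    left = (k - 1) // 2
    right = k - 1 - left
    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    # patches: (batch, length, c_in, kernel)
    patches = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    out_data = np.tensordot(patches, weight.data, axes=([3, 2], [0, 1])) + bias.data
    length = x.data.shape[1]

    def backward(g):
        if bias.requires_grad:
            bias.grad += g.sum(axis=(0, 1))
        if weight.requires_grad:
            # (c_in, kernel, c_out) -> (kernel, c_in, c_out)
            gw = np.tensordot(patches, g, axes=([0, 1], [0, 1]))
            weight.grad += np.transpose(gw, (1, 0, 2))
        if x.requires_grad:
            gx_patch = np.tensordot(g, weight.data, axes=([2], [2]))  # (B, L, k, c_in)
            gxp = np.zeros_like(xp)
            for i in range(k):
                gxp[:, i : i + length, :] += gx_patch[:, :, i, :]
            x.grad += gxp[:, left : left + length, :]

    return x._child(out_data, (x, weight, bias), backward)


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling along the time axis (trailing remainder dropped)."""
    b, length, c = x.data.shape
    n_win = length // pool
    if n_win == 0:
        raise ValueError(f"sequence length {length} shorter than pool size {pool}")
    xr = x.data[:, : n_win * pool, :].reshape(b, n_win, pool, c)
    arg = xr.argmax(axis=2)
    out_data = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        if not x.requires_grad:
            return
        gxr = np.zeros_like(xr)
        np.put_along_axis(gxr, arg[:, :, None, :], g[:, :, None, :], axis=2)
        x.grad[:, : n_win * pool, :] += gxr.reshape(b, n_win * pool, c)

    return x._child(out_data, (x,), backward)


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax(logits)."""
    labels = np.asarray(labels)
    logp = _log_softmax(logits.data)
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            grad = np.exp(logp)
            grad[np.arange(n), labels] -= 1.0
            logits.grad += g * grad / n

    return logits._child(np.asarray(loss), (logits,), backward)


def sigmoid_binary_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean per-element binary cross-entropy under sigmoid(logits)."""
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    # log(1+exp(-|z|)) + max(z,0) - z*t, numerically stable
    loss = (np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * t).mean()
    p = 0.5 * (1.0 + np.tanh(0.5 * z))
    n = z.size

    def backward(g):
        if logits.requires_grad:
            logits.grad += g * (p - t) / n

    return logits._child(np.asarray(loss), (logits,), backward)
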
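"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the message-passing layers and the
classification head need: einsum, broadcast add/multiply, concatenation,
axis permutation, reshape, reductions, the activations (sigmoid, softplus,
ReLU, PReLU), a batched row-gather, and a numerically stable
binary-crossentropy-with-logits. Gradients accumulate into ``Tensor.grad``
after :func:`backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "sub",
    "mul",
    "einsum",
    "concat",
    "transpose",
    "reshape",
    "reduce_sum",
    "sigmoid",
    "softplus",
    "relu",
    "prelu",
    "gather_rows",
    "bce_with_logits",
    "backward",
]


class Tensor:
    """A node in the computation graph: a value, its parents, and a backward rule."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g


def constant(value) -> Tensor:
    return Tensor(value)


def parameter(value) -> Tensor:
    return Tensor(value, requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value + b.value, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.value.shape))

    out._backward = bw
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value - b.value, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g, b.value.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value * b.value, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.value, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.value, b.value.shape))

    out._backward = bw
    return out


def einsum(spec: str, *operands: Tensor) -> Tensor:
    """Differentiable einsum. Each index of every operand must also appear in
    the output spec or in another operand (true for all contractions used here)."""
    in_specs, out_spec = spec.replace(" ", "").split("->")
    in_specs = in_specs.split(",")
    if len(in_specs) != len(operands):
        raise ValueError("einsum spec/operand count mismatch")
    out = Tensor(np.einsum(spec, *[op.value for op in operands], optimize=True), operands)

    def bw(g):
        for k, op in enumerate(operands):
            if not op.requires_grad:
                continue
            others = [(in_specs[j], operands[j].value) for j in range(len(operands)) if j != k]
            specs = [out_spec] + [s for s, _ in others]
            vals = [g] + [v for _, v in others]
            back_spec = ",".join(specs) + "->" + in_specs[k]
            op.accumulate(np.einsum(back_spec, *vals, optimize=True))

    out._backward = bw
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), tensors)
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t.accumulate(piece)

    out._backward = bw
    return out


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    out = Tensor(np.transpose(a.value, axes), (a,))
    inv = tuple(np.argsort(axes))

    def bw(g):
        if a.requires_grad:
            a.accumulate(np.transpose(g, inv))

    out._backward = bw
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.value.reshape(shape), (a,))

    def bw(g):
        if a.requires_grad:
            a.accumulate(g.reshape(a.value.shape))

    out._backward = bw
    return out


def reduce_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.value.sum(axis=axis, keepdims=keepdims), (a,))

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.value.shape).copy())
            return
        axes = (axis,) if np.isscalar(axis) else tuple(axis)
        if not keepdims:
            g = np.expand_dims(g, tuple(ax % a.value.ndim for ax in axes))
        a.accumulate(np.broadcast_to(g, a.value.shape).copy())

    out._backward = bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = np.empty_like(a.value)
    pos = a.value >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-a.value[pos]))
    ez = np.exp(a.value[~pos])
    s[~pos] = ez / (1.0 + ez)
    out = Tensor(s, (a,))

    def bw(g):
        if a.requires_grad:
            a.accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def softplus(a: Tensor) -> Tensor:
    out = Tensor(np.logaddexp(0.0, a.value), (a,))

    def bw(g):
        if a.requires_grad:
            a.accumulate(g / (1.0 + np.exp(-a.value)))

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.value, 0.0), (a,))

    def bw(g):
        if a.requires_grad:
            a.accumulate(g * (a.value > 0))

    out._backward = bw
    return out


def prelu(a: Tensor, slope: Tensor) -> Tensor:
    """PReLU with a per-channel slope broadcast on the last axis."""
    neg = a.value < 0
    out = Tensor(np.where(neg, slope.value * a.value, a.value), (a, slope))

    def bw(g):
        if a.requires_grad:
            a.accumulate(g * np.where(neg, slope.value, 1.0))
        if slope.requires_grad:
            contrib = g * np.where(neg, a.value, 0.0)
            slope.accumulate(_unbroadcast(contrib, slope.value.shape))

    out._backward = bw
    return out


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """out[b] = a[b, idx[b]] for a batched [B, N, ...] tensor."""
    idx = np.asarray(idx)
    batch = np.arange(a.value.shape[0])
    out = Tensor(a.value[batch, idx], (a,))

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.value)
            np.add.at(full, (batch, idx), g)
            a.accumulate(full)

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary crossentropy of sigmoid(logits) against {0,1} targets,
    computed in the numerically stable softplus form."""
    y = np.asarray(targets, dtype=np.float64)
    z = logits.value
    loss = np.logaddexp(0.0, z) - y * z
    out = Tensor(loss.mean(), (logits,))

    def bw(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits.accumulate(g * (p - y) / y.size)

    out._backward = bw
    return out


def backward(root: Tensor) -> None:
    """Run reverse-mode accumulation from a scalar root."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    root.grad = np.ones_like(root.value)
    for node in reversed(order):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
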
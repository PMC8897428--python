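"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for a small transformer encoder–decoder: a
:class:`Tensor` wrapping an ndarray with a gradient slot, primitive ops
(broadcasting add/mul, batched matmul, reshape/transpose, relu, dropout),
fused numerically-stable ops (layer norm, masked softmax, token
cross-entropy), an embedding gather, and an Adam optimizer.  Gradients are
accumulated by a topological-order sweep over the recorded graph.

All ops are gradient-checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "add",
    "mul",
    "scale",
    "matmul",
    "reshape",
    "transpose",
    "relu",
    "dropout",
    "layer_norm",
    "softmax",
    "embedding",
    "cross_entropy",
    "Adam",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable ``requires_grad`` tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def _needs_graph(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (the reverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitives

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    if not _needs_graph(a, b):
        return Tensor(out_data)
    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    if not _needs_graph(a, b):
        return Tensor(out_data)
    return Tensor(out_data, parents=(a, b), backward=backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        return (g * s,)

    if not _needs_graph(a):
        return Tensor(a.data * s)
    return Tensor(a.data * s, parents=(a,), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    if not _needs_graph(a, b):
        return Tensor(out_data)
    return Tensor(out_data, parents=(a, b), backward=backward)


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        return (g.reshape(a.shape),)

    if not _needs_graph(a):
        return Tensor(a.data.reshape(shape))
    return Tensor(a.data.reshape(shape), parents=(a,), backward=backward)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        return (np.transpose(g, inv),)

    if not _needs_graph(a):
        return Tensor(np.transpose(a.data, axes))
    return Tensor(np.transpose(a.data, axes), parents=(a,), backward=backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        return (g * mask,)

    if not _needs_graph(a):
        return Tensor(a.data * mask)
    return Tensor(a.data * mask, parents=(a,), backward=backward)


def dropout(a: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when ``p == 0`` or not training."""
    if not train or p <= 0.0:
        return a
    keep = (rng.random(a.shape) >= p) / (1.0 - p)

    def backward(g):
        return (g * keep,)

    if not _needs_graph(a):
        return Tensor(a.data * keep)
    return Tensor(a.data * keep, parents=(a,), backward=backward)


# ---------------------------------------------------------------------------
# fused ops

def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gain.data + bias.data
    n = x.data.shape[-1]

    def backward(g):
        g_gain = _unbroadcast(g * xhat, gain.shape)
        g_bias = _unbroadcast(g, bias.shape)
        gx_hat = g * gain.data
        gx = inv * (
            gx_hat
            - gx_hat.mean(axis=-1, keepdims=True)
            - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
        )
        return gx, g_gain, g_bias

    if not _needs_graph(x, gain, bias):
        return Tensor(out_data)
    return Tensor(out_data, parents=(x, gain, bias), backward=backward)


def softmax(x: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis, optionally after adding a mask of -inf/0."""
    z = x.data if additive_mask is None else x.data + additive_mask
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        return (p * (g - (g * p).sum(axis=-1, keepdims=True)),)

    if not _needs_graph(x):
        return Tensor(p)
    return Tensor(p, parents=(x,), backward=backward)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``table[ids]``; backward scatter-adds into the table."""
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def backward(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        return (gt,)

    if not _needs_graph(table):
        return Tensor(out_data)
    return Tensor(out_data, parents=(table,), backward=backward)


def cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over positions where ``mask`` is true.

    ``logits`` has shape (..., V); ``targets`` holds class ids with the
    leading shape; masked-out positions contribute nothing.
    """
    targets = np.asarray(targets)
    mask = np.asarray(mask, dtype=bool)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    picked = np.take_along_axis(z, targets[..., None], axis=-1)[..., 0]
    nll = (logsumexp - picked) * mask
    count = max(int(mask.sum()), 1)
    out_data = nll.sum() / count

    def backward(g):
        grad = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
        # subtract the one-hot target
        idx = np.meshgrid(*[np.arange(s) for s in targets.shape], indexing="ij")
        grad[(*idx, targets)] -= 1.0
        grad *= (mask / count)[..., None] * g
        return (grad,)

    if not _needs_graph(logits):
        return Tensor(out_data)
    return Tensor(np.asarray(out_data), parents=(logits,), backward=backward)


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with optional gradient clipping by global norm."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = 1.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / total) for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
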
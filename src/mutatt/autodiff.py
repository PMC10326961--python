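"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations needed by the attention classifier are provided. A
:class:`Tape` records operations in execution order; calling
:meth:`Tape.backward` replays them in reverse, accumulating gradients into
``Node.grad``. All arrays are float64 so that numeric gradient checks are
meaningful.
"""

from __future__ import annotations

import math

import numpy as np

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


class Node:
    __slots__ = ("data", "grad")

    def __init__(self, data):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None

    def add_grad(self, g) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over broadcast axes back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tape:
    """Operation tape; one per forward pass."""

    def __init__(self) -> None:
        self._ops: list[tuple[Node, callable]] = []

    def node(self, data) -> Node:
        return Node(data)

    def _emit(self, data, backward) -> Node:
        out = Node(data)
        self._ops.append((out, backward))
        return out

    def backward(self, loss: Node) -> None:
        loss.grad = np.ones_like(loss.data)
        for out, bwd in reversed(self._ops):
            if out.grad is not None:
                bwd(out.grad)

    # -- primitive ops ----------------------------------------------------

    def matmul(self, a: Node, b: Node) -> Node:
        def bwd(g):
            a.add_grad(g @ b.data.T)
            b.add_grad(a.data.T @ g)

        return self._emit(a.data @ b.data, bwd)

    def add(self, a: Node, b: Node) -> Node:
        def bwd(g):
            a.add_grad(_unbroadcast(g, a.data.shape))
            b.add_grad(_unbroadcast(g, b.data.shape))

        return self._emit(a.data + b.data, bwd)

    def scale(self, a: Node, c: float) -> Node:
        return self._emit(a.data * c, lambda g: a.add_grad(g * c))

    def transpose(self, a: Node) -> Node:
        return self._emit(a.data.T, lambda g: a.add_grad(g.T))

    def gather(self, table: Node, idx: np.ndarray) -> Node:
        """Row lookup (embedding); gradient scatter-adds into the table."""

        def bwd(g):
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            np.add.at(table.grad, idx, g)

        return self._emit(table.data[idx], bwd)

    def concat(self, nodes: list[Node]) -> Node:
        """Concatenate along the last axis."""
        widths = [n.data.shape[-1] for n in nodes]
        offsets = np.cumsum([0] + widths)

        def bwd(g):
            for n, lo, hi in zip(nodes, offsets[:-1], offsets[1:]):
                n.add_grad(g[..., lo:hi])

        return self._emit(np.concatenate([n.data for n in nodes], axis=-1), bwd)

    def slice_last(self, a: Node, lo: int, hi: int) -> Node:
        def bwd(g):
            full = np.zeros_like(a.data)
            full[..., lo:hi] = g
            a.add_grad(full)

        return self._emit(a.data[..., lo:hi], bwd)

    def gelu(self, a: Node) -> Node:
        """GELU with the tanh approximation (smooth, exactly differentiable)."""
        x = a.data
        inner = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
        t = np.tanh(inner)

        def bwd(g):
            d_inner = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x**2)
            a.add_grad(g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * d_inner))

        return self._emit(0.5 * x * (1.0 + t), bwd)

    def softmax_last(self, a: Node) -> Node:
        """Numerically stabilized softmax over the last axis."""
        z = a.data - a.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)

        def bwd(g):
            a.add_grad(p * (g - (g * p).sum(axis=-1, keepdims=True)))

        return self._emit(p, bwd)

    def layer_norm(self, a: Node, gain: Node, bias: Node, eps: float = 1e-5) -> Node:
        x = a.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv

        def bwd(g):
            gd = g * gain.data
            a.add_grad(
                inv * (gd - gd.mean(axis=-1, keepdims=True)
                       - xhat * (gd * xhat).mean(axis=-1, keepdims=True))
            )
            gain.add_grad(_unbroadcast(g * xhat, gain.data.shape))
            bias.add_grad(_unbroadcast(g, bias.data.shape))

        return self._emit(xhat * gain.data + bias.data, bwd)

    def mean_rows(self, a: Node) -> Node:
        """Mean over axis 0: (l, d) -> (1, d)."""
        l = a.data.shape[0]

        def bwd(g):
            a.add_grad(np.broadcast_to(g / l, a.data.shape).copy())

        return self._emit(a.data.mean(axis=0, keepdims=True), bwd)

    def cross_entropy_logits(self, logits: Node, label: int, eps: float = 1e-12):
        """Cross-entropy of one-hot ``label`` against softmax(logits).

        ``logits`` has shape (1, C). Returns (loss node, probabilities).
        The correct-class probability is clamped at ``eps``.
        """
        z = logits.data.ravel()
        z = z - z.max()
        e = np.exp(z)
        p = e / e.sum()

        def bwd(g):
            d = p.copy()
            d[label] -= 1.0
            logits.add_grad(g * d.reshape(logits.data.shape))

        loss = self._emit(-np.log(max(p[label], eps)), bwd)
        return loss, p
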
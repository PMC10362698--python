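"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the model in this package: broadcasting
arithmetic, matmul, elementwise nonlinearities, reductions, a causal
dilated 1-D convolution primitive, a fused categorical log-likelihood,
and an Adam optimizer.  Everything is float64 and single-threaded
deterministic.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = parents

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- elementwise ---------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        out._backward = bwd
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            self._accumulate(g * (1.0 - y**2))

        out._backward = bwd
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            self._accumulate(g * y)

        out._backward = bwd
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            self._accumulate(g * 0.5 / y)

        out._backward = bwd
        return out

    # -- reductions & shaping -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            self._accumulate(g.reshape(self.shape))

        out._backward = bwd
        return out


def causal_conv1d(x: Tensor, weight: Tensor, bias: Tensor, dilation: int) -> Tensor:
    """Left-padded dilated convolution along the last axis.

    ``x`` is (B, Cin, L), ``weight`` is (Cout, Cin, k), ``bias`` (Cout,).
    Output (B, Cout, L); output position t depends only on inputs at
    positions <= t (left padding of (k-1)*dilation zeros).
    """
    if dilation < 1:
        raise ValueError("dilation must be a positive integer")
    k = weight.data.shape[2]
    if k < 1:
        raise ValueError("kernel size must be a positive integer")
    batch, _, length = x.data.shape
    pad = (k - 1) * dilation
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, 0)))
    y = np.broadcast_to(bias.data[None, :, None], (batch, weight.data.shape[0], length)).copy()
    for i in range(k):
        y += np.einsum("oc,bcl->bol", weight.data[:, :, i], xp[:, :, i * dilation : i * dilation + length])
    out = Tensor(y, parents=(x, weight, bias))

    def bwd(g):
        if bias.requires_grad or bias._parents:
            bias._accumulate(g.sum(axis=(0, 2)))
        gxp = np.zeros_like(xp)
        for i in range(k):
            sl = slice(i * dilation, i * dilation + length)
            if weight.requires_grad or weight._parents:
                weight._accumulate_tap(i, np.einsum("bol,bcl->oc", g, xp[:, :, sl]))
            gxp[:, :, sl] += np.einsum("oc,bol->bcl", weight.data[:, :, i], g)
        if x.requires_grad or x._parents:
            x._accumulate(gxp[:, :, pad:])

    out._backward = bwd
    return out


def _accumulate_tap(self: Tensor, tap: int, grad: np.ndarray) -> None:
    if self.grad is None:
        self.grad = np.zeros_like(self.data)
    self.grad[:, :, tap] += grad


Tensor._accumulate_tap = _accumulate_tap  # type: ignore[attr-defined]


def categorical_logprob(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Sum over positions of log softmax(logits) at the observed symbols.

    ``logits`` is (B, L, A), ``targets`` integer (B, L); returns (B,).
    """
    z = logits.data
    zmax = z.max(axis=2, keepdims=True)
    logz = zmax + np.log(np.exp(z - zmax).sum(axis=2, keepdims=True))
    logp = z - logz  # (B, L, A)
    batch, length = targets.shape
    bi = np.arange(batch)[:, None]
    li = np.arange(length)[None, :]
    out = Tensor(logp[bi, li, targets].sum(axis=1), parents=(logits,))
    softmax = np.exp(logp)

    def bwd(g):
        grad = -softmax * g[:, None, None]
        grad[bi, li, targets] += g[:, None]
        logits._accumulate(grad)

    out._backward = bwd
    return out


class Parameter(Tensor):
    """A leaf tensor that Adam updates."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
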
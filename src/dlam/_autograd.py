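"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core behind the network modules: a tape-based
``Tensor`` supporting the handful of operations the architecture needs
(broadcast arithmetic, matmul, 1D convolution and pooling, the activation
functions, axis reductions, concatenation). Gradients are accumulated by a
topological backward sweep. Every op's backward is verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Tensor", "Parameter", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- reductions / shaping -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose_2d(self):
        out = Tensor(self.data.T, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        out._backward = backward
        return out

    def max_reduce(self, axis: int, keepdims: bool = True):
        """Maximum along one axis; gradient routed to (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _prev=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), gg, axis)
            self._accum(gx)

        out._backward = backward
        return out

    # -- activations ---------------------------------------------------------
    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(np.where(mask, g, slope * g))

        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(np.where(mask, g, 0.0))

        out._backward = backward
        return out

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(s, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = backward
        return out

    def satlin(self):
        """Saturating linear: 0 below 0, identity on [0,1], 1 above 1."""
        out = Tensor(np.clip(self.data, 0.0, 1.0), _prev=(self,))
        mask = (self.data >= 0.0) & (self.data <= 1.0)

        def backward(g):
            if self.requires_grad:
                self._accum(np.where(mask, g, 0.0))

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = backward
        return out

    # -- convolution / pooling ----------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """Cross-correlation of a (B, Cin, L) batch with (Cout, Cin, K) kernels."""
        weight = Tensor._lift(weight)
        x = self.data
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        B, C, L = x.shape
        Cout, Cin, K = weight.data.shape
        if Cin != C:
            raise ValueError(f"conv1d channel mismatch: input {C}, weight {Cin}")
        Lout = (L - K) // stride + 1
        if Lout < 1:
            raise ValueError(f"conv1d: input length {L} too short for kernel {K}")
        s0, s1, s2 = x.strides
        cols = as_strided(x, (B, C, Lout, K), (s0, s1, s2 * stride, s2))
        out_data = np.einsum("bclk,ock->bol", cols, weight.data, optimize=True)
        prev = (self, weight) + ((bias,) if bias is not None else ())
        if bias is not None:
            out_data = out_data + bias.data[None, :, None]
        out = Tensor(out_data, _prev=prev)

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if weight.requires_grad:
                weight._accum(np.einsum("bol,bclk->ock", g, cols, optimize=True))
            if self.requires_grad:
                gcols = np.einsum("bol,ock->bclk", g, weight.data, optimize=True)
                gx = np.zeros((B, C, L))
                for k in range(K):
                    gx[:, :, k : k + stride * Lout : stride] += gcols[:, :, :, k]
                if padding:
                    gx = gx[:, :, padding:-padding]
                self._accum(gx)

        out._backward = backward
        return out

    def maxpool1d(self, kernel: int, stride: int) -> "Tensor":
        x = self.data
        B, C, L = x.shape
        Lout = (L - kernel) // stride + 1
        if Lout < 1:
            raise ValueError(f"maxpool1d: input length {L} too short for kernel {kernel}")
        s0, s1, s2 = x.strides
        win = as_strided(x, (B, C, Lout, kernel), (s0, s1, s2 * stride, s2))
        idx = win.argmax(axis=3)
        out = Tensor(win.max(axis=3), _prev=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(x)
            b, c, l = np.meshgrid(
                np.arange(B), np.arange(C), np.arange(Lout), indexing="ij"
            )
            np.add.at(gx, (b, c, l * stride + idx), g)
            self._accum(gx)

        out._backward = backward
        return out

    # -- backward sweep -------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    order.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a flat list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
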
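"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a volumetric vision transformer: broadcasting
elementwise arithmetic, matmul, reshape/transpose, softmax, layer norm,
GELU, sigmoid and nearest-neighbour upsampling. Gradients accumulate on
leaf tensors marked ``requires_grad``; ``backward`` walks the tape in
reverse topological order. Single-threaded numpy keeps every run bitwise
reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

# float32 keeps training memory-bandwidth bound ops ~2x faster; tests that
# need tighter arithmetic (finite-difference gradient checks) switch to
# float64 via set_dtype.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = dtype


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_aliased")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self._grad_aliased = False

    @property
    def shape(self):
        return self.value.shape

    # -- graph walk ---------------------------------------------------------

    def backward(self, seed: np.ndarray) -> None:
        """Accumulate gradients given d(loss)/d(self) = ``seed``."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, False)]
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

        visit(self)
        self.grad = np.asarray(seed, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        # First contribution keeps a reference (which may alias the producer's
        # buffer); the reverse topological order guarantees that buffer is no
        # longer written to, and a second contribution allocates fresh storage
        # instead of mutating the alias.
        if self.grad is None:
            self.grad = g
            self._grad_aliased = True
        elif self._grad_aliased:
            self.grad = self.grad + g
            self._grad_aliased = False
        else:
            self.grad += g

    # -- ops ---------------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(a.value + b.value, parents=(a, b), backward=bwd)

    def __mul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.value, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.value, b.shape))

        return Tensor(a.value * b.value, parents=(a, b), backward=bwd)

    def scale(self, c: float) -> "Tensor":
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g * c)

        return Tensor(a.value * c, parents=(a,), backward=bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.value, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.value, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor(a.value @ b.value, parents=(a, b), backward=bwd)

    def reshape(self, *shape) -> "Tensor":
        a = self
        old = a.shape

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor(a.value.reshape(*shape), parents=(a,), backward=bwd)

    def transpose(self, axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            if a.requires_grad:
                a._accum(np.transpose(g, inv))

        return Tensor(np.transpose(a.value, axes), parents=(a,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        a = self
        out = 1.0 / (1.0 + np.exp(-a.value))

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out * (1.0 - out))

        return Tensor(out, parents=(a,), backward=bwd)

    def gelu(self) -> "Tensor":
        """tanh approximation of GELU."""
        a = self
        c = np.sqrt(2.0 / np.pi)
        x = a.value
        inner = c * (x + 0.044715 * x**3)
        th = np.tanh(inner)
        out = 0.5 * x * (1.0 + th)

        def bwd(g):
            if a.requires_grad:
                sech2 = 1.0 - th * th
                d = 0.5 * (1.0 + th) + 0.5 * x * sech2 * c * (1.0 + 3 * 0.044715 * x**2)
                a._accum(g * d)

        return Tensor(out, parents=(a,), backward=bwd)

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        a = self
        x = a.value
        m = x.max(axis=-1, keepdims=True)
        e = np.exp(x - m)
        out = e / e.sum(axis=-1, keepdims=True)

        def bwd(g):
            if a.requires_grad:
                dot = (g * out).sum(axis=-1, keepdims=True)
                a._accum(out * (g - dot))

        return Tensor(out, parents=(a,), backward=bwd)

    def layernorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Layer normalization over the last axis with learnable scale/shift."""
        a = self
        x = a.value
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = xhat * gamma.value + beta.value

        def bwd(g):
            n = x.shape[-1]
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.shape))
            if a.requires_grad:
                gx = g * gamma.value
                t1 = gx * inv
                t2 = inv / n * gx.sum(axis=-1, keepdims=True)
                t3 = xhat * inv / n * (gx * xhat).sum(axis=-1, keepdims=True)
                a._accum(t1 - t2 - t3)

        return Tensor(out, parents=(a, gamma, beta), backward=bwd)

    def crop(self, slices: tuple[slice, ...]) -> "Tensor":
        a = self
        full = a.shape

        def bwd(g):
            if a.requires_grad:
                buf = np.zeros(full, dtype=DTYPE)
                buf[slices] = g
                a._accum(buf)

        return Tensor(a.value[slices], parents=(a,), backward=bwd)

    def upsample_nearest(self, spatial_axes: tuple[int, ...]) -> "Tensor":
        """Repeat each listed axis twice (nearest-neighbour x2 upsampling)."""
        a = self
        out = a.value
        for ax in spatial_axes:
            out = np.repeat(out, 2, axis=ax)

        def bwd(g):
            if a.requires_grad:
                for ax in spatial_axes:
                    n = g.shape[ax] // 2
                    shp = list(g.shape)
                    shp[ax : ax + 1] = [n, 2]
                    g = g.reshape(shp).sum(axis=ax + 1)
                a._accum(g)

        return Tensor(out, parents=(a,), backward=bwd)


def param(rng: np.random.Generator, shape, scale: float | None = None) -> Tensor:
    """Seeded Gaussian-initialized trainable parameter (fan-in scaling)."""
    if scale is None:
        fan_in = shape[-2] if len(shape) >= 2 else shape[-1]
        scale = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def zeros_param(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def ones_param(shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


class Adam:
    """Standard Adam optimizer over a list of :class:`Tensor` parameters."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

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
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
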
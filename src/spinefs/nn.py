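"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a deliberately small, dependency-light tape: enough primitives for a
convolutional encoder-decoder generator, a strided patch discriminator, and a
windowed SSIM + binary-cross-entropy loss, all exactly differentiable. The
engine is single-threaded numpy, so a fixed seed reproduces training
bit-exactly.

Conventions: image tensors are (N, C, H, W); convolution weights are
(C_out, C_in, kH, kW); gradients accumulate into ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Adam", "conv2d", "leaky_relu", "relu", "tanh", "sigmoid",
    "softplus", "log", "exp", "dropout", "upsample2x", "concat_channels",
    "mean_all", "sum_all",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self._parents)

    # -- graph machinery ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape, seeded with ones) node.

        Iterative topological sort: recursion would both hit Python's depth
        limit on deep graphs and, as a self-referencing closure, keep the
        whole graph alive until the cyclic garbage collector runs.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            t, children_done = stack.pop()
            if children_done:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g / other.data, self.data.shape))
            _accum(other, _unbroadcast(-g * self.data / other.data ** 2,
                                       other.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other, self.data.dtype) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, (self,))
        out._backward = lambda g: _accum(
            self, g * exponent * self.data ** (exponent - 1))
        return out


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), (x,))
    out._backward = lambda g: _accum(x, g / x.data)
    return out


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    out = Tensor(y, (x,))
    # closure captures the output array, never the output Tensor: a backward
    # closure referencing its own node would make every graph a GC cycle
    out._backward = lambda g: _accum(x, g * y)
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: _accum(x, g * (1.0 - y ** 2))
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = _sigmoid(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: _accum(x, g * y * (1.0 - y))
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    pos = z >= 0
    out = np.empty_like(z)
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(x: Tensor) -> Tensor:
    """Numerically stable log(1 + exp(x)); gradient is sigmoid(x)."""
    z = x.data
    out = Tensor(np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z))), (x,))
    out._backward = lambda g: _accum(x, g * _sigmoid(z))
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), (x,))
    out._backward = lambda g: _accum(x, g * (x.data > 0))
    return out


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    slope = np.where(x.data > 0, x.data.dtype.type(1.0), x.data.dtype.type(alpha))
    out = Tensor(x.data * slope, (x,))
    out._backward = lambda g: _accum(x, g * slope)
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    out = Tensor(x.data * keep, (x,))
    out._backward = lambda g: _accum(x, g * keep)
    return out


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def sum_all(x: Tensor) -> Tensor:
    out = Tensor(np.asarray(x.data.sum(), dtype=x.data.dtype), (x,))
    out._backward = lambda g: _accum(x, np.broadcast_to(g, x.data.shape).copy())
    return out


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size
    out = Tensor(np.asarray(x.data.mean(), dtype=x.data.dtype), (x,))
    out._backward = lambda g: _accum(
        x, np.broadcast_to(g / n, x.data.shape).astype(x.data.dtype))
    return out


def concat_channels(tensors: list[Tensor]) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=1)
    out = Tensor(data, tuple(tensors))

    def bw(g):
        start = 0
        for t in tensors:
            c = t.data.shape[1]
            _accum(t, g[:, start:start + c])
            start += c
    out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (N, C, H, W)."""
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(data, (x,))

    def bw(g):
        n, c, h2, w2 = g.shape
        _accum(x, g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation with zero padding.

    Implemented as one BLAS contraction per kernel offset (kh*kw GEMMs over
    strided views), which avoids materializing im2col patch matrices.
    """
    kh, kw = w.data.shape[2], w.data.shape[3]
    xd = x.data
    if padding > 0:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n, _, h, wdt = xd.shape
    ho = (h - kh) // stride + 1
    wo = (wdt - kw) // stride + 1

    def shifted(i: int, j: int) -> np.ndarray:
        return xd[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]

    y = None
    for i in range(kh):
        for j in range(kw):
            r = np.tensordot(shifted(i, j), w.data[:, :, i, j],
                             axes=([1], [1]))           # (N, Ho, Wo, O)
            y = r if y is None else y + r
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))   # (N, O, Ho, Wo)
    if b is not None:
        y += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents)

    def bw(g):
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        dw = np.zeros_like(w.data) if w.requires_grad else None
        dxp = np.zeros_like(xd) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                if dw is not None:
                    dw[:, :, i, j] = np.tensordot(g, shifted(i, j),
                                                  axes=([0, 2, 3], [0, 2, 3]))
                if dxp is not None:
                    r = np.tensordot(g, w.data[:, :, i, j],
                                     axes=([1], [0]))   # (N, Ho, Wo, C)
                    dxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += r.transpose(0, 3, 1, 2)
        if dw is not None:
            _accum(w, dw)
        if dxp is not None:
            if padding > 0:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            _accum(x, dxp)
    out._backward = bw
    return out


def box_mean(x: Tensor, win: int) -> Tensor:
    """Valid-window uniform (box) filter over the trailing two axes.

    Equivalent to ``conv2d`` with a ``win x win`` kernel of ``1/win**2`` but
    computed via integral images in O(H*W); used by the windowed SSIM loss.
    """
    out = Tensor(_box_mean_raw(x.data, win), (x,))

    def bw(g):
        p = win - 1
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
        _accum(x, _box_mean_raw(gp, win))
    out._backward = bw
    return out


def _box_mean_raw(x: np.ndarray, win: int) -> np.ndarray:
    s = x.astype(np.float64).cumsum(axis=-2).cumsum(axis=-1)
    s = np.pad(s, ((0, 0), (0, 0), (1, 0), (1, 0)))
    total = (s[..., win:, win:] - s[..., :-win, win:]
             - s[..., win:, :-win] + s[..., :-win, :-win])
    return (total / (win * win)).astype(x.dtype)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled per-parameter state; betas default to the
    conditional-GAN convention (0.5, 0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
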
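"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operator set the denoising U-Net needs:
3x3 and 1x1 convolutions, group normalization, SiLU, softmax / batched
matmul (for attention), average pooling, nearest-neighbour upsampling,
pixel shuffle, concatenation and broadcast addition.  Feature maps use the
NHWC memory layout internally, which keeps the convolution inner loops
contiguous; the public network API converts from the package-wide
channel-first convention at its boundary.

Gradients are accumulated on a dynamically built tape (`Tensor._parents` /
`Tensor._backward`), released after `backward()`.  Inference runs under
`no_grad()`, in which case no tape is built and operations may work
in place on scratch buffers.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True

# batch chunk used by the 3x3 convolution so that shifted slices stay
# cache resident; purely a speed knob, never changes results
_CONV_CHUNK = 32


@contextmanager
def no_grad():
    """Disable tape construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """Array node of the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        """Reverse sweep from this node; accumulates into `.grad` leaves."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
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
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            node._backward = None  # free closure memory eagerly

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(data, parents, backward):
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _sum_to_shape(g, shape):
    """Reduce a broadcast gradient back to `shape`."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------- basic ops

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def back(g):
        return _sum_to_shape(g, a.shape), _sum_to_shape(g, b.shape)

    return _wrap(out, (a, b), back)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.data - b.data

    def back(g):
        return _sum_to_shape(g, a.shape), -_sum_to_shape(g, b.shape)

    return _wrap(out, (a, b), back)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def back(g):
        return (_sum_to_shape(g * b.data, a.shape),
                _sum_to_shape(g * a.data, b.shape))

    return _wrap(out, (a, b), back)


def scale(a: Tensor, s: float) -> Tensor:
    s = float(s)
    return _wrap(a.data * s, (a,), lambda g: (g * s,))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    return _wrap(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    return _wrap(np.ascontiguousarray(a.data.transpose(axes)), (a,),
                 lambda g: (g.transpose(inv),))


def concat_last(a: Tensor, b: Tensor) -> Tensor:
    na = a.shape[-1]
    out = np.concatenate([a.data, b.data], axis=-1)

    def back(g):
        return g[..., :na], g[..., na:]

    return _wrap(out, (a, b), back)


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size

    def back(g):
        return (np.full(a.shape, g / n, dtype=np.float32),)

    return _wrap(np.float32(a.data.mean()), (a,), back)


def sum_sq(a: Tensor) -> Tensor:
    """Sum of squares, used by the training loss."""
    def back(g):
        return (g * 2.0 * a.data,)

    return _wrap(np.float32(np.square(a.data, dtype=np.float64).sum()), (a,), back)


# ------------------------------------------------------------- activations

def silu(a: Tensor) -> Tensor:
    # sigmoid via tanh: numerically stable and SIMD-friendly
    sig = np.tanh(a.data * np.float32(0.5))
    sig += np.float32(1.0)
    sig *= np.float32(0.5)
    out = a.data * sig

    def back(g):
        return (g * (sig * (1.0 + a.data * (1.0 - sig))),)

    return _wrap(out, (a,), back)


def softmax_last(a: Tensor) -> Tensor:
    x = a.data - a.data.max(axis=-1, keepdims=True)
    np.exp(x, out=x)
    y = x / x.sum(axis=-1, keepdims=True)

    def back(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        return (y * (g - dot),)

    return _wrap(y.astype(np.float32), (a,), back)


# ------------------------------------------------------------ linear algebra

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def back(g):
        return g @ b.data.T, a.data.T @ g

    return _wrap(out, (a, b), back)


def bmm(a: Tensor, b: Tensor) -> Tensor:
    """Batched matmul over leading axes (shapes must match, no broadcast)."""
    out = np.matmul(a.data, b.data)

    def back(g):
        return (np.matmul(g, np.swapaxes(b.data, -1, -2)),
                np.matmul(np.swapaxes(a.data, -1, -2), g))

    return _wrap(out, (a, b), back)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x @ w + b for 2-D x."""
    out = x.data @ w.data + b.data

    def back(g):
        return g @ w.data.T, x.data.T @ g, g.sum(axis=0)

    return _wrap(out, (x, w, b), back)


# -------------------------------------------------------------- convolution

def _conv3x3_forward(xp, w):
    """Shift-and-accumulate 3x3 convolution on padded NHWC input."""
    B, Hp, Wp, cin = xp.shape
    H, W = Hp - 2, Wp - 2
    cout = w.shape[3]
    out = np.empty((B, H, W, cout), dtype=np.float32)
    for s in range(0, B, _CONV_CHUNK):
        e = min(s + _CONV_CHUNK, B)
        acc = None
        for dy in range(3):
            for dx in range(3):
                sl = np.ascontiguousarray(
                    xp[s:e, dy:dy + H, dx:dx + W, :]).reshape(-1, cin)
                r = sl @ w[dy, dx]
                acc = r if acc is None else acc.__iadd__(r)
        out[s:e] = acc.reshape(e - s, H, W, cout)
    return out


def conv3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 3x3 convolution; x NHWC, w (3,3,Cin,Cout)."""
    B, H, W, cin = x.shape
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = _conv3x3_forward(xp, w.data)
    out += b.data

    def back(g):
        cout = w.shape[3]
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        gb = g.sum(axis=(0, 1, 2))
        for s in range(0, B, _CONV_CHUNK):
            e = min(s + _CONV_CHUNK, B)
            gflat = np.ascontiguousarray(g[s:e]).reshape(-1, cout)
            for dy in range(3):
                for dx in range(3):
                    sl = np.ascontiguousarray(
                        xp[s:e, dy:dy + H, dx:dx + W, :]).reshape(-1, cin)
                    gw[dy, dx] += sl.T @ gflat
                    gxp[s:e, dy:dy + H, dx:dx + W, :] += (
                        gflat @ w.data[dy, dx].T).reshape(e - s, H, W, cin)
        return gxp[:, 1:-1, 1:-1, :], gw, gb

    return _wrap(out, (x, w, b), back)


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Pointwise convolution; x NHWC, w (Cin, Cout)."""
    cin = x.shape[-1]
    out = x.data.reshape(-1, cin) @ w.data + b.data
    out = out.reshape(x.shape[:-1] + (w.shape[1],))

    def back(g):
        gf = g.reshape(-1, w.shape[1])
        return (
            (gf @ w.data.T).reshape(x.shape),
            x.data.reshape(-1, cin).T @ gf,
            gf.sum(axis=0),
        )

    return _wrap(out, (x, w, b), back)


# ------------------------------------------------------------ normalization

def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Per-sample group normalization over NHWC feature maps."""
    B, H, W, C = x.shape
    g_sz = C // groups
    n = H * W * g_sz
    xf = x.data.reshape(B, H * W, C)
    s1 = np.einsum("bsc->bc", xf).reshape(B, groups, g_sz).sum(axis=2)
    s2 = np.einsum("bsc,bsc->bc", xf, xf).reshape(
        B, groups, g_sz).sum(axis=2)
    mean = (s1 / n).astype(np.float64)
    var = s2.astype(np.float64) / n - mean**2
    inv = 1.0 / np.sqrt(var + eps)
    # fold normalization + affine into one fused pass: out = x*A + Bb
    inv_ch = np.repeat(inv, g_sz, axis=1).astype(np.float32)
    mean_ch = np.repeat(mean, g_sz, axis=1).astype(np.float32)
    a_ch = inv_ch * gamma.data
    b_ch = beta.data - mean_ch * a_ch
    out = xf * a_ch[:, None, :]
    out += b_ch[:, None, :]
    out = out.reshape(B, H, W, C)

    def back(g):
        gf = g.reshape(B, H * W, C)
        xhat = (xf - mean_ch[:, None, :]) * inv_ch[:, None, :]
        gr = gf * gamma.data
        m1 = np.einsum("bsc->bc", gr).reshape(
            B, groups, g_sz).sum(axis=2) / n
        m2 = np.einsum("bsc,bsc->bc", gr, xhat).reshape(
            B, groups, g_sz).sum(axis=2) / n
        gx = inv_ch[:, None, :] * (
            gr - np.repeat(m1, g_sz, 1).astype(np.float32)[:, None, :]
            - xhat * np.repeat(m2, g_sz, 1).astype(np.float32)[:, None, :])
        ggamma = np.einsum("bsc,bsc->c", gf, xhat)
        gbeta = np.einsum("bsc->c", gf)
        return gx.reshape(B, H, W, C), ggamma, gbeta

    return _wrap(out, (x, gamma, beta), back)


# ------------------------------------------------------------------ resizing

def avg_pool2(x: Tensor) -> Tensor:
    B, H, W, C = x.shape
    out = x.data.reshape(B, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))

    def back(g):
        gup = np.broadcast_to(
            (g * 0.25)[:, :, None, :, None, :], (B, H // 2, 2, W // 2, 2, C))
        return (gup.reshape(B, H, W, C),)

    return _wrap(out, (x,), back)


def upsample_nearest2(x: Tensor) -> Tensor:
    B, H, W, C = x.shape
    out = np.broadcast_to(
        x.data[:, :, None, :, None, :], (B, H, 2, W, 2, C))
    out = np.ascontiguousarray(out).reshape(B, 2 * H, 2 * W, C)

    def back(g):
        return (g.reshape(B, H, 2, W, 2, C).sum(axis=(2, 4)),)

    return _wrap(out, (x,), back)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """(B, H, W, C*r*r) -> (B, H*r, W*r, C); channel index viewed (C, r, r)."""
    if r == 1:
        return x
    B, H, W, crr = x.shape
    C = crr // (r * r)
    v = x.data.reshape(B, H, W, C, r, r)
    out = np.ascontiguousarray(v.transpose(0, 1, 4, 2, 5, 3))
    out = out.reshape(B, H * r, W * r, C)

    def back(g):
        gv = g.reshape(B, H, r, W, r, C).transpose(0, 1, 3, 5, 2, 4)
        return (np.ascontiguousarray(gv).reshape(B, H, W, crr),)

    return _wrap(out, (x,), back)


# ------------------------------------------------------------------ optimizer

class AdamW:
    """Decoupled weight-decay Adam over a name->Tensor parameter dict."""

    def __init__(self, params: dict, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.wd:
                p.data -= self.lr * self.wd * p.data

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def parameter(rng: np.random.Generator, shape, fan_in: int,
              zero: bool = False) -> Tensor:
    """He-style normal initialization (or zeros), seeded."""
    if zero:
        data = np.zeros(shape, dtype=np.float32)
    else:
        std = math.sqrt(2.0 / fan_in)
        data = rng.normal(0.0, std, size=shape).astype(np.float32)
    return Tensor(data, requires_grad=True)
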
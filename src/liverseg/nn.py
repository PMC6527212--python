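"""Minimal reverse-mode automatic differentiation over numpy for 2D
segmentation networks.

Provides exactly the primitives the encoder--decoder architecture needs:
valid-mode 2D convolution (stride 1 or 2), 2x2 stride-2 transposed
convolution, batch normalization, ReLU, inverted dropout, channel
concatenation, center cropping, and scalar arithmetic for composing the
soft-Dice objective, plus an Adam optimizer. Arrays are NCHW float64.

Gradients of every fused primitive are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """Array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "_parents", "_bw", "requires_grad")

    def __init__(self, data, parents=(), bw=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._bw = bw
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bw(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                g = _unbroadcast(g, parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- composable scalar/elementwise arithmetic ------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data + other.data, (self, other), lambda g: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data * other.data, (self, other),
                      lambda g: (g * other.data, g * self.data))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data / other.data, (self, other),
                      lambda g: (g / other.data,
                                 -g * self.data / (other.data ** 2)))

    def sum(self):
        return Tensor(self.data.sum(), (self,),
                      lambda g: (np.broadcast_to(g, self.data.shape),))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(grad, shape):
    if grad.shape == shape:
        return grad
    g = grad.sum(axis=tuple(range(grad.ndim - len(shape))))
    for axis, n in enumerate(shape):
        if n == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g.reshape(shape)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """Valid-mode 2D convolution (cross-correlation), NCHW.

    ``w`` has shape (out_ch, in_ch, kh, kw). For stride 2 the spatial input
    minus kernel extent must be even so the grid tiles exactly.
    """
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    if h < kh or wd < kw:
        raise ValueError(f"input {h}x{wd} smaller than kernel {kh}x{kw}")
    if stride > 1 and ((h - kh) % stride or (wd - kw) % stride):
        raise ValueError(
            f"input {h}x{wd} does not tile with kernel {kh} stride {stride}")
    ho = (h - kh) // stride + 1
    wo = (wd - kw) // stride + 1

    out = np.zeros((n, f, ho, wo))
    for i in range(kh):
        for j in range(kw):
            xs = x.data[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            out += np.einsum("nchw,fc->nfhw", xs, w.data[:, :, i, j], optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    def bw(g):
        dx = np.zeros_like(x.data)
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                xs = x.data[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                dw[:, :, i, j] = np.einsum("nfhw,nchw->fc", g, xs, optimize=True)
                dx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                    np.einsum("nfhw,fc->nchw", g, w.data[:, :, i, j], optimize=True)
        db = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents, bw)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """2x2 stride-2 transposed convolution: exact 2x upsampling.

    ``w`` has shape (in_ch, out_ch, 2, 2); output spatial size is twice the
    input's.
    """
    n, c, h, wd = x.data.shape
    c2, f, kh, kw = w.data.shape
    if c != c2 or (kh, kw) != (2, 2):
        raise ValueError(f"expected (in={c}, out, 2, 2) kernel, got {w.data.shape}")
    out = np.zeros((n, f, 2 * h, 2 * wd))
    for i in range(2):
        for j in range(2):
            out[:, :, i::2, j::2] = np.einsum(
                "nchw,cf->nfhw", x.data, w.data[:, :, i, j], optimize=True)
    if b is not None:
        out += b.data[None, :, None, None]

    def bw(g):
        dx = np.zeros_like(x.data)
        dw = np.zeros_like(w.data)
        for i in range(2):
            for j in range(2):
                gs = g[:, :, i::2, j::2]
                dx += np.einsum("nfhw,cf->nchw", gs, w.data[:, :, i, j], optimize=True)
                dw[:, :, i, j] = np.einsum("nchw,nfhw->cf", x.data, gs, optimize=True)
        db = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents, bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics are used and the running estimates
    are updated in place; in inference mode the running estimates are used.
    """
    if training:
        axes = (0, 2, 3)
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size / x.data.shape[1]
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
        inv = 1.0 / np.sqrt(var + eps)
        xc = x.data - mu[None, :, None, None]
        xhat = xc * inv[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def bw(g):
            dgamma = (g * xhat).sum(axis=axes)
            dbeta = g.sum(axis=axes)
            dxhat = g * gamma.data[None, :, None, None]
            inv_b = inv[None, :, None, None]
            # standard batch-norm backward, vectorized per channel
            t1 = dxhat.sum(axis=axes)[None, :, None, None]
            t2 = (dxhat * xhat).sum(axis=axes)[None, :, None, None]
            dx = (inv_b / m) * (m * dxhat - t1 - xhat * t2)
            return dx, dgamma, dbeta

        return Tensor(out, (x, gamma, beta), bw)

    inv = 1.0 / np.sqrt(running_var + eps)
    xhat = (x.data - running_mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw_eval(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dx = g * (gamma.data * inv)[None, :, None, None]
        return dx, dgamma, dbeta

    return Tensor(out, (x, gamma, beta), bw_eval)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: identity at inference time."""
    if not training or rate <= 0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape[0] != b.data.shape[0] or a.data.shape[2:] != b.data.shape[2:]:
        raise ValueError(f"cannot concat shapes {a.data.shape} and {b.data.shape}")
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)
    return Tensor(out, (a, b), lambda g: (g[:, :ca], g[:, ca:]))


def center_crop(x: Tensor, target_hw) -> Tensor:
    """Center crop spatial dims to ``target_hw``; offsets must be integral."""
    h, w = x.data.shape[2:]
    th, tw = target_hw
    if th > h or tw > w or (h - th) % 2 or (w - tw) % 2:
        raise ValueError(f"cannot center-crop {h}x{w} to {th}x{tw}")
    oh, ow = (h - th) // 2, (w - tw) // 2

    def bw(g):
        dx = np.zeros_like(x.data)
        dx[:, :, oh:oh + th, ow:ow + tw] = g
        return (dx,)

    return Tensor(x.data[:, :, oh:oh + th, ow:ow + tw], (x,), bw)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the channel axis (NCHW)."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def bw(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        return (p * (g - dot),)

    return Tensor(p, (x,), bw)


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
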
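"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the operations the segmentation network needs:
2-D convolution (stride 1, zero padding) via im2col and BLAS matmul, 2x2
stride-2 transposed convolution, 2x2 average pooling, batch normalization,
rectifier, channel concatenation, channel softmax, and a fused categorical
cross-entropy reduction.  A :class:`Tensor` records its parents and a closure
that propagates the upstream gradient; :meth:`Tensor.backward` runs a
topological sweep.

Activations are laid out **channels-last** (N, H, W, C): im2col then reduces
to a handful of contiguous slice copies feeding one big matmul, which is what
keeps CPU training viable.  Convolution weights keep the conventional
(out, in, kh, kw) shape; the cheap weight-side transposes happen inside the
ops.  Everything is plain float arrays — float32 by default for speed, but
every op preserves its input dtype so tests can gradient-check in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "relu",
    "concat",
    "conv2d",
    "conv_transpose2x2",
    "avg_pool2x2",
    "softmax_channels",
    "cross_entropy",
    "nhwc_to_nchw",
    "Adam",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=False)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow Python recursion
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
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


# ---------------------------------------------------------------------------
# Convolution (stride 1, symmetric zero padding) via channels-last im2col
# ---------------------------------------------------------------------------

def _im2col_np(xp, kh, kw):
    """(N, Hp, Wp, C) -> (N*H*W, kh*kw*C) patch matrix, H = Hp-kh+1."""
    n, hp, wp, c = xp.shape
    h, w = hp - kh + 1, wp - kw + 1
    cols = np.empty((n, h, w, kh * kw, c), dtype=xp.dtype)
    k = 0
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, k, :] = xp[:, i : i + h, j : j + w, :]
            k += 1
    return cols.reshape(n * h * w, kh * kw * c)


def _col2im_np(cols, x_shape, kh, kw, pad):
    """Scatter-add patch gradients back to the (padded, then cropped) input."""
    n, h, w, c = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh, ow = hp - kh + 1, wp - kw + 1
    d = cols.reshape(n, oh, ow, kh * kw, c)
    gx = np.zeros((n, hp, wp, c), dtype=cols.dtype)
    k = 0
    for i in range(kh):
        for j in range(kw):
            gx[:, i : i + oh, j : j + ow, :] += d[:, :, :, k, :]
            k += 1
    if pad:
        gx = gx[:, pad:-pad, pad:-pad, :]
    return gx


try:  # JIT-compiled patch kernels; the numpy path is the reference behaviour
    import numba as _nb

    @_nb.njit(cache=True)
    def _im2col_jit(xp, kh, kw, cols):  # pragma: no cover - exercised via _im2col
        n, hp, wp, c = xp.shape
        h, w = hp - kh + 1, wp - kw + 1
        for b in range(n):
            for y in range(h):
                for x in range(w):
                    row = (b * h + y) * w + x
                    k = 0
                    for i in range(kh):
                        for j in range(kw):
                            base = k * c
                            for ch in range(c):
                                cols[row, base + ch] = xp[b, y + i, x + j, ch]
                            k += 1

    @_nb.njit(cache=True)
    def _col2im_jit(cols, gx, kh, kw):  # pragma: no cover - exercised via _col2im
        n, hp, wp, c = gx.shape
        h, w = hp - kh + 1, wp - kw + 1
        for b in range(n):
            for y in range(h):
                for x in range(w):
                    row = (b * h + y) * w + x
                    k = 0
                    for i in range(kh):
                        for j in range(kw):
                            base = k * c
                            for ch in range(c):
                                gx[b, y + i, x + j, ch] += cols[row, base + ch]
                            k += 1

    def _im2col(xp, kh, kw):
        n, hp, wp, c = xp.shape
        h, w = hp - kh + 1, wp - kw + 1
        cols = np.empty((n * h * w, kh * kw * c), dtype=xp.dtype)
        _im2col_jit(np.ascontiguousarray(xp), kh, kw, cols)
        return cols

    def _col2im(cols, x_shape, kh, kw, pad):
        n, h, w, c = x_shape
        gx = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=cols.dtype)
        _col2im_jit(np.ascontiguousarray(cols), gx, kh, kw)
        if pad:
            gx = gx[:, pad:-pad, pad:-pad, :]
        return gx

except ImportError:  # pragma: no cover
    _im2col = _im2col_np
    _col2im = _col2im_np


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int | None = None) -> Tensor:
    """Stride-1 convolution on (N, H, W, C). ``w``: (Cout, Cin, kh, kw);
    default 'same' padding."""
    x, w = _as_tensor(x), _as_tensor(w)
    cout, cin, kh, kw = w.data.shape
    if pad is None:
        pad = (kh - 1) // 2
    n, h, ww, c = x.data.shape
    if c != cin:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cin}")
    if kh == 1 and kw == 1 and pad == 0:
        return _conv1x1(x, w, b)
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.data
    cols = _im2col(xp, kh, kw)
    # weight matrix in (kh, kw, cin) -> cout layout to match the patch order
    wmat = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0)).reshape(kh * kw * cin, cout)
    oh, ow = h + 2 * pad - kh + 1, ww + 2 * pad - kw + 1
    out = cols @ wmat
    if b is not None:
        out += b.data
    out = out.reshape(n, oh, ow, cout)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(-1, cout)
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if w.requires_grad:
            gw = (cols.T @ gm).reshape(kh, kw, cin, cout).transpose(3, 2, 0, 1)
            w._accumulate(np.ascontiguousarray(gw))
        if x.requires_grad:
            x._accumulate(_col2im(gm @ wmat.T, x.data.shape, kh, kw, pad))

    return Tensor(out, parents=parents, backward=backward)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution: a per-pixel matmul, no patch extraction."""
    cout, cin = w.data.shape[:2]
    xm = x.data.reshape(-1, cin)
    wmat = np.ascontiguousarray(w.data.reshape(cout, cin).T)
    out = xm @ wmat
    if b is not None:
        out += b.data
    out = out.reshape(*x.data.shape[:3], cout)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(-1, cout)
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if w.requires_grad:
            w._accumulate((gm.T @ xm).reshape(w.data.shape))
        if x.requires_grad:
            x._accumulate((gm @ wmat.T).reshape(x.data.shape))

    return Tensor(out, parents=parents, backward=backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x spatial upsampling by a kernel-2 stride-2 transposed convolution.

    ``x``: (N, H, W, Cin); ``w``: (Cin, Cout, 2, 2).  Stride equals kernel
    size, so output 2x2 blocks never overlap and the op is a per-pixel matmul
    followed by a block interleave.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    cin, cout, _, _ = w.data.shape
    n, h, ww, c = x.data.shape
    if c != cin:
        raise ValueError(f"conv_transpose2x2: input has {c} channels, weight expects {cin}")
    xm = x.data.reshape(-1, cin)
    wmat = np.ascontiguousarray(w.data.transpose(0, 2, 3, 1)).reshape(cin, 4 * cout)
    prod = (xm @ wmat).reshape(n, h, ww, 2, 2, cout)
    out = np.ascontiguousarray(prod.transpose(0, 1, 3, 2, 4, 5)).reshape(n, 2 * h, 2 * ww, cout)
    if b is not None:
        out += b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gb = g.reshape(n, h, 2, ww, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        gm = np.ascontiguousarray(gb).reshape(-1, 4 * cout)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            gw = (xm.T @ gm).reshape(cin, 2, 2, cout).transpose(0, 3, 1, 2)
            w._accumulate(np.ascontiguousarray(gw))
        if x.requires_grad:
            x._accumulate((gm @ wmat.T).reshape(x.data.shape))

    return Tensor(out, parents=parents, backward=backward)


def avg_pool2x2(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2x2 requires even spatial size, got {h}x{w}")
    out_data = x.data.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(g):
        if x.requires_grad:
            gq = (g * np.asarray(0.25, dtype=g.dtype))[:, :, None, :, None, :]
            gx = np.broadcast_to(gq, (n, h // 2, 2, w // 2, 2, c)).reshape(x.data.shape)
            x._accumulate(np.ascontiguousarray(gx))

    return Tensor(out_data, parents=(x,), backward=backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the trailing channel axis."""
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            x._accumulate(p * (g - dot))

    return Tensor(p, parents=(x,), backward=backward)


def nhwc_to_nchw(x: Tensor) -> Tensor:
    """Layout boundary: internal (N, H, W, C) -> external (N, C, H, W)."""
    x = _as_tensor(x)
    out_data = np.ascontiguousarray(x.data.transpose(0, 3, 1, 2))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.ascontiguousarray(g.transpose(0, 2, 3, 1)))

    return Tensor(out_data, parents=(x,), backward=backward)


def cross_entropy(probs: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Categorical cross entropy against one-hot targets on (N, C, H, W).

    Sums over the class axis (1), averages over batch and pixels.
    Probabilities are clamped at ``eps`` before the log; the clamp blocks the
    gradient where it is active.
    """
    probs = _as_tensor(probs)
    target = np.asarray(target)
    if target.shape != probs.data.shape:
        raise ValueError(f"cross_entropy: target shape {target.shape} != prediction shape {probs.data.shape}")
    clamped = np.maximum(probs.data, eps)
    per_pixel = -(target * np.log(clamped)).sum(axis=1)
    denom = per_pixel.size
    out_data = np.asarray(per_pixel.sum() / denom, dtype=probs.data.dtype)

    def backward(g):
        if probs.requires_grad:
            gp = np.where(probs.data >= eps, -target / clamped, 0.0) * (g / denom)
            probs._accumulate(gp.astype(probs.data.dtype, copy=False))

    return Tensor(out_data, parents=(probs,), backward=backward)


class Adam:
    """Adaptive-moment optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
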
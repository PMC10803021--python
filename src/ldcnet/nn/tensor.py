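"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor core: just the operations the segmentation model
needs (depthwise / pointwise convolution, batch normalization, bilinear
resizing, softmax families, elementwise arithmetic, einsum contractions and a
label gather for the loss).  Arrays are float32 throughout; gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` in reverse
topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "add", "sub", "mul", "neg", "relu", "concat",
    "narrow", "einsum2", "pointwise_conv", "depthwise_conv", "batch_norm",
    "bilinear_resize", "resize_matrix", "avg_pool2", "softmax", "log_softmax",
    "exp", "power", "masked_mean",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        g = np.asarray(g, dtype=np.float32)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or not g.flags.owndata else g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        """Backpropagate from this tensor (scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep (dense connectivity)
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    # convenience operator sugar -------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return sub(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  parents=[p for p in parents if p.requires_grad],
                  backward_fn=backward_fn if req else None)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    a = as_tensor(a)

    def backward(g):
        a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def sub(a, b):
    return add(a, neg(as_tensor(b)))


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tensors, backward)


def narrow(a, axis, start, length):
    a = as_tensor(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        a._accumulate(full)

    return _make(a.data[idx], (a,), backward)


def einsum2(spec, a, b):
    """Two-operand einsum with automatic backward.

    Every index of each operand must appear in the output or in the other
    operand (no internal sums over a single operand), which holds for all
    contractions used here.
    """
    a, b = as_tensor(a), as_tensor(b)
    ins, s_out = spec.split("->")
    s_a, s_b = ins.split(",")
    out_data = np.einsum(spec, a.data, b.data, optimize=True)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.einsum(f"{s_out},{s_b}->{s_a}", g, b.data, optimize=True))
        if b.requires_grad:
            b._accumulate(np.einsum(f"{s_out},{s_a}->{s_b}", g, a.data, optimize=True))

    return _make(out_data, (a, b), backward)


def pointwise_conv(x, w, b=None):
    """1x1 convolution: x (N,C,H,W), w (O,C), optional bias (O,)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    o = w.data.shape[0]
    xr = x.data.reshape(n, c, h * wd)
    out_data = np.matmul(w.data[None], xr).reshape(n, o, h, wd)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gr = g.reshape(n, o, h * wd)
        if x.requires_grad:
            x._accumulate(np.matmul(w.data.T[None], gr).reshape(n, c, h, wd))
        if w.requires_grad:
            w._accumulate(np.einsum("noh,nch->oc", gr, xr, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out_data, parents, backward)


def depthwise_conv(x, w, stride=1):
    """Depthwise convolution: x (N,C,H,W), w (C,k,k), 'same' padding.

    Implemented as a shift-and-accumulate over the k*k kernel offsets, which
    vectorizes well and avoids im2col buffers.  For stride 2, H and W must be
    even and the output is H/2 x W/2.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    k = w.data.shape[1]
    pad = k // 2
    if stride not in (1, 2):
        raise ValueError("stride must be 1 or 2")
    if stride == 2 and (h % 2 or wd % 2):
        raise ValueError("stride-2 depthwise convolution needs even spatial size")
    ho, wo = h // stride, wd // stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_data = np.zeros((n, c, ho, wo), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            sl = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            out_data += w.data[:, i, j][None, :, None, None] * sl

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(k):
                for j in range(k):
                    sl = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                    gw[:, i, j] = np.einsum("nchw,nchw->c", g, sl, optimize=True)
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += (
                        w.data[:, i, j][None, :, None, None] * g)
            x._accumulate(gxp[:, :, pad:pad + h, pad:pad + wd])

    return _make(out_data, (x, w), backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training,
               momentum=0.1, eps=1e-5):
    """Batch normalization over (N,H,W) per channel.

    ``running_mean``/``running_var`` are plain float32 arrays updated in place
    in training mode (biased variance, as used for normalization).
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xc = x.data - mean[None, :, None, None]
    xhat = xc * ivar[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(np.einsum("nchw,nchw->c", g, xhat, optimize=True))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                # mean/variance depend on x: full batch-norm backward
                s1 = gxhat.sum(axis=(0, 2, 3))[None, :, None, None]
                s2 = np.einsum("nchw,nchw->c", gxhat, xhat,
                               optimize=True)[None, :, None, None]
                gx = (gxhat - s1 / m - xhat * s2 / m) * ivar[None, :, None, None]
            else:
                gx = gxhat * ivar[None, :, None, None]
            x._accumulate(gx.astype(np.float32))

    return _make(out_data, (x, gamma, beta), backward)


def resize_matrix(n_out, n_in):
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers).

    ``out[i] = sum_j M[i, j] * in[j]`` with source coordinate
    ``(i + 0.5) * n_in / n_out - 0.5`` clamped to the valid range.
    """
    m = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x, out_h, out_w):
    """Separable bilinear resize of x (N,C,H,W) to (N,C,out_h,out_w)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    mh = resize_matrix(out_h, h)
    mw = resize_matrix(out_w, w)
    tmp = np.tensordot(x.data, mh, axes=([2], [1]))       # (N,C,W,out_h)
    out_data = np.tensordot(tmp, mw, axes=([2], [1]))     # (N,C,out_h,out_w)
    out_data = np.ascontiguousarray(out_data.astype(np.float32))

    def backward(g):
        t = np.tensordot(g, mw, axes=([3], [0]))          # (N,C,out_h,W)
        gx = np.tensordot(t.transpose(0, 1, 3, 2), mh, axes=([3], [0]))
        x._accumulate(gx.transpose(0, 1, 3, 2).astype(np.float32))

    return _make(out_data, (x,), backward)


def avg_pool2(x):
    """2x2 average pooling with stride 2 (even spatial sizes)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 needs even spatial size")
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def softmax(x, axis=-1):
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return _make(s, (x,), backward)


def log_softmax(x, axis=1):
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    p = np.exp(out_data)

    def backward(g):
        x._accumulate(g - p * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (x,), backward)


def exp(x):
    x = as_tensor(x)
    e = np.exp(x.data)

    def backward(g):
        x._accumulate(g * e)

    return _make(e, (x,), backward)


def power(x, p):
    """Elementwise x**p for constant p >= 1 (used for the focal modulator)."""
    x = as_tensor(x)
    out_data = np.power(x.data, p)

    def backward(g):
        x._accumulate(g * p * np.power(x.data, p - 1.0))

    return _make(out_data, (x,), backward)


def gather_label(x, labels):
    """Select x[n, labels[n,h,w], h, w] from logits-like x (N,K,H,W)."""
    x = as_tensor(x)
    labels = np.asarray(labels)
    n, k, h, w = x.data.shape
    ni, hi, wi = np.ogrid[:n, :h, :w]
    out_data = x.data[ni, labels, hi, wi]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[ni, labels, hi, wi] = g  # (n,h,w) index triples are unique
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def masked_mean(x, mask=None):
    """Mean of x over entries where mask is True (all entries if None)."""
    x = as_tensor(x)
    if mask is None:
        cnt = x.data.size
        out_data = x.data.mean()

        def backward(g):
            x._accumulate(np.full_like(x.data, g / cnt))
    else:
        mask = np.asarray(mask, dtype=bool)
        cnt = int(mask.sum())
        if cnt == 0:
            raise ValueError("masked_mean over an empty mask")
        out_data = x.data[mask].mean()

        def backward(g):
            gx = np.zeros_like(x.data)
            gx[mask] = g / cnt
            x._accumulate(gx)

    return _make(np.float32(out_data), (x,), backward)
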
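"""Criss-cross attention: sparse row/column self-attention.

Each spatial position u attends to the H + W - 1 positions sharing its row or
column.  Query/key maps Q, K (B channels, B < C) and value map V (C channels)
come from 1x1 convolutions of the input F.  For each u the affinity scores
are d_u = Omega_u Q_u, where Omega_u stacks the K-vectors on u's cross;
softmax gives attention weights A_u, and the output is
F'_u = Phi_u^T A_u + F_u with Phi_u the stacked V-vectors (a residual around
a convex combination of values on the cross).

Internally the weight tensor has H + W entries per position: the full row
plus the full column, with the duplicate of u in the column part masked to
-inf before the softmax, leaving exactly H + W - 1 positions with nonzero
weight.  The efficient path never materializes an (H*W) x (H*W) score matrix;
its peak intermediate is H * W * (H + W) scores.  A dense masked-attention
oracle (:func:`dense_attention_oracle`) exists for testing only.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor, as_tensor

_NEG = np.float32(-1e9)  # underflows to exactly zero weight after softmax


def _duplicate_mask(h, w):
    """Additive mask (1,H,W,W+H) cancelling u's duplicate column entry."""
    mask = np.zeros((1, h, w, w + h), dtype=np.float32)
    for i in range(h):
        mask[0, i, :, w + i] = _NEG
    return mask


def criss_cross_affinity(q, k):
    """Attention weights over each position's row and column.

    ``q``, ``k``: (N,B,H,W).  Returns a Tensor (N,H,W,W+H): entries
    ``[..., :W]`` weight the row positions (u included at index w), entries
    ``[..., W:]`` the column positions, with the duplicate at column index h
    forced to zero weight.  Each weight vector is nonnegative and sums to 1.
    """
    q, k = as_tensor(q), as_tensor(k)
    n, b, h, w = q.shape
    if h == 0 or w == 0:
        raise ValueError("empty spatial grid")
    if k.shape != q.shape:
        raise ValueError("Q and K must have identical shape")
    row = T.einsum2("nbhw,nbhj->nhwj", q, k)   # scores against row positions
    col = T.einsum2("nbhw,nbiw->nhwi", q, k)   # scores against column positions
    scores = T.concat([row, col], axis=3)
    scores = T.add(scores, Tensor(_duplicate_mask(h, w)))
    return T.softmax(scores, axis=3)


def criss_cross_aggregate(attn, v, f):
    """Aggregate values along each cross and add the residual.

    ``attn``: (N,H,W,W+H) from :func:`criss_cross_affinity`; ``v``, ``f``:
    (N,C,H,W).  Returns F'_u = Phi_u^T A_u + F_u, shape (N,C,H,W).
    """
    attn, v, f = as_tensor(attn), as_tensor(v), as_tensor(f)
    n, h, w, s = attn.shape
    if v.shape[2:] != (h, w) or f.shape != v.shape:
        raise ValueError("attention and value grids disagree")
    if s != h + w:
        raise ValueError("attention support must cover the row and column")
    a_row = T.narrow(attn, 3, 0, w)
    a_col = T.narrow(attn, 3, w, h)
    out = T.add(T.einsum2("nhwj,nchj->nchw", a_row, v),
                T.einsum2("nhwi,nciw->nchw", a_col, v))
    return T.add(out, f)


class CrissCrossAttention(nn.Module):
    """The full module: 1x1 projections to Q, K, V, affinity, aggregation."""

    def __init__(self, channels, rng, reduction=8):
        super().__init__()
        b = max(1, channels // reduction)
        if b >= channels:
            raise ValueError("channel reduction must give B < C")
        self.channels = channels
        self.reduced = b
        self.query = nn.PointwiseConv(channels, b, rng, bias=True)
        self.key = nn.PointwiseConv(channels, b, rng, bias=True)
        self.value = nn.PointwiseConv(channels, channels, rng, bias=True)

    def forward(self, f):
        if f.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {f.shape[1]}")
        q = self.query(f)
        k = self.key(f)
        v = self.value(f)
        attn = criss_cross_affinity(q, k)
        return criss_cross_aggregate(attn, v, f)

    def count_macs(self, h, w):
        m = 0
        for conv in (self.query, self.key, self.value):
            m += conv.count_macs(h, w)[0]
        cross = h + w - 1
        m += h * w * self.reduced * cross      # affinity dot products
        m += h * w * self.channels * cross     # aggregation weighted sums
        return m, h, w


def dense_attention_oracle(f, module: CrissCrossAttention):
    """Brute-force reference: dense attention masked to the criss-cross support.

    Builds the full (H*W) x (H*W) score matrix Q_u . K_v, sets entries where v
    shares neither row nor column with u to -inf, softmaxes each row,
    aggregates V and adds the residual.  Small inputs only (H*W <= 256);
    numpy-only, no autograd.
    """
    f = np.asarray(f.data if isinstance(f, Tensor) else f, dtype=np.float32)
    n, c, h, w = f.shape
    if h * w > 256:
        raise ValueError("oracle is restricted to tiny inputs")
    flat = f.reshape(n, c, h * w)
    wq, bq = module.query.weight.data, module.query.bias.data
    wk, bk = module.key.weight.data, module.key.bias.data
    wv, bv = module.value.weight.data, module.value.bias.data
    q = wq @ flat + bq[:, None]
    k = wk @ flat + bk[:, None]
    v = wv @ flat + bv[:, None]

    rows = np.repeat(np.arange(h), w)
    cols = np.tile(np.arange(w), h)
    support = (rows[:, None] == rows[None, :]) | (cols[:, None] == cols[None, :])

    out = np.empty_like(flat)
    for ni in range(n):
        scores = q[ni].T @ k[ni]                      # (HW, HW)
        scores = np.where(support, scores, -np.inf)
        scores -= scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        a = e / e.sum(axis=1, keepdims=True)
        out[ni] = v[ni] @ a.T + flat[ni]
    return out.reshape(n, c, h, w)
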
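"""Criss-cross attention: affinity/aggregation semantics and the dense oracle."""

import numpy as np
import pytest

from ldcnet import nn
from ldcnet.ccam import (CrissCrossAttention, criss_cross_affinity,
                         criss_cross_aggregate, dense_attention_oracle)
from ldcnet.nn.tensor import Tensor


def _brute_affinity(q, k):
    """Double loop over (u, v): gather row/column dot products, softmax."""
    n, b, h, w = q.shape
    out = np.zeros((n, h, w, w + h), dtype=np.float64)
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                scores = []
                for jj in range(w):                 # row, u included at jj == j
                    scores.append(q[ni, :, i, j] @ k[ni, :, i, jj])
                for ii in range(h):                 # column; duplicate masked
                    s = q[ni, :, i, j] @ k[ni, :, ii, j]
                    scores.append(-np.inf if ii == i else s)
                scores = np.asarray(scores)
                scores -= scores[np.isfinite(scores)].max()
                e = np.exp(scores)
                out[ni, i, j] = e / e.sum()
    return out


def _brute_aggregate(a, v, f):
    n, c, h, w = v.shape
    out = np.zeros_like(v, dtype=np.float64)
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                acc = np.zeros(c)
                for jj in range(w):
                    acc += a[ni, i, j, jj] * v[ni, :, i, jj]
                for ii in range(h):
                    acc += a[ni, i, j, w + ii] * v[ni, :, ii, j]
                out[ni, :, i, j] = acc + f[ni, :, i, j]
    return out


class TestAffinity:
    def test_single_position_weight_is_one(self, rng):
        q = rng.standard_normal((1, 2, 1, 1)).astype(np.float32)
        k = rng.standard_normal((1, 2, 1, 1)).astype(np.float32)
        a = criss_cross_affinity(Tensor(q), Tensor(k)).data
        nz = a[a > 0]
        assert nz.shape == (1,)
        assert nz[0] == pytest.approx(1.0, abs=1e-6)

    def test_constant_key_gives_uniform_weights(self, rng):
        h, w = 3, 5
        q = rng.standard_normal((1, 4, h, w)).astype(np.float32)
        k = np.broadcast_to(rng.standard_normal((1, 4, 1, 1)), (1, 4, h, w))
        a = criss_cross_affinity(Tensor(q), Tensor(k.astype(np.float32))).data
        nz = a[a > 0].reshape(h * w, h + w - 1)
        assert np.allclose(nz, 1.0 / (h + w - 1), atol=1e-6)

    def test_matches_gather_and_dot_brute_force(self, rng):
        q = rng.standard_normal((1, 4, 3, 5)).astype(np.float32)
        k = rng.standard_normal((1, 4, 3, 5)).astype(np.float32)
        a = criss_cross_affinity(Tensor(q), Tensor(k)).data
        assert np.allclose(a, _brute_affinity(q, k), atol=1e-5)

    def test_weights_sum_to_one_and_support_size(self, rng):
        q = rng.standard_normal((2, 3, 6, 4)).astype(np.float32)
        k = rng.standard_normal((2, 3, 6, 4)).astype(np.float32)
        a = criss_cross_affinity(Tensor(q), Tensor(k)).data
        assert np.allclose(a.sum(axis=3), 1.0, atol=1e-6)
        assert ((a > 0).sum(axis=3) == 6 + 4 - 1).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            criss_cross_affinity(Tensor(np.zeros((1, 2, 0, 3))),
                                 Tensor(np.zeros((1, 2, 0, 3))))


class TestAggregate:
    def test_constant_value_adds_constant(self, rng):
        h, w, c = 4, 3, 5
        q = rng.standard_normal((1, 2, h, w)).astype(np.float32)
        k = rng.standard_normal((1, 2, h, w)).astype(np.float32)
        a = criss_cross_affinity(Tensor(q), Tensor(k))
        const = rng.standard_normal(c).astype(np.float32)
        v = np.broadcast_to(const[None, :, None, None], (1, c, h, w)).copy()
        f = rng.standard_normal((1, c, h, w)).astype(np.float32)
        out = criss_cross_aggregate(a, Tensor(v), Tensor(f)).data
        assert np.allclose(out, f + const[None, :, None, None], atol=1e-5)

    def test_single_position_is_residual_plus_value(self, rng):
        a = Tensor(np.ones((1, 1, 1, 2), dtype=np.float32) * [[[[1.0, 0.0]]]])
        v = rng.standard_normal((1, 3, 1, 1)).astype(np.float32)
        f = rng.standard_normal((1, 3, 1, 1)).astype(np.float32)
        out = criss_cross_aggregate(a, Tensor(v), Tensor(f)).data
        assert np.allclose(out, v + f, atol=1e-6)

    def test_matches_double_loop_oracle(self, rng):
        h, w, c = 3, 5, 4
        q = rng.standard_normal((1, 2, h, w)).astype(np.float32)
        k = rng.standard_normal((1, 2, h, w)).astype(np.float32)
        a = criss_cross_affinity(Tensor(q), Tensor(k))
        v = rng.standard_normal((1, c, h, w)).astype(np.float32)
        f = rng.standard_normal((1, c, h, w)).astype(np.float32)
        out = criss_cross_aggregate(a, Tensor(v), Tensor(f)).data
        assert np.allclose(out, _brute_aggregate(a.data, v, f), atol=1e-5)


class TestModule:
    def test_zero_input_zero_output(self, rng):
        mod = CrissCrossAttention(8, rng, reduction=4)
        for conv in (mod.query, mod.key, mod.value):
            conv.bias.data[:] = 0.0
        f = Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32))
        assert np.allclose(mod(f).data, 0.0)

    def test_output_minus_input_in_value_convex_hull(self, rng):
        mod = CrissCrossAttention(6, rng, reduction=3)
        f = rng.standard_normal((1, 6, 5, 4)).astype(np.float32)
        out = mod(Tensor(f)).data
        v = (np.einsum("oc,nchw->nohw", mod.value.weight.data, f)
             + mod.value.bias.data[None, :, None, None])
        delta = out - f
        for i in range(5):
            for j in range(4):
                cross = np.concatenate([v[0, :, i, :], v[0, :, :, j]], axis=1)
                assert (delta[0, :, i, j] <= cross.max(axis=1) + 1e-5).all()
                assert (delta[0, :, i, j] >= cross.min(axis=1) - 1e-5).all()

    def test_residual_guarantee_with_zero_value_projection(self, rng):
        mod = CrissCrossAttention(8, rng, reduction=4)
        mod.value.weight.data[:] = 0.0
        mod.value.bias.data[:] = 0.0
        f = rng.standard_normal((2, 8, 3, 3)).astype(np.float32)
        assert np.array_equal(mod(Tensor(f)).data, f)

    def test_reduction_must_shrink_channels(self, rng):
        with pytest.raises(ValueError):
            CrissCrossAttention(1, rng, reduction=2)

    def test_efficient_path_intermediate_size(self, rng):
        # structural: the attention tensor covers H+W entries per position,
        # never (H*W)^2
        mod = CrissCrossAttention(4, rng, reduction=4)
        q = mod.query(Tensor(rng.random((1, 4, 6, 7)).astype(np.float32)))
        k = mod.key(Tensor(rng.random((1, 4, 6, 7)).astype(np.float32)))
        a = criss_cross_affinity(q, k)
        assert a.shape == (1, 6, 7, 7 + 6)


class TestDenseOracle:
    def test_equivalence_over_random_configs(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            c = int(rng.integers(2, 16))
            red = int(rng.integers(2, min(c, 8) + 1)) if c > 1 else 2
            h = int(rng.integers(1, 13))
            w = int(rng.integers(1, 13))
            mod = CrissCrossAttention(c, rng, reduction=red)
            f = rng.standard_normal((1, c, h, w)).astype(np.float32)
            got = mod(Tensor(f)).data
            ref = dense_attention_oracle(f, mod)
            worst = max(worst, float(np.abs(got - ref).max()))
        assert worst < 1e-5

    def test_oracle_mask_support_count(self):
        h, w = 3, 5
        rows = np.repeat(np.arange(h), w)
        cols = np.tile(np.arange(w), h)
        support = ((rows[:, None] == rows[None, :])
                   | (cols[:, None] == cols[None, :]))
        assert (support.sum(axis=1) == h + w - 1).all()

    def test_transpose_symmetry(self, rng):
        mod = CrissCrossAttention(5, rng, reduction=5 // 2 + 1)
        f = rng.standard_normal((1, 5, 4, 7)).astype(np.float32)
        out = mod(Tensor(f)).data
        out_t = mod(Tensor(np.ascontiguousarray(f.transpose(0, 1, 3, 2)))).data
        assert np.allclose(out_t, out.transpose(0, 1, 3, 2), atol=1e-5)
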
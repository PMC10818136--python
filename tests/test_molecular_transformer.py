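"""Encoder stacks, the interaction pairing map and the conv readout."""

import numpy as np
import pytest

from sagdti.autodiff import Tensor
from sagdti.molecular_transformer import ConvReadout, EncoderBlock, EncoderStack, pairing_map


def _zero_block(block: EncoderBlock):
    for t in (block.W_Q, block.W_K, block.W_V, block.W_O, block.W_1, block.W_2):
        t.data[:] = 0.0


def _layernorm(x):
    mu = x.mean(-1, keepdims=True)
    v = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(v + 1e-5)


class TestEncoder:
    def test_zero_weights_give_layer_normalized_passthrough(self, rng):
        blk = EncoderBlock(8, 2, rng)
        _zero_block(blk)
        x = Tensor(rng.standard_normal((1, 5, 8)))
        out = blk.forward(x, None, None).data
        assert np.allclose(out, _layernorm(_layernorm(x.data)), atol=1e-10)

    def test_single_token_self_attention_weight_one(self, rng):
        blk = EncoderBlock(6, 1, rng)
        x = Tensor(rng.standard_normal((1, 1, 6)))
        # with one valid token attention output is exactly V for that token
        v = x.data @ blk.W_V.data @ blk.W_O.data
        got = blk.msa(x, None, np.array([[True]])).data
        assert np.allclose(got, v, atol=1e-12)

    def test_multi_head_matches_loop_oracle(self, rng):
        dim, heads, n = 8, 2, 5
        blk = EncoderBlock(dim, heads, rng)
        x = rng.standard_normal((1, n, dim))
        got = blk.msa(Tensor(x), None, None).data[0]
        hd = dim // heads
        outs = []
        for h in range(heads):
            sl = slice(h * hd, (h + 1) * hd)
            q = (x[0] @ blk.W_Q.data)[:, sl]
            k = (x[0] @ blk.W_K.data)[:, sl]
            v = (x[0] @ blk.W_V.data)[:, sl]
            head = np.zeros((n, hd))
            for i in range(n):
                logits = np.array([q[i] @ k[j] / np.sqrt(hd) for j in range(n)])
                w = np.exp(logits - logits.max())
                w /= w.sum()
                for j in range(n):
                    head[i] += w[j] * v[j]
            outs.append(head)
        want = np.concatenate(outs, axis=1) @ blk.W_O.data
        assert np.abs(got - want).max() < 1e-5

    def test_head_count_must_divide_hidden_dim(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            EncoderBlock(10, 3, rng)

    def test_token_permutation_equivariance(self, rng):
        stack = EncoderStack(8, 2, 2, rng)
        n = 6
        x = rng.standard_normal((1, n, 8))
        bias = rng.standard_normal((1, n, n))
        perm = rng.permutation(n)
        out = stack.forward(Tensor(x), bias=Tensor(bias)).data[0]
        out_p = stack.forward(Tensor(x[:, perm]), bias=Tensor(bias[:, perm][:, :, perm])).data[0]
        assert np.abs(out[perm] - out_p).max() < 1e-10

    def test_zero_initialized_extra_blocks_are_identity(self, rng):
        """Doubling the stack depth with fully zeroed blocks (weights and
        LayerNorm gains) leaves the output unchanged: each zero block emits 0
        and the residual add passes the input through."""
        stack = EncoderStack(8, 2, 1, rng)
        x = Tensor(rng.standard_normal((1, 4, 8)))
        base = stack.forward(x).data
        extra = EncoderBlock(8, 2, rng)
        _zero_block(extra)
        extra.ln1_g.data[:] = 0.0
        extra.ln2_g.data[:] = 0.0
        deeper = EncoderStack(8, 2, 1, rng)
        deeper.blocks = stack.blocks + [extra]
        assert np.allclose(deeper.forward(x).data, base, atol=0)

    def test_attention_rows_sum_to_one_with_mask(self, rng):
        from sagdti.autodiff import softmax

        blk = EncoderBlock(8, 2, rng)
        x = Tensor(rng.standard_normal((2, 5, 8)))
        mask = np.array([[True] * 5, [True, True, True, False, False]])
        q = (x.data @ blk.W_Q.data).reshape(2, 5, 2, 4).transpose(0, 2, 1, 3)
        k = (x.data @ blk.W_K.data).reshape(2, 5, 2, 4).transpose(0, 2, 1, 3)
        logits = Tensor(q @ k.transpose(0, 1, 3, 2) / 2.0)
        attn = softmax(logits, axis=-1, mask=mask[:, None, None, :]).data
        assert np.allclose(attn.sum(-1), 1.0, atol=1e-6)
        assert np.all(attn[1, :, :, 3:] == 0.0)


class TestPairingMap:
    def test_orthogonal_embeddings_give_half(self):
        d = Tensor(np.array([[[1.0, 0.0]]]))
        p = Tensor(np.array([[[0.0, 1.0]]]))
        im = pairing_map(d, p).data
        assert im[0, 0, 0] == pytest.approx(0.5)

    def test_identical_unit_embeddings_closed_form(self):
        dim = 4
        v = np.zeros((1, 1, dim))
        v[..., 0] = 1.0
        im = pairing_map(Tensor(v), Tensor(v)).data
        assert im[0, 0, 0] == pytest.approx(1 / (1 + np.exp(-1 / np.sqrt(dim))))

    def test_matrix_product_equals_per_pair_loop(self, rng):
        d = rng.standard_normal((1, 4, 6))
        p = rng.standard_normal((1, 3, 6))
        raw = pairing_map(Tensor(d), Tensor(p), transform="raw").data[0]
        for i in range(4):
            for j in range(3):
                want = float(sum(d[0, i, k] * p[0, j, k] for k in range(6)))
                assert raw[i, j] == pytest.approx(want, abs=1e-12)

    def test_sigmoid_map_bounded_and_monotone(self, rng):
        d = rng.standard_normal((1, 5, 4)) * 3
        p = rng.standard_normal((1, 5, 4)) * 3
        raw = pairing_map(Tensor(d), Tensor(p), transform="raw").data.ravel()
        im = pairing_map(Tensor(d), Tensor(p), transform="sigmoid").data.ravel()
        assert np.all((im >= 0) & (im <= 1))
        order = np.argsort(raw)
        assert np.all(np.diff(im[order]) >= 0)

    def test_masked_entries_exactly_zero(self, rng):
        d = rng.standard_normal((1, 4, 5))
        p = rng.standard_normal((1, 3, 5))
        rm = np.array([[True, True, False, True]])
        cm = np.array([[True, False, True]])
        im = pairing_map(Tensor(d), Tensor(p), row_mask=rm, col_mask=cm).data[0]
        assert np.all(im[2, :] == 0.0) and np.all(im[:, 1] == 0.0)

    def test_dimension_mismatch_names_both(self):
        with pytest.raises(ValueError, match="4 vs.*6|drug 4"):
            pairing_map(Tensor(np.zeros((1, 2, 4))), Tensor(np.zeros((1, 2, 6))))


class TestConvReadout:
    def test_identity_one_by_one_filter_returns_map(self, rng):
        ro = ConvReadout(1, rng, filter_size=(1, 1), pool=None)
        ro.filters.data[:] = 1.0
        ro.bias.data[:] = 0.0
        m = rng.standard_normal((1, 4, 5))
        out = ro.forward(Tensor(m), activation="linear").data
        assert np.allclose(out, m.reshape(1, -1))

    def test_all_zero_map_gives_zero_features(self, rng):
        ro = ConvReadout(3, rng, pool=None)
        out = ro.forward(Tensor(np.zeros((1, 4, 4)))).data
        assert np.all(out == 0.0)

    def test_three_by_three_matches_sliding_window_oracle(self, rng):
        ro = ConvReadout(1, rng, pool=None)
        m = rng.standard_normal((1, 5, 5))
        out = ro.forward(Tensor(m), activation="linear").data.reshape(5, 5)
        f = ro.filters.data[0, 0]
        b = float(ro.bias.data[0])
        padded = np.pad(m[0], 1)
        for i in range(5):
            for j in range(5):
                want = (padded[i : i + 3, j : j + 3] * f).sum() + b
                assert out[i, j] == pytest.approx(want, abs=1e-10)

    def test_global_pool_is_per_channel_max(self, rng):
        ro = ConvReadout(2, rng, pool="global")
        m = rng.standard_normal((3, 6, 7))
        got = ro.forward(Tensor(m)).data
        full = ConvReadout(2, rng, pool=None)
        full.filters.data = ro.filters.data.copy()
        full.bias.data = ro.bias.data.copy()
        maps = full.forward(Tensor(m)).data.reshape(3, 2, 42)
        assert np.allclose(got, maps.max(-1))
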
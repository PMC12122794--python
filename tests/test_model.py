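"""Architecture tests: attention oracles, reduction identities, fusion
gating, classifier softmax, initialization and the parameter budget."""

import numpy as np
import pytest

from impact.model import (CrossModalFusion, ImpactModel, ModalityEncoder,
                          ModelConfig, MultiHeadAttention, TransformerLayer,
                          count_parameters, estimate_fusion_memory,
                          relative_attention, scaled_dot_attention,
                          sinusoidal_positions, softmax_probabilities)
from impact.nn import Parameter, Tensor


def naive_attention(Q, K, V, B=None):
    """Oracle: definitional two-loop softmax attention."""
    T_q, d_k = Q.shape
    T_k = K.shape[0]
    out = np.zeros((T_q, V.shape[1]))
    W = np.zeros((T_q, T_k))
    for i in range(T_q):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d_k) for j in range(T_k)])
        if B is not None:
            scores = scores + B[i]
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        W[i] = w
        for j in range(T_k):
            out[i] += w[j] * V[j]
    return out, W


class TestScaledDotAttention:
    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        Q, K, V = (rng.standard_normal((4, 8)) for _ in range(3))
        out, w = scaled_dot_attention(Tensor(Q), Tensor(K), Tensor(V))
        oracle_out, oracle_w = naive_attention(Q, K, V)
        np.testing.assert_allclose(out.data, oracle_out, atol=1e-10)
        np.testing.assert_allclose(w.data, oracle_w, atol=1e-10)

    def test_single_timepoint_passes_value_through(self):
        out, w = scaled_dot_attention(Tensor(np.ones((1, 4))),
                                      Tensor(np.ones((1, 4))),
                                      Tensor(np.arange(4.0)[None, :]))
        np.testing.assert_array_equal(w.data, [[1.0]])
        np.testing.assert_array_equal(out.data, np.arange(4.0)[None, :])

    def test_orthogonal_queries_give_uniform_weights(self):
        Q = np.zeros((3, 4))
        K = np.random.default_rng(1).standard_normal((5, 4))
        _, w = scaled_dot_attention(Tensor(Q), Tensor(K), Tensor(np.ones((5, 4))))
        np.testing.assert_allclose(w.data, 1.0 / 5.0, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        bad = np.full((2, 2), np.nan)
        with pytest.raises(ValueError, match="finite"):
            scaled_dot_attention(Tensor(bad), Tensor(bad), Tensor(bad))


class TestRelativeAttention:
    def test_zero_bias_reduces_to_plain_attention(self):
        rng = np.random.default_rng(2)
        Q, K, V = (rng.standard_normal((5, 6)) for _ in range(3))
        plain, _ = scaled_dot_attention(Tensor(Q), Tensor(K), Tensor(V))
        rel, _ = relative_attention(Tensor(Q), Tensor(K), Tensor(V),
                                    Tensor(np.zeros((5, 5))))
        np.testing.assert_allclose(rel.data, plain.data, atol=1e-14)

    def test_large_negative_offdiagonal_attends_to_self(self):
        rng = np.random.default_rng(3)
        Q, K, V = (rng.standard_normal((4, 6)) for _ in range(3))
        B = np.full((4, 4), -1e9)
        np.fill_diagonal(B, 0.0)
        out, w = relative_attention(Tensor(Q), Tensor(K), Tensor(V), Tensor(B))
        np.testing.assert_allclose(w.data, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(out.data, V, atol=1e-9)

    def test_random_bias_matches_naive_oracle(self):
        rng = np.random.default_rng(4)
        Q, K, V = (rng.standard_normal((4, 8)) for _ in range(3))
        B = rng.standard_normal((4, 4))
        out, _ = relative_attention(Tensor(Q), Tensor(K), Tensor(V), Tensor(B))
        oracle, _ = naive_attention(Q, K, V, B)
        np.testing.assert_allclose(out.data, oracle, atol=1e-10)

    def test_incompatible_bias_shape_rejected(self):
        rng = np.random.default_rng(5)
        Q = Tensor(rng.standard_normal((4, 8)))
        with pytest.raises(ValueError, match="incompatible"):
            relative_attention(Q, Q, Q, Tensor(np.zeros((3, 3))))


class TestMultiHeadAttention:
    def test_single_head_equals_scaled_dot_after_projections(self):
        rng = np.random.default_rng(6)
        mha = MultiHeadAttention(8, 1, rng)
        x = Tensor(rng.standard_normal((1, 5, 8)))
        out, _ = mha(x, x)
        q = x.data[0] @ mha.w_q.weight.data
        k = x.data[0] @ mha.w_k.weight.data
        v = x.data[0] @ mha.w_v.weight.data
        inner, _ = naive_attention(q, k, v)
        expected = inner @ mha.w_o.weight.data
        np.testing.assert_allclose(out.data[0], expected, atol=1e-10)

    def test_head_permutation_with_matched_output_blocks(self):
        rng = np.random.default_rng(7)
        mha = MultiHeadAttention(8, 2, rng)
        x = Tensor(rng.standard_normal((1, 6, 8)))
        base, _ = mha(x, x)
        # swap the two heads in Q/K/V columns and W_O rows
        perm = np.r_[4:8, 0:4]
        for lin in (mha.w_q, mha.w_k, mha.w_v):
            lin.weight.data = lin.weight.data[:, perm]
            lin.bias.data = lin.bias.data[perm]
        mha.w_o.weight.data = mha.w_o.weight.data[perm, :]
        permuted, _ = mha(x, x)
        np.testing.assert_allclose(permuted.data, base.data, atol=1e-10)

    def test_zero_value_projection_gives_output_bias_only(self):
        rng = np.random.default_rng(8)
        mha = MultiHeadAttention(8, 2, rng)
        mha.w_v.weight.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 4, 8)))
        out, _ = mha(x, x)
        np.testing.assert_allclose(
            out.data, np.broadcast_to(mha.w_o.bias.data, out.shape), atol=1e-12)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadAttention(10, 3, np.random.default_rng(0))


class TestTransformerLayer:
    @pytest.fixture
    def layer(self):
        cfg = ModelConfig(hidden_dim=16, n_heads=2, n_layers=1, dropout=0.2,
                          ffn_expansion=2, classifier_width=8, roi_dim=4,
                          ica_dim=2, conn_dim=6)
        rng = np.random.default_rng(9)
        return TransformerLayer(cfg, rng, None, np.random.default_rng(1))

    def test_eval_mode_is_deterministic(self, layer):
        layer.eval()
        x = Tensor(np.random.default_rng(0).standard_normal((1, 7, 16)))
        a, _ = layer(x)
        b, _ = layer(x)
        np.testing.assert_array_equal(a.data, b.data)

    def test_rows_have_layernorm_statistics(self, layer):
        layer.eval()
        x = Tensor(np.random.default_rng(1).standard_normal((1, 7, 16)))
        out, _ = layer(x)
        assert np.max(np.abs(out.data.mean(axis=-1))) < 1e-5
        assert np.max(np.abs(out.data.var(axis=-1) - 1.0)) < 1e-3

    def test_zero_ffn_reduces_to_layernorm_of_h1(self, layer):
        layer.eval()
        layer.ffn.lin1.weight.data[:] = 0.0
        layer.ffn.lin2.weight.data[:] = 0.0
        x = Tensor(np.random.default_rng(2).standard_normal((1, 5, 16)))
        out, w = layer(x)
        attn_out, _ = layer.attn(x, x)
        h1 = layer.ln1(x + attn_out)
        np.testing.assert_allclose(out.data, layer.ln2(h1).data, atol=1e-12)


class TestEncoder:
    def test_embedding_linearity_before_positions(self, tiny_model_config):
        rng = np.random.default_rng(0)
        enc = ModalityEncoder(8, tiny_model_config, rng, np.random.default_rng(0))
        x = rng.standard_normal((1, 6, 8))
        e = enc.embed(Tensor(x)).data
        e2 = enc.embed(Tensor(2.0 * x)).data
        np.testing.assert_allclose(
            e2 - enc.embed.bias.data, 2.0 * (e - enc.embed.bias.data), atol=1e-10)

    def test_states_shape_and_attention_rows_sum_to_one(self, tiny_model_config):
        enc = ModalityEncoder(28, tiny_model_config, np.random.default_rng(1),
                              np.random.default_rng(1))
        enc.eval()
        out = enc(Tensor(np.random.default_rng(2).standard_normal((2, 4, 28))))
        assert out.states.shape == (2, 4, 16)
        for maps in out.attention:
            assert np.all(maps >= 0)
            np.testing.assert_allclose(maps.sum(axis=-1), 1.0, atol=1e-5)

    def test_modalities_are_parameter_isolated(self, tiny_model_config):
        model = ImpactModel(tiny_model_config)
        streams = {
            "roi": np.random.default_rng(0).standard_normal((1, 6, 8)),
            "ica": np.random.default_rng(1).standard_normal((1, 6, 3)),
            "conn": np.random.default_rng(2).standard_normal((1, 3, 28)),
        }
        before = model(streams).encoders["ica"].states.data.copy()
        for p in model.encoders["roi"].parameters():
            p.data = p.data + 1.0
        after = model(streams).encoders["ica"].states.data
        np.testing.assert_array_equal(before, after)

    def test_zero_layer_encoder_reduces_to_embedding(self, tiny_model_config):
        from dataclasses import replace
        cfg = replace(tiny_model_config, n_layers=0)
        enc = ModalityEncoder(8, cfg, np.random.default_rng(0),
                              np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).standard_normal((1, 5, 8)))
        out = enc(x)
        np.testing.assert_array_equal(out.states.data, enc.embed_sequence(x).data)
        assert out.attention == []

    def test_empty_sequence_rejected(self, tiny_model_config):
        enc = ModalityEncoder(8, tiny_model_config, np.random.default_rng(0),
                              np.random.default_rng(0))
        with pytest.raises(ValueError, match="empty"):
            enc(Tensor(np.zeros((1, 0, 8))))


class TestFusion:
    def _states(self, cfg, rng):
        return {
            "roi": Tensor(rng.standard_normal((2, 5, cfg.hidden_dim))),
            "ica": Tensor(rng.standard_normal((2, 5, cfg.hidden_dim))),
            "conn": Tensor(rng.standard_normal((2, 3, cfg.hidden_dim))),
        }

    def test_equal_gate_logits_give_uniform_mixture(self, tiny_model_config):
        rng = np.random.default_rng(0)
        fusion = CrossModalFusion(tiny_model_config, rng)
        for lin in fusion.gates.values():
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0
        states = self._states(tiny_model_config, rng)
        out = fusion(states)
        np.testing.assert_allclose(out.gates.data, 1.0 / 3.0, atol=1e-12)
        pooled_roi = out.cross_states.data.mean(axis=1)
        expected = (pooled_roi + states["ica"].data.mean(axis=1)
                    + states["conn"].data.mean(axis=1)) / 3.0
        np.testing.assert_allclose(out.fused.data, expected, atol=1e-10)

    def test_dominant_gate_saturates(self, tiny_model_config):
        rng = np.random.default_rng(1)
        fusion = CrossModalFusion(tiny_model_config, rng)
        for m, lin in fusion.gates.items():
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 100.0 if m == "conn" else 0.0
        out = fusion(self._states(tiny_model_config, rng))
        conn_idx = out.gate_order.index("conn")
        assert np.all(out.gates.data[:, conn_idx] > 1 - 1e-6)

    def test_fused_vector_in_convex_hull(self, tiny_model_config):
        rng = np.random.default_rng(2)
        fusion = CrossModalFusion(tiny_model_config, rng)
        states = self._states(tiny_model_config, rng)
        out = fusion(states)
        np.testing.assert_allclose(out.gates.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(out.gates.data >= 0)
        pooled = np.stack([out.cross_states.data.mean(axis=1),
                           states["ica"].data.mean(axis=1),
                           states["conn"].data.mean(axis=1)], axis=0)
        lo = pooled.min(axis=0) - 1e-9
        hi = pooled.max(axis=0) + 1e-9
        assert np.all(out.fused.data >= lo) and np.all(out.fused.data <= hi)

    def test_width_mismatch_rejected(self, tiny_model_config):
        fusion = CrossModalFusion(tiny_model_config, np.random.default_rng(0))
        bad = self._states(tiny_model_config, np.random.default_rng(0))
        bad["roi"] = Tensor(np.zeros((2, 5, 7)))
        with pytest.raises(ValueError):
            fusion(bad)


class TestClassifierAndProbabilities:
    def test_softmax_closed_forms(self):
        np.testing.assert_allclose(softmax_probabilities(np.array([[0.0, 0.0]])),
                                   [[0.5, 0.5]])
        p = softmax_probabilities(np.array([[0.0, np.log(3.0)]]))
        assert p[0, 1] == pytest.approx(0.75)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((5, 2))
        np.testing.assert_allclose(softmax_probabilities(z),
                                   softmax_probabilities(z + 123.4), atol=1e-12)

    def test_extreme_logits_do_not_overflow(self):
        p = softmax_probabilities(np.array([[1000.0, -1000.0]]))
        assert np.all(np.isfinite(p))
        assert p[0, 0] == pytest.approx(1.0)


class TestInitialization:
    def test_biases_exactly_zero_and_seed_determinism(self, tiny_model_config):
        a = ImpactModel(tiny_model_config)
        b = ImpactModel(tiny_model_config)
        for (name, pa), (_, pb) in zip(sorted(a.named_parameters()),
                                       sorted(b.named_parameters())):
            np.testing.assert_array_equal(pa.data, pb.data)
            if name.endswith("bias") or name.endswith("beta"):
                assert np.all(pa.data == 0.0), name

    def test_attention_projection_scaled_by_sqrt_heads(self):
        cfg = ModelConfig()          # full-size: stable sample moments
        model = ImpactModel(cfg)
        w = model.encoders["roi"].layers[0].attn.w_q.weight.data
        expected = np.sqrt(2.0 / 256) / np.sqrt(8)
        assert w.std() == pytest.approx(expected, rel=0.1)

    def test_frozen_tensors_leave_the_count(self, tiny_model_config):
        model = ImpactModel(tiny_model_config)
        full = count_parameters(model)
        p = model.classifier.out.weight
        p.trainable = False
        assert count_parameters(model) == full - p.size


class TestBudgetAndMemory:
    def test_default_model_has_9_34_million_parameters(self):
        model = ImpactModel(ModelConfig())
        assert round(count_parameters(model) / 1e6, 2) == 9.34

    def test_memory_estimate_formula(self):
        assert estimate_fusion_memory(1, 1, 1, 1, 1, 1) == 5
        base = estimate_fusion_memory(132, 4, 48, 5, 1128, 256)
        assert base == 132 * (48 + 5) + 4 * 1128 + 2 * 132 * 256
        # linear in T for the T-dependent terms
        doubled = estimate_fusion_memory(264, 4, 48, 5, 1128, 256)
        assert doubled - 4 * 1128 == 2 * (base - 4 * 1128)
        with pytest.raises(ValueError):
            estimate_fusion_memory(0, 1, 1, 1, 1, 1)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(hidden_dim=10, n_heads=3)
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(dropout=1.0)


class TestForwardContract:
    def test_eval_forward_is_deterministic_with_dropout_configured(self):
        cfg = ModelConfig(hidden_dim=16, n_heads=2, n_layers=1, dropout=0.3,
                          ffn_expansion=2, classifier_width=8, roi_dim=4,
                          ica_dim=2, conn_dim=6)
        model = ImpactModel(cfg)
        streams = {"roi": np.random.default_rng(0).standard_normal((2, 5, 4)),
                   "ica": np.random.default_rng(1).standard_normal((2, 5, 2)),
                   "conn": np.random.default_rng(2).standard_normal((2, 2, 6))}
        a = model(streams).output.probabilities
        b = model(streams).output.probabilities
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-9)

    def test_missing_stream_rejected(self, tiny_model_config):
        model = ImpactModel(tiny_model_config)
        with pytest.raises(ValueError, match="missing input stream"):
            model({"roi": np.zeros((1, 4, 8))})

    def test_positional_encoding_shape(self):
        pe = sinusoidal_positions(10, 16)
        assert pe.shape == (10, 16)
        np.testing.assert_allclose(pe[0, 0::2], 0.0, atol=1e-12)   # sin(0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0, atol=1e-12)   # cos(0)
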
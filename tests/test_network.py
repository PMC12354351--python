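"""Network algebraic limits, shape contracts and degenerate equivalences."""

import math

import numpy as np
import pytest

import tcmrec as tr
from tcmrec.autodiff import Tensor
from tcmrec.network import (MetaAttentionNet, ModelConfig, degenerate_numpy_forward,
                            feed_forward, merge_task_scores, meta_unit,
                            scaled_dot_attention, senet_fuse)

SIZES = {"n_symptom_ids": 12, "n_profile_ids": 6, "n_scene_ids": 4,
         "dense_dim": 11, "task_vocab_sizes": [3, 2, 4, 3, 2]}


def tiny_cfg(**kw):
    base = dict(embed_dim=8, n_heads=2, expert_hidden=10, expert_dim=6,
                tower_hidden=6, tower_depth=2, scene_dim=4, meta_hidden=4,
                senet_hidden=4, mlp_hidden=(12,), seed=1)
    base.update(kw)
    return ModelConfig(**base)


def rand_batch(rng, B=4, T=5, wide_sizes=SIZES["task_vocab_sizes"]):
    sym = rng.integers(0, SIZES["n_symptom_ids"], size=(B, T))
    sym[:, 0] = np.maximum(sym[:, 0], 1)  # at least one real token
    return {
        "sym_ids": sym,
        "prof_ids": rng.integers(1, SIZES["n_profile_ids"], size=(B, 5)),
        "scene_ids": rng.integers(0, SIZES["n_scene_ids"], size=B),
        "dense": rng.normal(size=(B, SIZES["dense_dim"])),
        "wide": [rng.random((B, v)) for v in wide_sizes],
        "case_ids": [str(i) for i in range(B)],
    }


class TestScaledDotAttention:
    def test_zero_scores_give_column_mean(self):
        rng = np.random.default_rng(0)
        V = Tensor(rng.normal(size=(3, 4)))
        Q = Tensor(np.zeros((2, 5)))
        K = Tensor(np.zeros((3, 5)))
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out.data, V.data.mean(axis=0))

    def test_single_key_returns_v_exactly(self):
        rng = np.random.default_rng(1)
        Q = Tensor(rng.normal(size=(4, 3)))
        K = Tensor(rng.normal(size=(1, 3)))
        V = Tensor(rng.normal(size=(1, 6)))
        out = scaled_dot_attention(Q, K, V)
        assert np.array_equal(out.data, np.repeat(V.data, 4, axis=0))

    def test_matches_two_loop_oracle(self):
        rng = np.random.default_rng(2)
        Q, K, V = (rng.normal(size=(3, 4)) for _ in range(3))
        out = scaled_dot_attention(Tensor(Q), Tensor(K), Tensor(V)).data
        d = Q.shape[-1]
        expect = np.zeros((3, 4))
        for i in range(3):
            w = np.array([np.dot(Q[i], K[j]) / math.sqrt(d) for j in range(3)])
            w = np.exp(w - w.max())
            w /= w.sum()
            for j in range(3):
                expect[i] += w[j] * V[j]
        assert np.allclose(out, expect, atol=1e-6)

    def test_rows_sum_to_one_via_constant_values(self):
        rng = np.random.default_rng(3)
        Q, K = Tensor(rng.normal(size=(5, 4))), Tensor(rng.normal(size=(6, 4)))
        ones = Tensor(np.ones((6, 1)))
        assert np.allclose(scaled_dot_attention(Q, K, ones).data, 1.0, atol=1e-9)

    def test_zero_dim_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(Tensor(np.zeros((2, 0))),
                                 Tensor(np.zeros((2, 0))),
                                 Tensor(np.zeros((2, 2))))


class TestMultiHead:
    def test_single_head_reduces_to_sdpa(self):
        cfg = tiny_cfg(n_heads=1)
        net = MetaAttentionNet(cfg, SIZES)
        rng = np.random.default_rng(4)
        X = Tensor(rng.normal(size=(2, 5, cfg.embed_dim)))
        mask = np.ones((2, 5))
        got = net.multi_head_block(X, mask).data
        P = net.params()
        Q, K, V = X.data @ P["Wq"].data, X.data @ P["Wk"].data, X.data @ P["Wv"].data
        expect = np.stack([
            scaled_dot_attention(Tensor(Q[b]), Tensor(K[b]), Tensor(V[b])).data
            for b in range(2)]) @ P["WH"].data
        assert np.allclose(got, expect, atol=1e-9)

    def test_key_value_permutation_invariance(self):
        cfg = tiny_cfg()
        net = MetaAttentionNet(cfg, SIZES)
        rng = np.random.default_rng(5)
        X = rng.normal(size=(1, 6, cfg.embed_dim))
        mask = np.ones((1, 6))
        base = net.multi_head_block(Tensor(X), mask).data
        # permuting tokens permutes outputs correspondingly (self-attention)
        perm = rng.permutation(6)
        permuted = net.multi_head_block(Tensor(X[:, perm]), mask).data
        assert np.allclose(permuted, base[:, perm], atol=1e-9)

    def test_output_shape(self):
        cfg = tiny_cfg()
        net = MetaAttentionNet(cfg, SIZES)
        X = Tensor(np.zeros((3, 7, cfg.embed_dim)))
        assert net.multi_head_block(X, np.ones((3, 7))).shape == (3, 7, cfg.embed_dim)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divide"):
            tiny_cfg(embed_dim=8, n_heads=3)


class TestFeedForward:
    def test_zero_weights_give_bias(self):
        x = Tensor(np.random.default_rng(6).normal(size=(4, 3)))
        W1, b1 = Tensor(np.zeros((3, 5))), Tensor(np.zeros(5))
        W2, b2 = Tensor(np.zeros((5, 3))), Tensor(np.arange(3.0))
        out = feed_forward(x, W1, b1, W2, b2)
        assert np.array_equal(out.data, np.tile(np.arange(3.0), (4, 1)))

    def test_dead_relu_zone(self):
        x = Tensor(np.full((2, 3), -5.0))
        W1, b1 = Tensor(np.eye(3)), Tensor(np.zeros(3))
        W2, b2 = Tensor(np.eye(3)), Tensor(np.ones(3))
        # (xW1+b1)W2 = x < 0 everywhere -> outer ReLU kills it -> b2
        assert np.array_equal(feed_forward(x, W1, b1, W2, b2).data,
                              np.ones((2, 3)))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(3, 4))
        W1, b1 = rng.normal(size=(4, 6)), rng.normal(size=6)
        W2, b2 = rng.normal(size=(6, 4)), rng.normal(size=4)
        got = feed_forward(Tensor(x), Tensor(W1), Tensor(b1),
                           Tensor(W2), Tensor(b2)).data
        expect = np.zeros((3, 4))
        for i in range(3):
            h = np.array([x[i] @ W1[:, k] + b1[k] for k in range(6)])
            expect[i] = np.maximum(np.array([h @ W2[:, m] for m in range(4)]), 0) + b2
        assert np.allclose(got, expect, atol=1e-6)


class TestSenet:
    def test_zero_mlp_gate_is_half(self):
        groups = [Tensor(np.ones((2, 3))), Tensor(np.zeros((2, 2)))]
        W1, b1 = Tensor(np.zeros((2, 4))), Tensor(np.zeros(4))
        W2, b2 = Tensor(np.zeros((4, 5))), Tensor(np.zeros(5))
        out = senet_fuse(groups, W1, b1, W2, b2, mode="additive")
        x = np.concatenate([np.ones((2, 3)), np.zeros((2, 2))], axis=1)
        assert np.allclose(out.data, x + 0.5)

    def test_multiplicative_identity_limit(self):
        groups = [Tensor(np.random.default_rng(8).normal(size=(2, 4)))]
        W1, b1 = Tensor(np.zeros((1, 3))), Tensor(np.zeros(3))
        W2 = Tensor(np.zeros((3, 4)))
        b2 = Tensor(np.full(4, 30.0))  # sigmoid saturates to ~1
        out = senet_fuse(groups, W1, b1, W2, b2, mode="multiplicative")
        assert np.allclose(out.data, groups[0].data, atol=1e-9)

    def test_gate_in_open_interval(self):
        rng = np.random.default_rng(9)
        groups = [Tensor(rng.normal(size=(5, 3))), Tensor(rng.normal(size=(5, 4)))]
        W1, b1 = Tensor(rng.normal(size=(2, 4))), Tensor(rng.normal(size=4))
        W2, b2 = Tensor(rng.normal(size=(4, 7))), Tensor(rng.normal(size=7))
        add = senet_fuse(groups, W1, b1, W2, b2, mode="additive").data
        x = np.concatenate([g.data for g in groups], axis=1)
        gate = add - x
        assert np.all(gate > 0) and np.all(gate < 1)


class TestMetaUnit:
    def test_zero_generator_is_fixed_dense(self):
        rng = np.random.default_rng(10)
        in_d, out_d, sd = 4, 3, 5
        W0 = rng.normal(size=(out_d, in_d))
        b0 = rng.normal(size=out_d)
        Wg = Tensor(np.zeros((sd, in_d * out_d + out_d)))
        bg = Tensor(np.concatenate([W0.ravel(), b0]))
        x = rng.normal(size=(6, in_d))
        for scene in (np.zeros(sd), rng.normal(size=sd)):
            y = meta_unit(Tensor(x), Tensor(scene), Wg, bg, in_d, out_d)
            assert np.array_equal(y.data, np.maximum(x @ W0.T + b0, 0))

    def test_distinct_scenes_differ(self):
        rng = np.random.default_rng(11)
        in_d, out_d, sd = 4, 3, 5
        Wg = Tensor(rng.normal(size=(sd, in_d * out_d + out_d)))
        bg = Tensor(rng.normal(size=in_d * out_d + out_d))
        x = Tensor(rng.normal(size=(2, in_d)))
        y1 = meta_unit(x, Tensor(rng.normal(size=sd)), Wg, bg, in_d, out_d)
        y2 = meta_unit(x, Tensor(rng.normal(size=sd)), Wg, bg, in_d, out_d)
        assert not np.allclose(y1.data, y2.data)

    def test_zero_input_gives_relu_bias(self):
        rng = np.random.default_rng(12)
        in_d, out_d, sd = 3, 4, 2
        Wg = Tensor(rng.normal(size=(sd, in_d * out_d + out_d)))
        bg = Tensor(rng.normal(size=in_d * out_d + out_d))
        scene = rng.normal(size=(2, sd))
        y = meta_unit(Tensor(np.zeros((2, in_d))), Tensor(scene), Wg, bg, in_d, out_d)
        gen = scene @ Wg.data + bg.data
        assert np.allclose(y.data, np.maximum(gen[:, in_d * out_d:], 0))

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="generator"):
            meta_unit(Tensor(np.zeros((1, 3))), Tensor(np.zeros(2)),
                      Tensor(np.zeros((2, 7))), Tensor(np.zeros(7)), 3, 4)


class TestMetaAttention:
    def test_identical_experts_uniform_gate(self):
        cfg = tiny_cfg()
        net = MetaAttentionNet(cfg, SIZES)
        E = Tensor(np.random.default_rng(13).normal(size=(3, cfg.expert_dim)))
        scene = Tensor(np.zeros(cfg.scene_dim))
        alpha = net.meta_attention([E, E, E], scene, task=0)
        assert np.allclose(alpha.data, 1 / 3, atol=1e-12)

    def test_singleton_gate_is_one(self):
        cfg = tiny_cfg()
        net = MetaAttentionNet(cfg, SIZES)
        E = Tensor(np.random.default_rng(14).normal(size=(2, cfg.expert_dim)))
        alpha = net.meta_attention([E], Tensor(np.zeros(cfg.scene_dim)), task=1)
        assert np.allclose(alpha.data, 1.0)

    def test_gates_normalized_over_random_inputs(self):
        cfg = tiny_cfg()
        net = MetaAttentionNet(cfg, SIZES)
        rng = np.random.default_rng(15)
        for _ in range(10):
            Es = [Tensor(rng.normal(size=(4, cfg.expert_dim))) for _ in range(4)]
            alpha = net.meta_attention(Es, Tensor(rng.normal(size=cfg.scene_dim)), 2)
            assert np.allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)


class TestFullModel:
    def test_forward_shapes_and_softmax_merge(self):
        cfg = tiny_cfg()
        net = MetaAttentionNet(cfg, SIZES)
        batch = rand_batch(np.random.default_rng(16))
        logits = net.forward(batch)
        assert [z.shape[1] for z in logits] == SIZES["task_vocab_sizes"]
        merged, ids = merge_task_scores([z.data for z in logits],
                                        [[1, 2, 3], [4, 5], [6, 7, 8, 9],
                                         [10, 11, 12], [13, 14]], merge="softmax")
        sums = np.add.reduceat(merged, [0, 3, 5, 9, 12], axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert len(ids) == merged.shape[1]

    def test_forward_deterministic(self):
        cfg = tiny_cfg()
        batch = rand_batch(np.random.default_rng(17))
        a = MetaAttentionNet(cfg, SIZES).forward(batch)
        b = MetaAttentionNet(cfg, SIZES).forward(batch)
        for za, zb in zip(a, b):
            assert np.array_equal(za.data, zb.data)

    def test_scene_independence_after_zeroing_generators(self):
        cfg = tiny_cfg(scene_field="department")
        net = MetaAttentionNet(cfg, SIZES)
        net.zero_meta_generators()
        batch = rand_batch(np.random.default_rng(18))
        base = [z.data for z in net.forward(batch)]
        other = dict(batch)
        other["meta_scene_ids"] = (batch["scene_ids"] + 1) % SIZES["n_scene_ids"]
        alt = [z.data for z in net.forward(other)]
        for za, zb in zip(base, alt):
            assert np.array_equal(za, zb)

    def test_degenerate_limit_matches_independent_numpy_model(self):
        cfg = tiny_cfg()
        net = MetaAttentionNet(cfg, SIZES)
        net.zero_meta_generators()
        batch = rand_batch(np.random.default_rng(19))
        ours = [z.data for z in net.forward(batch)]
        theirs = degenerate_numpy_forward(net, batch)
        for za, zb in zip(ours, theirs):
            assert np.allclose(za, zb, atol=1e-10)

    def test_stage_mismatch_names_field(self):
        cfg = tiny_cfg()
        net = MetaAttentionNet(cfg, SIZES)
        batch = rand_batch(np.random.default_rng(20))
        batch["wide"] = None
        with pytest.raises(ValueError, match="wide"):
            net.forward(batch)


class TestBaselines:
    @pytest.mark.parametrize("kind", ["mlp", "mmoe"])
    def test_same_output_shapes_as_main_model(self, kind):
        cfg = tiny_cfg()
        net = tr.build_baseline(kind, cfg, SIZES)
        batch = rand_batch(np.random.default_rng(21))
        logits = net.forward(batch)
        assert [z.shape[1] for z in logits] == SIZES["task_vocab_sizes"]

    def test_mlp_zero_hidden_is_linear(self):
        cfg = tiny_cfg(mlp_hidden=())
        net = tr.build_baseline("mlp", cfg, SIZES)
        batch = rand_batch(np.random.default_rng(22))
        batch2 = dict(batch)
        batch2["dense"] = batch["dense"] * 2.0
        # with no hidden layer the head is affine in the encoded input;
        # doubling dense features moves logits by the dense projection only
        z1 = net.forward(batch)[0].data
        z2 = net.forward(batch2)[0].data
        assert z1.shape == z2.shape  # smoke: structure holds without hidden stack

    def test_mmoe_single_expert_gate_is_one(self):
        cfg = tiny_cfg(n_shared_experts=1, n_unique_experts=0)
        net = tr.build_baseline("mmoe", cfg, SIZES)
        assert net.n_experts == 1
        batch = rand_batch(np.random.default_rng(23))
        P = net.params()
        x = net._encode(batch)
        gate = (x @ P["gate0_W"] + P["gate0_b"]).softmax(axis=1)
        assert np.allclose(gate.data, 1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            tr.build_baseline("textcnn", tiny_cfg(), SIZES)


class TestCheckpoint:
    def test_round_trip_bitwise(self, tmp_path):
        cfg = tiny_cfg()
        net = MetaAttentionNet(cfg, SIZES)
        tr.save_checkpoint(net, tmp_path / "ck")
        back = tr.load_checkpoint(tmp_path / "ck")
        for k, p in net.params().items():
            assert np.array_equal(p.data, back.params()[k].data)
        batch = rand_batch(np.random.default_rng(24))
        for za, zb in zip(net.forward(batch), back.forward(batch)):
            assert np.array_equal(za.data, zb.data)

    def test_schema_mismatch_rejected(self, tmp_path):
        import json
        net = MetaAttentionNet(tiny_cfg(), SIZES)
        tr.save_checkpoint(net, tmp_path / "ck")
        m = json.loads((tmp_path / "ck" / "manifest.json").read_text())
        m["schema_version"] = "bogus"
        (tmp_path / "ck" / "manifest.json").write_text(json.dumps(m))
        with pytest.raises(ValueError, match="schema"):
            tr.load_checkpoint(tmp_path / "ck")


def test_embedded_batch_concat_length():
    cfg = tiny_cfg()
    net = MetaAttentionNet(cfg, SIZES)
    batch = rand_batch(np.random.default_rng(25))
    eb = net.embed_batch(batch)
    assert eb.concatenated.shape[1] == (2 * cfg.embed_dim + cfg.scene_dim
                                        + SIZES["dense_dim"])
    # two records differing only in scene id share e_u but not e_s
    b2 = dict(batch)
    b2["scene_ids"] = (batch["scene_ids"] + 1) % SIZES["n_scene_ids"]
    eb2 = net.embed_batch(b2)
    assert np.array_equal(eb.e_u.data, eb2.e_u.data)
    assert not np.array_equal(eb.e_s.data, eb2.e_s.data)
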
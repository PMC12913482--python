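"""Architecture contracts: shapes, attention semantics, invariances."""

import numpy as np
import pytest

from siamphage._autodiff import Tensor
from siamphage.embedding import random_table
from siamphage.errors import ConfigurationError, ContractError
from siamphage.model import (DualTowerNetwork, MatchProbability, ModelConfig,
                             attention_head, genome_token_ids, load_checkpoint,
                             save_checkpoint, _softmax_np)


class TestShapeContracts:
    def test_full_architecture_shapes(self, full_network, full_config, make_genome):
        """2000-bp segments -> 1998x64 embeddings -> 256-d tower vectors ->
        512-d fused vector -> width-4096 classifier -> 2-class simplex."""
        net, cfg = full_network, full_config
        phage = make_genome(4001, role="phage", id="p")
        ids = genome_token_ids(phage, cfg)
        assert ids.shape == (3, 1998)  # ceil(4001/2000) segments
        x = net.embed_ids(ids)
        assert x.shape == (3, 1, 1998, 64)
        seg_vecs = net.cnn_tower_forward(x, "phage")
        assert seg_vecs.shape == (3, 256)
        c_phage = net.transformer_encode(seg_vecs, "phage")
        assert c_phage.shape == (256,)
        assert net.fc1.weight.shape == (512, 4096)
        assert net.fc2.weight.shape == (4096, 2)
        logits = net.fuse_and_classify(c_phage, c_phage)
        p = _softmax_np(logits.data[0])
        assert p.shape == (2,) and abs(p.sum() - 1.0) < 1e-6 and np.all(p >= 0)

    def test_classifier_parameter_count(self, full_network):
        n = (full_network.fc1.weight.data.size + full_network.fc1.bias.data.size
             + full_network.fc2.weight.data.size + full_network.fc2.bias.data.size)
        assert n == 512 * 4096 + 4096 + 4096 * 2 + 2

    def test_tower_maps_different_lengths_to_fixed_width(self, full_network):
        """Global average pooling makes the tower output 256-d regardless of
        the segment's spatial extent (e.g. a 1000-bp segment config)."""
        rng = np.random.default_rng(0)
        for n_tokens in (998, 1998):
            x = rng.normal(size=(1, 1, n_tokens, 64))
            out = full_network.cnn_tower_forward(x, "host")
            assert out.shape == (1, 256)

    def test_eval_mode_is_deterministic(self, tiny_network, make_genome):
        phage = make_genome(95, role="phage", id="p")
        host = make_genome(130, role="host", id="h")
        p1 = tiny_network.forward_pair(phage, host)
        p2 = tiny_network.forward_pair(phage, host)
        assert p1 == p2

    def test_bad_input_shape_rejected(self, tiny_network):
        with pytest.raises(ContractError):
            tiny_network.cnn_tower_forward(np.zeros((1, 2, 10, 8)), "phage")

    def test_head_dim_times_heads_must_equal_tower_dim(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(tower_dim=256, n_heads=4, head_dim=32)

    def test_match_probability_invariants(self):
        with pytest.raises(ContractError):
            MatchProbability(0.7, 0.7)
        p = MatchProbability(0.3, 0.7)
        assert p.label == 1


class TestAttention:
    def test_rows_of_attention_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        q, k, v = (rng.normal(size=(5, 8)) for _ in range(3))
        _, w = attention_head(q, k, v, d_k=8, return_weights=True)
        assert np.allclose(w.sum(axis=-1), 1.0)
        assert np.all(w >= 0)

    def test_single_position_passthrough(self):
        rng = np.random.default_rng(1)
        q, k, v = (rng.normal(size=(1, 8)) for _ in range(3))
        out = attention_head(q, k, v, d_k=8)
        assert np.allclose(out, v)

    def test_matches_explicit_loop_oracle(self):
        """Vectorised scaled-dot-product attention equals a brute-force
        computation with explicit Python loops, on random 3x64 inputs."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            q, k, v = (rng.normal(size=(3, 64)) for _ in range(3))
            out = attention_head(q, k, v, d_k=64)
            # explicit-loop oracle
            expected = np.zeros((3, 64))
            for i in range(3):
                logits = [sum(q[i, d] * k[j, d] for d in range(64)) / np.sqrt(64)
                          for j in range(3)]
                m = max(logits)
                weights = [np.exp(l - m) for l in logits]
                z = sum(weights)
                for j in range(3):
                    for d in range(64):
                        expected[i, d] += (weights[j] / z) * v[j, d]
            assert np.abs(out - expected).max() < 1e-5

    def test_masked_keys_get_zero_weight(self):
        rng = np.random.default_rng(3)
        q, k, v = (rng.normal(size=(4, 8)) for _ in range(3))
        mask = np.array([True, True, False, True])
        _, w = attention_head(q, k, v, d_k=8, mask=mask, return_weights=True)
        assert np.all(w[:, 2] < 1e-6)
        assert np.allclose(w.sum(axis=-1), 1.0)

    def test_nonpositive_dk_rejected(self):
        with pytest.raises(ConfigurationError):
            attention_head(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)),
                           d_k=0)


class TestEncoderInvariances:
    @pytest.mark.parametrize("case", range(20))
    def test_cls_output_invariant_to_segment_permutation(self, full_network,
                                                         case):
        """Without positional encoding the segment set is unordered: permuting
        segment vectors must leave the CLS representation unchanged."""
        rng = np.random.default_rng(100 + case)
        c = int(rng.integers(2, 9))
        vecs = rng.normal(size=(c, 256))
        perm = rng.permutation(c)
        out1 = full_network.transformer_encode(vecs, "phage").data
        out2 = full_network.transformer_encode(vecs[perm], "phage").data
        assert np.abs(out1 - out2).max() < 1e-5

    @pytest.mark.parametrize("case", range(20))
    def test_cls_output_unchanged_by_masked_padding(self, full_network, case):
        rng = np.random.default_rng(200 + case)
        c = int(rng.integers(1, 9))
        vecs = rng.normal(size=(c, 256))
        padded = np.vstack([vecs, rng.normal(size=(3, 256))])
        mask = np.array([True] * c + [False] * 3)
        out1 = full_network.transformer_encode(vecs, "phage").data
        out2 = full_network.transformer_encode(padded, "phage", mask=mask).data
        assert np.abs(out1 - out2).max() < 1e-5

    def test_positional_encoding_breaks_permutation_invariance(self):
        cfg = ModelConfig(segment_length=40, k=3, d_embed=8, tower_dim=12,
                          n_transformer_layers=1, n_heads=2, mlp_hidden=16,
                          conv_channels=(4, 8, 12), use_positional_encoding=True,
                          dtype="float64")
        net = DualTowerNetwork(cfg, seed=0, embedding=random_table(3, 8, 0))
        rng = np.random.default_rng(0)
        vecs = rng.normal(size=(4, 12))
        out1 = net.transformer_encode(vecs, "phage").data
        out2 = net.transformer_encode(vecs[::-1].copy(), "phage").data
        assert np.abs(out1 - out2).max() > 1e-6

    def test_empty_or_fully_masked_input_rejected(self, full_network):
        with pytest.raises(ContractError):
            full_network.transformer_encode(np.zeros((0, 256)), "phage")
        with pytest.raises(ContractError):
            full_network.transformer_encode(np.zeros((2, 256)), "phage",
                                            mask=np.array([False, False]))

    def test_internal_sequence_length_is_segments_plus_cls(self, full_network):
        """c=5 segments -> CLS + 5 rows inside the encoder, 256-d output."""
        rng = np.random.default_rng(4)
        vecs = rng.normal(size=(5, 256))
        out = full_network.transformer_encode(vecs, "host")
        assert out.shape == (256,)


class TestEndToEnd:
    def test_towers_have_independent_parameters(self, tiny_network, make_genome):
        """Swapping which genome feeds which tower changes the output
        (pseudo-Siamese: same architecture, independent weights)."""
        a = make_genome(95, role="phage", id="a")
        b = make_genome(130, role="host", id="b")
        p_ab = tiny_network.forward_pair(a, b)
        a2 = type(a)(id="a", sequence=b.sequence, role="phage")
        b2 = type(b)(id="b", sequence=a.sequence, role="host")
        p_ba = tiny_network.forward_pair(a2, b2)
        assert abs(p_ab.p_match - p_ba.p_match) > 1e-9

    def test_shared_tower_variant_is_symmetric_in_encoders(self, make_genome):
        cfg = ModelConfig(segment_length=40, k=3, d_embed=8, tower_dim=12,
                          n_transformer_layers=1, n_heads=2, mlp_hidden=16,
                          conv_channels=(4, 8, 12), share_tower_weights=True,
                          dtype="float64")
        net = DualTowerNetwork(cfg, seed=0, embedding=random_table(3, 8, 0))
        g = make_genome(80, id="g")
        ids = genome_token_ids(g, cfg)
        cp = net.encode_genome(ids, "phage").data
        ch = net.encode_genome(ids, "host").data
        assert np.allclose(cp, ch)

    def test_no_transformer_ablation_uses_mean_of_segments(self, make_genome):
        cfg = ModelConfig(segment_length=40, k=3, d_embed=8, tower_dim=12,
                          n_transformer_layers=1, n_heads=2, mlp_hidden=16,
                          conv_channels=(4, 8, 12), use_transformer=False,
                          dtype="float64")
        net = DualTowerNetwork(cfg, seed=0, embedding=random_table(3, 8, 0))
        g = make_genome(120, id="g")
        ids = genome_token_ids(g, cfg)
        segs = net.cnn_tower_forward(net.embed_ids(ids), "phage")
        manual = segs.data.mean(axis=0)
        assert np.allclose(net.encode_genome(ids, "phage").data, manual)

    def test_trainable_embedding_ablation_has_embedding_parameter(self):
        cfg = ModelConfig(segment_length=40, k=3, d_embed=8, tower_dim=12,
                          n_transformer_layers=1, n_heads=2, mlp_hidden=16,
                          conv_channels=(4, 8, 12),
                          use_pretrained_embedding=False, dtype="float64")
        net = DualTowerNetwork(cfg, seed=0)
        assert net.embed_param is not None
        assert net.embed_param.data.shape == (65, 8)
        assert np.all(net.embed_param.data[-1] == 0.0)

    def test_batch_logits_match_single_pair_logits(self, tiny_network,
                                                   make_genome):
        cfg = tiny_network.cfg
        pairs = [(genome_token_ids(make_genome(95, id=f"p{i}"), cfg),
                  genome_token_ids(make_genome(120, id=f"h{i}"), cfg))
                 for i in range(3)]
        batch = tiny_network.batch_logits([p for p, _ in pairs],
                                          [h for _, h in pairs])
        for i, (pid, hid) in enumerate(pairs):
            single = tiny_network.pair_logits(pid, hid)
            assert np.abs(batch.data[i] - single.data[0]).max() < 1e-9

    def test_checkpoint_round_trip(self, tmp_path, tiny_network, tiny_config,
                                   make_genome):
        table = random_table(tiny_config.k, tiny_config.d_embed, seed=7)
        phage = make_genome(95, role="phage", id="p")
        host = make_genome(130, role="host", id="h")
        before = tiny_network.forward_pair(phage, host)
        save_checkpoint(tiny_network, tmp_path / "ck.npz", seed=7)
        restored, header = load_checkpoint(tmp_path / "ck.npz", embedding=table)
        after = restored.forward_pair(phage, host)
        assert header["config"]["tower_dim"] == tiny_config.tower_dim
        assert abs(before.p_match - after.p_match) < 1e-12
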
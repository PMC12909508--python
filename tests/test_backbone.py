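"""Backbone: layer-graph arithmetic, block semantics, detection head."""

import numpy as np
import pytest

from epilobe import backbone as bb
from epilobe import nn

TINY = bb.BackboneConfig(input_shape=(1, 32, 32), scale=0.0625, base_blocks=(1, 1, 1, 1))


@pytest.fixture(scope="module")
def tiny_model():
    return bb.build_backbone(TINY)


class TestLayerGraph:
    def test_reference_graph_has_182_layers(self):
        assert len(bb.layer_graph(bb.REFERENCE_CONFIG)) == 182

    def test_appended_head_is_ten_layers(self):
        names = bb.layer_graph()
        assert names[-10:] == [
            "incres_block_1",
            "incres_block_2",
            "regnet_refine",
            "conv3x3_a",
            "conv3x3_b",
            "conv3x3_c",
            "conv3x3_d",
            "global_avg_pool",
            "fc",
            "softmax",
        ]

    def test_base_minus_head_is_172(self):
        assert len(bb.layer_graph()) - 10 == 172  # 177 - 5 removed


class TestForward:
    def test_scaled_forward_finite_and_shaped(self, tiny_model):
        x = np.random.default_rng(0).standard_normal((3, 1, 32, 32)).astype(np.float32)
        feats, logits = tiny_model.forward(x)
        assert feats.data.shape == (3, tiny_model.feature_dim)
        assert logits.data.shape == (3, 2)
        assert np.all(np.isfinite(logits.data))

    def test_wrong_channel_count_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((1, 3, 32, 32), np.float32))

    def test_eval_mode_deterministic(self, tiny_model):
        x = np.random.default_rng(1).standard_normal((2, 1, 32, 32)).astype(np.float32)
        _, a = tiny_model.forward(x, training=False)
        _, b = tiny_model.forward(x, training=False)
        assert np.array_equal(a.data, b.data)

    def test_gradients_reach_first_conv(self, tiny_model):
        x = np.random.default_rng(2).standard_normal((4, 1, 32, 32)).astype(np.float32)
        for p in tiny_model.params():
            p.grad = None
        _, logits = tiny_model.forward(x, training=True)
        nn.softmax_cross_entropy(logits, np.array([0, 1, 0, 1])).backward()
        g = tiny_model.stem.w.grad
        assert g is not None and np.all(np.isfinite(g)) and np.linalg.norm(g) > 0


class TestInceptionResidual:
    def test_branch_concat_channel_arithmetic(self):
        rng = np.random.default_rng(0)
        block = bb.InceptionResidual(rng, ci=6, f=4)
        x = nn.Tensor(rng.standard_normal((2, 6, 8, 8)).astype(np.float32))
        out = block.inception(x)
        assert out.data.shape == (2, 3 * 4 + 6, 8, 8)  # 1x1+3x3+5x5 branches + pool

    def test_spatial_dims_preserved(self):
        rng = np.random.default_rng(1)
        block = bb.InceptionResidual(rng, ci=3, f=2)
        x = nn.Tensor(rng.standard_normal((1, 3, 9, 9)).astype(np.float32))
        assert block(x, training=False).data.shape[2:] == (9, 9)

    def test_zero_weights_keep_pool_branch_only(self):
        rng = np.random.default_rng(2)
        block = bb.InceptionResidual(rng, ci=2, f=3)
        for conv in (block.br1, block.br3, block.br5):
            conv.w.data[:] = 0
            conv.b.data[:] = 0
        x_data = np.abs(rng.standard_normal((1, 2, 6, 6))).astype(np.float32)
        out = block.inception(nn.Tensor(x_data))
        assert np.allclose(out.data[:, :9], 0.0)
        pool = nn.maxpool2d(nn.Tensor(x_data), 3, 1).data
        assert np.allclose(out.data[:, 9:], pool)

    def test_residual_skip_is_wired(self):
        rng = np.random.default_rng(3)
        block = bb.InceptionResidual(rng, ci=4, f=2)
        x = nn.Tensor(np.abs(rng.standard_normal((1, 4, 7, 7))).astype(np.float32))
        with_skip = block(x, training=False).data
        without_skip = nn.relu(block.inception(x)).data
        assert not np.allclose(with_skip, without_skip)


class TestRegNetBlock:
    def test_zero_branch_passes_input_through(self):
        rng = np.random.default_rng(4)
        block = bb.RegNetBlock(rng, ci=3, width=2)
        block.expand.w.data[:] = 0  # zero the residual branch output
        x = np.abs(rng.standard_normal((1, 3, 5, 5))).astype(np.float32)
        out = block(nn.Tensor(x), training=False)
        assert np.allclose(out.data, x, atol=1e-6)

    def test_spatial_shape_preserved(self):
        rng = np.random.default_rng(5)
        block = bb.RegNetBlock(rng, ci=2, width=2, stages=2)
        x = nn.Tensor(np.random.default_rng(0).standard_normal((2, 2, 6, 6)).astype(np.float32))
        assert block(x, training=False).data.shape == (2, 2, 6, 6)

    def test_convlstm_state_evolves(self):
        rng = np.random.default_rng(6)
        cell = bb.ConvLSTMCell(rng, ci=2, c=3)
        x = nn.Tensor(rng.standard_normal((1, 2, 4, 4)).astype(np.float32))
        h0 = nn.Tensor(np.zeros((1, 3, 4, 4), np.float32))
        c0 = nn.Tensor(np.zeros((1, 3, 4, 4), np.float32))
        h1, c1 = cell(x, h0, c0)
        assert not np.allclose(h1.data, h0.data)
        h2, _ = cell(x, h1, c1)
        assert not np.allclose(h2.data, h1.data)


class TestFeaturesAndHead:
    def test_one_row_per_spectrogram_and_deterministic(self, tiny_model):
        imgs = [np.random.default_rng(7).standard_normal((32, 32, 1)).astype(np.float32)] * 5
        feats = bb.extract_features(tiny_model, imgs)
        assert feats.shape[0] == 5
        assert np.allclose(feats[0], feats[1])

    def test_head_probabilities_sum_to_one(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((60, 6))
        y = (x[:, 0] > 0).astype(int)
        head = bb.train_detect(x, y, bb.HeadConfig(epochs=20))
        _, probs = bb.detect(head, x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_separable_features_learned_quickly(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 400)
        x = rng.standard_normal((400, 4)) * 0.2 + (y * 2 - 1)[:, None] * 2.0
        head = bb.train_detect(x, y, bb.HeadConfig(epochs=50))
        cls, _ = bb.detect(head, x)
        acc = np.mean((cls == "epilepsy") == (y == 1))
        assert acc >= 0.99

    def test_untrained_head_is_chance_level(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((200, 5))
            y = rng.integers(0, 2, 200)
            head = bb.DetectorHead(
                w=rng.standard_normal((5, 2)) * 0.01,
                b=np.zeros(2),
                mean=np.zeros(5),
                std=np.ones(5),
            )
            cls, _ = bb.detect(head, x)
            accs.append(np.mean((cls == "epilepsy") == (y == 1)))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            bb.train_detect(np.zeros((10, 3)), np.zeros(10, dtype=int))
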
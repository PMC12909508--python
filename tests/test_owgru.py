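"""Wave-GRU: step semantics, gate ranges, tuning, lobe derivation."""

import numpy as np
import pytest

from epilobe import nn
from epilobe import owgru as og
from epilobe.recording import LOBES
from epilobe.tuning import Categorical, LogUniform, tune


def _params(units, dim, rng=None, scale=0.5):
    rng = rng or np.random.default_rng(0)
    return {
        "K_r": rng.standard_normal((units, units + dim)) * scale,
        "K_u": rng.standard_normal((units, units + dim)) * scale,
        "K_c": rng.standard_normal((units, units + dim)) * scale,
    }


class TestWaveActivation:
    def test_fixed_points(self):
        assert og.wave_activation(0.0) == 0.0
        assert og.wave_activation(np.pi / 2) == pytest.approx(1.0)

    def test_range_bounded(self, rng):
        x = rng.standard_normal(1000) * 50
        y = og.wave_activation(x)
        assert np.all((y >= -1.0) & (y <= 1.0))


class TestStep:
    def test_zero_weights_give_half_gates(self):
        params = {k: np.zeros((4, 7)) for k in ("K_r", "K_u", "K_c")}
        _, gates = og.owgru_step(np.ones(3), np.zeros(4), params)
        assert np.allclose(gates["r"], 0.5) and np.allclose(gates["u"], 0.5)
        assert np.allclose(gates["candidate"], 0.0)  # sin(0)

    def test_zero_mixing_gate_keeps_hidden_state(self):
        params = _params(4, 3)
        params["b_u"] = np.full(4, -60.0)  # force u -> 0
        h_prev = np.random.default_rng(1).standard_normal(4)
        h, _ = og.owgru_step(np.ones(3), h_prev, params)
        assert np.allclose(h, h_prev, atol=1e-12)

    def test_gate_and_candidate_ranges_over_random_draws(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            params = _params(6, 4, rng, scale=2.0)
            h, gates = og.owgru_step(rng.standard_normal(4), rng.standard_normal(6), params)
            assert np.all((gates["r"] > 0) & (gates["r"] < 1))
            assert np.all((gates["u"] > 0) & (gates["u"] < 1))
            assert np.all(np.abs(gates["candidate"]) <= 1.0)

    @pytest.mark.parametrize("literal", [False, True])
    def test_convex_mixture_property(self, literal):
        rng = np.random.default_rng(5)
        params = _params(6, 4, rng)
        h_prev = rng.standard_normal(6)
        h, gates = og.owgru_step(rng.standard_normal(4), h_prev, params, literal_gate=literal)
        lo = np.minimum(h_prev, gates["candidate"]) - 1e-12
        hi = np.maximum(h_prev, gates["candidate"]) + 1e-12
        assert np.all((h >= lo) & (h <= hi))

    def test_gate_modes_differ(self):
        rng = np.random.default_rng(6)
        params = _params(6, 4, rng)
        x, h_prev = rng.standard_normal(4), rng.standard_normal(6)
        h_default, _ = og.owgru_step(x, h_prev, params, literal_gate=False)
        h_literal, _ = og.owgru_step(x, h_prev, params, literal_gate=True)
        assert not np.allclose(h_default, h_literal)


class TestModel:
    def test_probabilities_sum_to_one_and_deterministic(self):
        model = og.WaveGRU(5, og.OWGRUConfig(layers=2, units=8, seed=0))
        x = np.random.default_rng(0).standard_normal((3, 8, 5)).astype(np.float32)
        p1 = og.localize(model, x)
        p2 = og.localize(model, x)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(p1, p2)

    def test_empty_sequence_rejected(self):
        model = og.WaveGRU(5, og.OWGRUConfig(layers=1, units=4))
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 0, 5), np.float32))

    def test_long_range_gradient_survives_100_steps(self):
        """Input gradient at step 1 of 100 stays above 1e-8 (10 seeds)."""
        for seed in range(10):
            model = og.WaveGRU(3, og.OWGRUConfig(layers=1, units=8, dropout=0.0, seed=seed))
            x = np.random.default_rng(seed).standard_normal((2, 100, 3)).astype(np.float32)
            steps = [nn.Tensor(x[:, k, :], requires_grad=True) for k in range(100)]
            h = nn.Tensor(np.zeros((2, 8), np.float32))
            for k in range(100):
                h = model.layers[0].step(steps[k], h, False)
            head = np.random.default_rng(99).standard_normal((8, 2)).astype(np.float32)
            loss = nn.softmax_cross_entropy(nn.matmul(h, nn.Tensor(head)), np.array([0, 1]))
            loss.backward()
            assert steps[0].grad is not None
            assert np.linalg.norm(steps[0].grad) > 1e-8


class TestDeriveLobe:
    def test_concentrated_response_wins(self):
        names = ["FP1-F7", "T7-P7", "P7-O1", "O1-A1"]
        scores = [9.0, 0.1, 0.1, 0.1]
        assert og.derive_lobe_label(scores, names) == "frontal"

    def test_tie_breaks_by_fixed_order(self):
        names = ["FP1-F7", "T7-P7"]
        assert og.derive_lobe_label([1.0, 1.0], names) == "frontal"

    def test_matches_mean_argmax_oracle(self):
        rng = np.random.default_rng(7)
        names = ["FP1-F7", "FP2-F8", "T7-P7", "T8-P8", "P7-O1", "P8-O2", "O1-A1", "O2-A2"]
        groups = {"frontal": [0, 1], "temporal": [2, 3], "parietal": [4, 5], "occipital": [6, 7]}
        for _ in range(25):
            scores = rng.random(8)
            means = {l: scores[i].mean() for l, i in groups.items()}
            expected = max(LOBES, key=lambda l: means[l])
            assert og.derive_lobe_label(scores, names) == expected

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            og.derive_lobe_label([1.0], ["C3-P3"])


class TestTuning:
    def test_single_point_space_returns_it(self):
        best, log = tune(lambda p: 1.0, {"opt": Categorical(("adam",))}, trials=3, seed=0)
        assert best == {"opt": "adam"} and len(log) == 3

    def test_toy_objective_recovers_known_minimum(self):
        best, log = tune(
            lambda p: (p["lr"] - 0.01) ** 2,
            {"lr": LogUniform(1e-4, 1.0)},
            trials=50,
            seed=1,
        )
        assert 0.005 <= best["lr"] <= 0.02  # within x2 of the optimum
        assert len(log) == 50

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            tune(lambda p: 0.0, {}, trials=5)

    def test_owgru_tuning_logs_all_trials(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((24, 4, 3)).astype(np.float32)
        y = rng.integers(0, 4, 24)
        cfg = og.OWGRUConfig(layers=1, units=6, epochs=4, batch_size=12, trials=4, seed=0)
        tuned, log = og.tune_owgru(x[:16], y[:16], x[16:], y[16:], cfg)
        assert len(log) == 4
        assert tuned.optimizer in ("adam", "sgd")


class TestSequenceFeatures:
    def test_shape_and_fuzzy_index_column(self, frontal_recording):
        rec = frontal_recording.recording
        seg = rec.data[:, 12 * 256 : 14 * 256]
        seq = og.sequence_features(seg, 256.0, rec.channel_names, fuzzy_index=0.33)
        assert seq.shape == (8, 17)
        assert np.allclose(seq[:, -1], 0.33)

    def test_burst_lobe_has_highest_delta_power(self, frontal_recording):
        rec = frontal_recording.recording
        seg = rec.data[:, 12 * 256 : 14 * 256]
        seq = og.sequence_features(seg, 256.0, rec.channel_names)
        delta_cols = seq[:, [0, 4, 8, 12]]  # delta band per lobe
        assert np.argmax(delta_cols.mean(axis=0)) == 0  # frontal
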
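"""SVGL-HBO wrapper feature selection."""

import numpy as np
import pytest

from epilobe import hbo


def _informative_data(seed=0, n=120, d=8, informative=3):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x = rng.standard_normal((n, d))
    for j in range(informative):
        x[:, j] += (y * 2 - 1) * (0.8 + 0.4 * j)
    return x, y


class TestFitness:
    def test_empty_mask_scores_zero(self):
        x, y = _informative_data()
        assert hbo.fitness(np.zeros(8, bool), x, y) == 0.0

    def test_separable_features_score_one(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 90)
        x = rng.standard_normal((90, 4)) * 0.1
        x[:, 1] += (y * 2 - 1) * 5.0
        mask = np.array([False, True, False, False])
        assert hbo.fitness(mask, x, y) == 1.0

    def test_shuffled_labels_are_chance_level(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((100, 5))
            y = np.repeat([0, 1], 50)
            rng.shuffle(y)
            accs.append(hbo.fitness(np.ones(5, bool), x, y, hbo.HBOConfig(seed=seed)))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_matches_direct_probe_evaluation(self):
        x, y = _informative_data(3)
        cfg = hbo.HBOConfig(seed=3)
        for bits in (0b00000111, 0b10101010, 0b11111111):
            mask = np.array([(bits >> k) & 1 for k in range(8)], bool)
            direct = hbo._probe_cv_accuracy(x[:, mask], y, cfg.cv_folds, cfg.seed)
            assert hbo.fitness(mask, x, y, cfg) == pytest.approx(direct)


class TestSteps:
    def _state(self, d=4, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.random((6, d))
        return hbo.HBOState(
            positions=pos.copy(),
            fitness=np.full(6, 0.5),
            best_position=pos[0].copy(),
            best_fitness=0.5,
            iteration=1,
        )

    def test_zero_step_size_keeps_positions(self):
        x, y = _informative_data(d=4)
        cfg = hbo.HBOConfig(step_size=0.0, seed=0)
        state = self._state()
        before = state.positions.copy()

        class ZeroNoise:
            def standard_normal(self, *a):
                return np.zeros(a[0] if a else 1)

        hbo.exploration_step(state, cfg, x, y, ZeroNoise())
        assert np.allclose(state.positions, before)

    def test_direction_flag_sign_rule(self):
        """x2 <= 0.5 moves toward the prey (+1), x2 > 0.5 away (-1)."""
        x, y = _informative_data(d=4)

        class FixedRng:
            def __init__(self, x2):
                self.x2 = x2

            def random(self, *a):
                return self.x2

        for x2, mu in [(0.3, 1.0), (0.7, -1.0)]:
            cfg = hbo.HBOConfig(iterations=10, theta=2.0, seed=0)
            state = self._state()
            state.fitness[:] = -np.inf  # force acceptance of any candidate
            state.iteration = 5
            pos0 = state.positions[1].copy()
            phi = np.abs(state.best_position - pos0)
            expected = np.clip(
                state.best_position + mu * x2 * (2.0 * 5 / 10) * phi, 0.0, 1.0
            )
            hbo.exploitation_step(state, cfg, x, y, FixedRng(x2), cache={}, agents=[1])
            assert np.allclose(state.positions[1], expected)

    def test_density_factor_reaches_theta_at_final_iteration(self):
        cfg = hbo.HBOConfig(iterations=50, theta=2.0)
        assert cfg.theta * 50 / cfg.iterations == pytest.approx(2.0)

    def test_agent_at_prey_stays_when_phi_zero(self):
        x, y = _informative_data(d=4)
        cfg = hbo.HBOConfig(seed=1)
        state = self._state()
        state.positions[2] = state.best_position.copy()
        before = state.positions[2].copy()
        rng = np.random.default_rng(0)
        hbo.exploitation_step(state, cfg, x, y, rng, cache={}, agents=[2])
        assert np.allclose(state.positions[2], before)


class TestRun:
    def test_matches_exhaustive_oracle_within_one_percent(self):
        """Population-30 / 100-iteration search vs the 255-mask optimum."""
        for seed in (1, 2, 3):
            x, y = _informative_data(0)
            cfg = hbo.HBOConfig(population=30, iterations=100, seed=seed)
            _, state = hbo.run(x, y, cfg)
            _, chi_star = hbo.exhaustive_best(x, y, cfg)
            assert state.best_fitness >= chi_star - 0.01

    def test_informative_features_recovered(self):
        hits = 0
        for seed in range(5):
            x, y = _informative_data(7)
            sel, _ = hbo.run(x, y, hbo.HBOConfig(population=20, iterations=40, seed=seed))
            hits += len(set(sel) & {0, 1, 2}) >= 2
        assert hits >= 4

    def test_trace_non_decreasing_and_bounds_respected(self):
        x, y = _informative_data(5)
        cfg = hbo.HBOConfig(population=10, iterations=20, seed=5)
        _, state = hbo.run(x, y, cfg)
        best = [t[1] for t in state.trace]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
        assert state.positions.min() >= cfg.b_low
        assert state.positions.max() <= cfg.b_high

    def test_deterministic_under_seed(self):
        x, y = _informative_data(6)
        cfg = hbo.HBOConfig(population=8, iterations=10, seed=9)
        sel_a, _ = hbo.run(x, y, cfg)
        sel_b, _ = hbo.run(x, y, cfg)
        assert np.array_equal(sel_a, sel_b)

    def test_selected_set_never_empty(self):
        x, y = _informative_data(8)
        sel, _ = hbo.run(x, y, hbo.HBOConfig(population=4, iterations=2, seed=0))
        assert len(sel) >= 1

    def test_zero_features_rejected(self):
        with pytest.raises(ValueError):
            hbo.run(np.zeros((10, 0)), np.zeros(10), hbo.HBOConfig())
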
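import numpy as np
import pytest

from qmpa import mpa
from qmpa.mpa import (MPAConfig, PreyPopulation, SelectionMask,
                      binarize_position, compute_cf, fads_perturbation,
                      greedy_memory, init_population, optimize, phase_update,
                      quantum_update, random_motion, select_features,
                      selection_fitness)
from qmpa.synthetic import FeatureSpec, make_feature_dataset


class QueuedRng:
    """Stub generator returning pre-recorded draws, for scalar oracles."""

    def __init__(self, normals=(), uniforms=(), integers=()):
        self._n, self._u, self._i = list(normals), list(uniforms), list(integers)

    def normal(self, loc=0.0, scale=1.0, size=None):
        return np.full(size, self._n.pop(0)) if size else self._n.pop(0)

    def uniform(self, low=0.0, high=1.0, size=None):
        v = self._u.pop(0)
        out = low + (high - low) * np.asarray(v, dtype=float)
        return np.full(size, out) if size is not None and np.ndim(v) == 0 else out

    def integers(self, low, high, size=None):
        v = self._i.pop(0)
        return np.full(size, v, dtype=int) if size is not None else v


def evaluated_pop(positions, fitness, lb=0.0, ub=1.0):
    positions = np.asarray(positions, dtype=float)
    n, d = positions.shape
    pop = PreyPopulation(positions=positions.copy(),
                         lb=np.full(d, lb), ub=np.full(d, ub),
                         fitness=np.asarray(fitness, dtype=float))
    return greedy_memory(pop)


class TestInit:
    def test_bounds_and_shape(self, rng):
        pop = init_population(6, 3, -2.0, 5.0, rng)
        assert pop.positions.shape == (6, 3)
        assert np.all((pop.positions >= -2.0) & (pop.positions <= 5.0))

    def test_uniformity(self):
        pop = init_population(10_000, 1, 0.0, 1.0, np.random.default_rng(0))
        assert pop.positions.mean() == pytest.approx(0.5, abs=0.02)

    def test_inverted_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            init_population(3, 2, 1.0, 0.0, rng)


class TestRandomMotion:
    def test_brownian_moments(self):
        draws = random_motion("brownian", (100_000,), np.random.default_rng(1))
        assert draws.mean() == pytest.approx(0.0, abs=0.02)
        assert draws.std() == pytest.approx(1.0, abs=0.02)

    def test_levy_heavy_tailed(self):
        draws = random_motion("levy", (100_000,), np.random.default_rng(2))
        kurt = np.mean((draws - draws.mean()) ** 4) / draws.var() ** 2
        assert kurt > 30  # far beyond the normal's 3

    def test_seeded_reproducibility(self):
        a = random_motion("levy", (50,), np.random.default_rng(3))
        b = random_motion("levy", (50,), np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            random_motion("pogo", (3,), rng)


@pytest.mark.parametrize("it,maxit,expected", [
    (0, 100, 1.0),
    (100, 100, 0.0),
    (50, 100, 0.5),
])
def test_compute_cf(it, maxit, expected):
    assert compute_cf(it, maxit) == pytest.approx(expected)


class TestPhaseUpdate:
    def test_phase1_zero_draws_leave_positions(self):
        pop = evaluated_pop([[0.4, 0.6], [0.2, 0.8]], [1.0, 2.0])
        cfg = MPAConfig(n_agents=2, max_iter=9, quantum=False, T=0.5)
        rng = QueuedRng(normals=[0.0], uniforms=[0.3])
        before = pop.positions.copy()
        phase_update(pop, 1, 9, cfg, rng)
        np.testing.assert_allclose(pop.positions, before)

    def test_phase1_matches_scalar_oracle(self):
        # one agent, recorded draws: step = RB*(E - RB*P); P += T*R*step
        P0, E0, RB, R, T = 0.4, 0.4, 0.7, 0.3, 0.5
        pop = evaluated_pop([[P0]], [1.0])
        cfg = MPAConfig(n_agents=1, max_iter=9, quantum=False, T=T)
        phase_update(pop, 1, 9, cfg, QueuedRng(normals=[RB], uniforms=[R]))
        expected = P0 + T * R * (RB * (E0 - RB * P0))
        assert pop.positions[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_phase3_final_iteration_collapses_to_elite(self):
        pop = evaluated_pop([[0.1, 0.9], [0.7, 0.3]], [2.0, 1.0])
        cfg = MPAConfig(n_agents=2, max_iter=10, quantum=False)
        phase_update(pop, 10, 10, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(pop.positions,
                                   np.tile(pop.elite_position, (2, 1)))

    def test_unevaluated_population_rejected(self, rng):
        pop = init_population(3, 2, 0.0, 1.0, rng)
        with pytest.raises(ValueError):
            phase_update(pop, 1, 10, MPAConfig(), rng)

    def test_positions_stay_in_bounds(self, rng):
        cfg = MPAConfig(n_agents=8, max_iter=30)
        pop = init_population(8, 4, -1.0, 2.0, rng)
        pop.fitness = rng.uniform(0, 1, 8)
        greedy_memory(pop)
        for it in (1, 12, 25, 30):
            phase_update(pop, it, 30, cfg, rng)
            assert np.all((pop.positions >= -1.0) & (pop.positions <= 2.0))
            fads_perturbation(pop, it, 30, cfg, rng)
            assert np.all((pop.positions >= -1.0) & (pop.positions <= 2.0))


class TestFads:
    def test_jump_branch_with_zero_mask_is_noop(self):
        pop = evaluated_pop([[0.4, 0.6]] * 3, [1.0, 2.0, 3.0])
        cfg = MPAConfig(n_agents=3, fads=0.2)
        # r=0 -> jump branch for all agents; mask draws all below fads -> U=0
        rng = QueuedRng(uniforms=[np.zeros(3), np.full((3, 2), 0.1),
                                  np.full((3, 2), 0.5)])
        before = pop.positions.copy()
        fads_perturbation(pop, 1, 10, cfg, rng)
        np.testing.assert_allclose(pop.positions, before)

    def test_swap_branch_full_coefficient(self):
        P = np.array([[0.3, 0.3], [0.6, 0.1], [0.1, 0.5]])
        pop = evaluated_pop(P, [1.0, 2.0, 3.0])
        cfg = MPAConfig(n_agents=3, fads=0.2)
        # r=1 for all -> swap branch, coefficient FADs(1-r)+r = 1
        rng = QueuedRng(uniforms=[np.ones(3)], integers=[np.array([1, 1, 1]),
                                                          np.array([1, 1, 1])])
        # r1 = 1; raw r2 = 1 -> shifted to 2 where >= r1
        fads_perturbation(pop, 1, 10, cfg, rng)
        expected = np.clip(P + (P[1] - P[2]), 0.0, 1.0)
        np.testing.assert_allclose(pop.positions, expected)

    def test_identical_rows_swap_is_noop(self):
        P = np.full((4, 3), 0.42)
        pop = evaluated_pop(P, [1.0, 1.0, 1.0, 1.0])
        rng = QueuedRng(uniforms=[np.full(4, 0.9)],
                        integers=[np.array([0, 1, 2, 3]), np.array([0, 0, 0, 0])])
        fads_perturbation(pop, 1, 10, MPAConfig(n_agents=4), rng)
        np.testing.assert_allclose(pop.positions, P)


class TestQuantum:
    def test_u_one_collapses_to_attractor(self):
        pos = np.array([[0.3, 0.8]])
        cbest = np.array([[0.5, 0.5]])
        gbest = np.array([0.9, 0.1])
        theta = 0.25
        rng = QueuedRng(uniforms=[np.ones((1, 2)), np.full((1, 2), 0.7)])
        out = quantum_update(pos, cbest, gbest, b=1.0, theta=theta, rng=rng)
        C = theta * cbest + (1 - theta) * gbest
        np.testing.assert_allclose(out, C, atol=1e-12)

    @pytest.mark.parametrize("theta,expect_from", [(1.0, "cbest"), (0.0, "gbest")])
    def test_attractor_endpoints(self, theta, expect_from):
        cbest = np.array([[0.2, 0.4]])
        gbest = np.array([0.9, 0.1])
        rng = QueuedRng(uniforms=[np.ones((1, 2)), np.full((1, 2), 0.7)])
        out = quantum_update(cbest.copy(), cbest, gbest, 1.0, theta, rng)
        target = cbest[0] if expect_from == "cbest" else gbest
        np.testing.assert_allclose(out[0], target, atol=1e-12)

    def test_contraction_limit_b_zero(self, rng):
        pos = rng.uniform(0, 1, (5, 3))
        cbest = rng.uniform(0, 1, (5, 3))
        gbest = rng.uniform(0, 1, 3)
        out = quantum_update(pos, cbest, gbest, b=0.0, theta=0.6, rng=rng)
        np.testing.assert_allclose(out, 0.6 * cbest + 0.4 * gbest, atol=1e-12)

    def test_b_schedule_endpoints(self):
        assert mpa._b_schedule(0, 100, 1.0, 0.5) == pytest.approx(1.0)
        assert mpa._b_schedule(100, 100, 1.0, 0.5) == pytest.approx(0.5)


class TestGreedyMemory:
    def test_all_current_worse_reverts(self):
        pop = evaluated_pop([[0.1], [0.2]], [1.0, 2.0])
        old = pop.positions.copy()
        pop.positions = np.array([[0.9], [0.8]])
        pop.fitness = np.array([5.0, 6.0])
        greedy_memory(pop)
        np.testing.assert_allclose(pop.positions, old)
        np.testing.assert_allclose(pop.fitness, [1.0, 2.0])

    def test_all_current_better_overwrites(self):
        pop = evaluated_pop([[0.1], [0.2]], [1.0, 2.0])
        pop.positions = np.array([[0.9], [0.8]])
        pop.fitness = np.array([0.5, 0.6])
        greedy_memory(pop)
        np.testing.assert_allclose(pop.fitness, [0.5, 0.6])
        assert pop.elite_fitness == pytest.approx(0.5)

    def test_mixed_case_matches_argmin_oracle(self, rng):
        n, d = 6, 3
        f_old = rng.uniform(0, 1, n)
        f_new = rng.uniform(0, 1, n)
        P_old = rng.uniform(0, 1, (n, d))
        P_new = rng.uniform(0, 1, (n, d))
        pop = evaluated_pop(P_old, f_old)
        pop.positions, pop.fitness = P_new.copy(), f_new.copy()
        greedy_memory(pop)
        expect_f = np.minimum(f_old, f_new)
        expect_P = np.where((f_new <= f_old)[:, None], P_new, P_old)
        np.testing.assert_allclose(pop.fitness, expect_f)
        np.testing.assert_allclose(pop.positions, expect_P)


class TestBinarize:
    def test_threshold_with_tie_inclusive(self):
        mask = binarize_position(np.array([0.7, 0.2, 0.5]), 0.5)
        np.testing.assert_array_equal(mask.selected, [True, False, True])

    def test_empty_falls_back_to_argmax(self):
        mask = binarize_position(np.array([0.1, 0.4, 0.2]), 0.5)
        np.testing.assert_array_equal(mask.selected, [False, True, False])
        assert mask.n_selected == 1

    def test_zero_threshold_selects_all(self):
        # tau must be in (0,1) for configs, but binarize accepts the limit
        mask = binarize_position(np.array([0.0, 0.3]), 0.0)
        assert mask.n_selected == 2


class TestSelectionFitness:
    def test_informative_mask_near_zero_error(self, separable_features):
        data = separable_features
        mask = SelectionMask(np.isin(np.arange(data.d), data.informative_indices))
        fit = selection_fitness(mask, data.values, data.labels, MPAConfig(seed=0))
        assert fit < 0.05

    def test_informative_no_worse_than_full(self, separable_features):
        data = separable_features
        cfg = MPAConfig(seed=0)
        m_inf = SelectionMask(np.isin(np.arange(data.d), data.informative_indices))
        m_full = SelectionMask(np.ones(data.d, dtype=bool))
        f_inf = selection_fitness(m_inf, data.values, data.labels, cfg)
        f_full = selection_fitness(m_full, data.values, data.labels, cfg)
        assert f_inf <= f_full + 0.02

    def test_pure_noise_near_chance(self, rng):
        X = rng.uniform(0, 1, (120, 6))
        y = np.repeat([0, 1, 2], 40)
        cfg = MPAConfig(seed=0, fitness_alpha=1.0)
        fit = selection_fitness(SelectionMask(np.ones(6, dtype=bool)), X, y, cfg)
        assert fit == pytest.approx(2 / 3, abs=0.12)

    def test_single_class_rejected(self, rng):
        X = rng.uniform(0, 1, (20, 4))
        with pytest.raises(ValueError):
            selection_fitness(SelectionMask(np.ones(4, dtype=bool)), X,
                              np.zeros(20), MPAConfig())


class TestOptimize:
    def test_history_non_increasing_and_deterministic(self):
        cfg = MPAConfig(n_agents=10, max_iter=20, seed=4)
        f = lambda x: float(np.sum(x ** 2))
        r1 = optimize(f, 5, -5.0, 5.0, cfg)
        r2 = optimize(f, 5, -5.0, 5.0, cfg)
        assert np.all(np.diff(r1.history) <= 0)
        np.testing.assert_array_equal(r1.history, r2.history)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_zero_iterations_returns_initial_best(self):
        cfg = MPAConfig(n_agents=8, max_iter=0, seed=1)
        res = optimize(lambda x: float(np.sum(x ** 2)), 3, -1.0, 1.0, cfg)
        assert len(res.history) == 1
        assert res.n_evaluations == 8

    def test_quantum_ablation_runs(self):
        cfg = MPAConfig(n_agents=10, max_iter=15, seed=2, quantum=False)
        res = optimize(lambda x: float(np.sum(x ** 2)), 4, -2.0, 2.0, cfg)
        assert np.all(np.diff(res.history) <= 0)


class TestSelectFeatures:
    def test_planted_recovery_single_seed(self):
        spec = FeatureSpec(n_per_class=60, n_classes=3, d=20, n_informative=4,
                           class_sep=2.0, seed=0)
        data = make_feature_dataset(spec)
        cfg = MPAConfig(n_agents=15, max_iter=25, seed=0)
        mask, history = select_features(data.values, data.labels, cfg)
        recovered = np.isin(data.informative_indices, mask.indices).sum()
        assert recovered >= 3
        assert np.all(np.diff(history) <= 0)

    def test_max_iter_zero_returns_initial_best(self, separable_features):
        data = separable_features
        cfg = MPAConfig(n_agents=8, max_iter=0, seed=3)
        mask, history = select_features(data.values, data.labels, cfg)
        assert mask.n_selected >= 1
        assert len(history) == 1

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            select_features(rng.uniform(0, 1, (5, 4)), np.array([0, 1] * 2 + [0]),
                            MPAConfig(max_iter=1))
        with pytest.raises(ValueError):
            select_features(rng.uniform(0, 1, (20, 4)), np.zeros(20),
                            MPAConfig(max_iter=1))
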
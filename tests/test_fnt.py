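"""Flexible neural tree: Gaussian neurons, GP structure search, PSO tuning."""

import numpy as np
import pytest

from herbscreen.fnt import (FntModel, FntNode, eval_neuron, eval_tree,
                            evolve_structure, fit_fnt, pso_minimize,
                            pso_optimize, random_tree)


def two_terminal_model(w=(1.0, 1.0), a=0.0, b=1.0, width=2):
    root = FntNode("function", weights=np.array(w), a=a, b=b,
                   children=[FntNode("terminal", index=0),
                             FntNode("terminal", index=1)])
    return FntModel(root, input_width=width)


class TestEvalNeuron:
    def test_peak_of_one_when_sum_equals_a(self):
        assert eval_neuron([2.0, -1.0], [0.5, 1.0], a=0.0, b=0.7) == pytest.approx(1.0)

    def test_hand_computed_exp_minus_one(self):
        # o = 1*0.5 + 1*0.5 = 1, a = 0, b = 1 -> exp(-1)
        assert eval_neuron([1, 1], [0.5, 0.5], 0, 1) == pytest.approx(np.exp(-1))

    def test_tails_decay_but_stay_positive(self):
        far = eval_neuron([1.0], [6.0], a=0.0, b=1.0)
        near = eval_neuron([1.0], [2.0], a=0.0, b=1.0)
        assert 0 < far < near < 1

    def test_zero_width_b_raises(self):
        with pytest.raises(ValueError, match="b must be nonzero"):
            eval_neuron([1.0], [1.0], 0.0, 0.0)


class TestEvalTree:
    def test_terminal_root_is_identity(self):
        m = FntModel(FntNode("terminal", index=0), input_width=1)
        assert eval_tree(m, [0.7]) == pytest.approx(0.7)

    def test_two_level_hand_computation(self):
        m = two_terminal_model(w=(0.5, -0.25), a=0.1, b=0.8)
        x = np.array([0.6, 0.4])
        o = 0.5 * 0.6 - 0.25 * 0.4
        expected = np.exp(-(((o - 0.1) / 0.8) ** 2))
        assert eval_tree(m, x) == pytest.approx(expected)

    def test_deterministic(self, rng):
        tree = random_tree(rng, width=6)
        m = FntModel(tree, 6)
        x = rng.random(6)
        assert eval_tree(m, x) == eval_tree(m, x)

    def test_width_mismatch_raises(self):
        m = two_terminal_model()
        with pytest.raises(ValueError, match="width mismatch"):
            eval_tree(m, [0.1, 0.2, 0.3])

    def test_neuron_root_output_in_unit_interval(self, rng):
        for _ in range(10):
            tree = random_tree(rng, width=5)
            m = FntModel(tree, 5)
            X = rng.random((20, 5))
            s = m.predict_score(X)
            assert np.all(s > 0) and np.all(s <= 1)


@pytest.fixture
def gaussian_band_task(rng):
    """Labels are a thresholded Gaussian of feature 0: a band classifier."""
    X = rng.random((120, 4))
    y = (np.exp(-(((X[:, 0] - 0.5) / 0.2) ** 2)) > 0.5).astype(float)
    return X, y


class TestEvolveStructure:
    def test_zero_generations_returns_best_random_tree(self, gaussian_band_task):
        m = evolve_structure(gaussian_band_task, population_size=10, generations=0, seed=4)
        assert np.isfinite(m.fitness)

    def test_fixed_seed_reproduces_champion(self, gaussian_band_task):
        m1 = evolve_structure(gaussian_band_task, 12, 4, seed=9)
        m2 = evolve_structure(gaussian_band_task, 12, 4, seed=9)
        assert m1.to_json() == m2.to_json()

    def test_small_population_raises(self, gaussian_band_task):
        with pytest.raises(ValueError, match="population_size"):
            evolve_structure(gaussian_band_task, population_size=1, generations=1, seed=0)

    def test_recovers_informative_feature(self, rng):
        """On a task driven by one feature, the champion's terminal set should
        include that feature in at least 80% of seeded runs."""
        X = rng.random((100, 5))
        y = (X[:, 2] > 0.5).astype(float)
        hits = 0
        for seed in range(20):
            m = evolve_structure((X, y), population_size=16, generations=8,
                                 seed=seed, max_depth=2)
            hits += 2 in m.root.terminals()
        assert hits >= 16

    def test_champion_fitness_never_worse_with_more_generations(self, gaussian_band_task):
        f0 = evolve_structure(gaussian_band_task, 14, 0, seed=2).fitness
        f6 = evolve_structure(gaussian_band_task, 14, 6, seed=2).fitness
        assert f6 <= f0 + 1e-12


class TestPso:
    def test_zero_iterations_is_a_noop(self, gaussian_band_task):
        import json

        m = two_terminal_model(width=4)
        out = pso_optimize(m, gaussian_band_task, swarm_size=8, iterations=0, seed=0)
        assert json.loads(out.to_json())["root"] == json.loads(m.to_json())["root"]

    def test_bare_terminal_tree_returned_unchanged(self, gaussian_band_task):
        m = FntModel(FntNode("terminal", index=0), input_width=4)
        out = pso_optimize(m, gaussian_band_task, 8, 50, 0)
        assert out.root.kind == "terminal" and out.root.index == 0

    def test_quadratic_optimum_recovered(self):
        target = np.array([1.0, -2.0, 3.0])

        def f(v):
            return float(np.sum((v - target) ** 2))

        best, val, traj = pso_minimize(f, np.zeros(3), swarm_size=20,
                                       iterations=200, seed=0)
        assert np.abs(best - target).max() < 1e-3
        assert val < 1e-6

    def test_global_best_trajectory_non_increasing(self):
        def rosen(v):
            return float((1 - v[0]) ** 2 + 100 * (v[1] - v[0] ** 2) ** 2)

        _, _, traj = pso_minimize(rosen, np.array([2.0, 2.0]), 12, 80, 1)
        assert all(b <= a + 1e-15 for a, b in zip(traj, traj[1:]))

    def test_fixed_seed_identical_trajectory(self):
        def f(v):
            return float(v @ v)

        t1 = pso_minimize(f, np.ones(4), 10, 30, 5)[2]
        t2 = pso_minimize(f, np.ones(4), 10, 30, 5)[2]
        assert t1 == t2

    def test_optimized_fitness_not_worse_than_input(self, gaussian_band_task):
        X, y = gaussian_band_task
        m = evolve_structure((X, y), 10, 2, seed=1)
        out = pso_optimize(m, (X, y), swarm_size=12, iterations=25, seed=1)
        assert out.fitness <= m.fitness + 1e-12


class TestFitFnt:
    def test_depth_one_band_task_high_accuracy_across_seeds(self, gaussian_band_task):
        """A shallow FNT should solve the thresholded-Gaussian band task."""
        X, y = gaussian_band_task
        accs = []
        for seed in range(10):
            m = fit_fnt(X, y, population_size=20, generations=8, swarm_size=20,
                        pso_iterations=60, rounds=2, seed=seed, max_depth=1)
            accs.append((((m.predict_score(X) > 0.5).astype(float)) == y).mean())
        assert min(accs) >= 0.95

    def test_alternation_never_worsens_champion(self, gaussian_band_task):
        X, y = gaussian_band_task
        f1 = fit_fnt(X, y, rounds=1, seed=3, population_size=10, generations=3,
                     swarm_size=8, pso_iterations=10).fitness
        f2 = fit_fnt(X, y, rounds=2, seed=3, population_size=10, generations=3,
                     swarm_size=8, pso_iterations=10).fitness
        assert f2 <= f1 + 1e-12


class TestSerialization:
    def test_genome_json_roundtrip(self, rng):
        tree = random_tree(rng, width=7, max_depth=3)
        m = FntModel(tree, 7, fitness=0.25)
        m2 = FntModel.from_json(m.to_json())
        X = rng.random((15, 7))
        assert np.allclose(m.predict_score(X), m2.predict_score(X))
        assert m2.fitness == 0.25

    def test_sibling_terminals_distinct_in_random_trees(self, rng):
        for _ in range(20):
            tree = random_tree(rng, width=10, max_depth=3)
            for node in tree.function_nodes():
                idx = [c.index for c in node.children if c.kind == "terminal"]
                assert len(idx) == len(set(idx))
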
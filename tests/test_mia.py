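"""Operators and the full loop of the modified immune algorithm."""

import numpy as np
import pytest

from rcfopt.core import check_constraints
from rcfopt.mia import (
    MIAParams,
    clonal_select,
    concentration,
    guo_elite_mutation,
    initialize_population,
    mutation_probability,
    perturb_global_best,
    repair_encoding,
    run_mia,
    selection_threshold,
    update_memory,
)
from rcfopt.synthetic import oracle_instance


@pytest.fixture(scope="module")
def small():
    instance, p, optimum = oracle_instance(seed=2)
    return instance, p, optimum


class TestInitialization:
    def test_population_shape_and_validity(self, small):
        instance, p, _ = small
        params = MIAParams(p=p, pop_size=20, seed=3)
        enc = initialize_population(instance, params)
        assert enc.shape == (20, p)
        for row in enc:
            assert len(set(row.tolist())) == p
            assert row.min() >= 0 and row.max() < instance.n_sites

    def test_seed_determinism(self, small):
        instance, p, _ = small
        params = MIAParams(p=p, pop_size=20, seed=3)
        a = initialize_population(instance, params)
        b = initialize_population(instance, params)
        assert np.array_equal(a, b)

    def test_full_site_set_when_j_equals_p(self, small):
        instance, _, _ = small
        params = MIAParams(p=instance.n_sites, pop_size=4, seed=0)
        enc = initialize_population(instance, params)
        assert np.array_equal(enc, np.tile(np.arange(instance.n_sites), (4, 1)))

    def test_too_many_facilities_rejected(self, small):
        instance, _, _ = small
        with pytest.raises(ValueError):
            initialize_population(instance, MIAParams(p=instance.n_sites + 1, seed=0))


class TestConcentration:
    def test_identical_population_is_fully_concentrated(self):
        enc = np.tile([0, 1, 2], (5, 1))
        assert concentration(enc, 10).tolist() == [1.0] * 5

    def test_disjoint_population_sees_only_itself(self):
        enc = np.array([[0, 1], [2, 3], [4, 5], [6, 7]])
        assert concentration(enc, 8, 0.5).tolist() == [0.25] * 4

    def test_two_identical_pairs(self):
        enc = np.array([[0, 1], [0, 1], [2, 3], [2, 3]])
        assert concentration(enc, 6, 1.0).tolist() == [0.5] * 4


class TestSchedules:
    def test_threshold_flat_then_rises_to_one(self):
        params = MIAParams(p=3, t_max=100, seed=0)
        assert selection_threshold(0, params) == 0.3
        assert selection_threshold(50, params) == 0.3
        assert selection_threshold(100, params) == pytest.approx(1.0)
        grid = [selection_threshold(t, params) for t in range(101)]
        assert np.all(np.diff(grid) >= 0)

    def test_threshold_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            selection_threshold(101, MIAParams(p=3, t_max=100, seed=0))

    def test_mutation_probability_formula(self):
        params = MIAParams(p=3, eps_mut=0.1, gamma=0.05, period=40, seed=0)
        assert mutation_probability(0, params) == pytest.approx(0.15)
        assert mutation_probability(10, params) == pytest.approx(0.05)  # t = T/4
        for t in range(0, 120, 7):
            expected = 0.1 * abs(np.cos(2 * np.pi * t / 40)) + 0.05
            assert mutation_probability(t, params) == pytest.approx(expected)

    def test_mutation_probability_has_half_period(self):
        params = MIAParams(p=3, period=40, seed=0)
        for t in range(0, 40):
            assert mutation_probability(t, params) == pytest.approx(
                mutation_probability(t + 20, params)
            )

    def test_perturbation_only_on_interval_and_decays(self):
        params = MIAParams(p=3, theta=10, seed=0)
        rng = np.random.default_rng(0)
        assert perturb_global_best(1.0, 7, params, rng) == 1.0
        bumps = [
            perturb_global_best(1.0, t, params, np.random.default_rng(1)) - 1.0
            for t in (0, 10, 20, 50)
        ]
        assert all(b >= 0 for b in bumps)
        assert bumps[0] <= 1.0
        envelopes = [np.exp(-t / 10) for t in (0, 10, 20, 50)]
        assert all(b <= e for b, e in zip(bumps, envelopes))


class TestClonalSelection:
    def test_uniform_scores_spread_clones_evenly(self):
        params = MIAParams(p=3, pop_size=12, t_max=100, seed=0)
        selected, counts = clonal_select(
            np.ones(12), np.zeros(12), t=10, params=params
        )
        assert counts.sum() == 12
        assert counts.max() - counts.min() <= 1

    def test_strong_antibody_gets_most_clones(self):
        params = MIAParams(p=3, pop_size=10, t_max=100, seed=0)
        aff = np.ones(10)
        aff[4] = 10.0
        selected, counts = clonal_select(aff, np.zeros(10), t=10, params=params)
        assert counts[np.flatnonzero(selected == 4)[0]] == counts.max()

    def test_clone_total_is_population_size(self):
        params = MIAParams(p=3, pop_size=17, t_max=50, seed=0)
        rng = np.random.default_rng(8)
        for t in (1, 25, 50):
            _, counts = clonal_select(
                rng.uniform(0.5, 2.0, 17), rng.uniform(0, 0.9, 17), t, params
            )
            assert counts.sum() == 17


class TestGuoMutation:
    def test_identical_parents_are_a_fixed_point(self):
        pool = np.tile([2, 5, 7], (3, 1))
        child = guo_elite_mutation(pool, 10, np.random.default_rng(0))
        assert child.tolist() == [2, 5, 7]

    def test_vertex_phi_returns_parent(self):
        pool = np.array([[1, 4, 8], [0, 2, 9]])
        child = guo_elite_mutation(pool, 10, None, phi=np.array([1.0, 0.0]))
        assert child.tolist() == [1, 4, 8]

    def test_midpoint_combination_with_repair(self):
        pool = np.array([[0, 2], [4, 8]])
        child = guo_elite_mutation(pool, 10, None, phi=np.array([0.5, 0.5]))
        assert child.tolist() == [2, 5]

    def test_random_offspring_always_valid(self):
        rng = np.random.default_rng(4)
        pool = np.array([[0, 3, 7], [2, 5, 9], [1, 6, 8]])
        for _ in range(200):
            child = guo_elite_mutation(pool, 10, rng)
            assert len(set(child.tolist())) == 3
            assert child.min() >= 0 and child.max() < 10
            assert np.all(np.diff(child) > 0)

    def test_pool_of_one_rejected(self):
        with pytest.raises(ValueError):
            guo_elite_mutation(np.array([[1, 2]]), 5, np.random.default_rng(0))

    def test_repair_resolves_duplicates_to_nearest_unused(self):
        assert repair_encoding(np.array([2.4, 1.6, 2.0]), 10).tolist() == [1, 2, 3]


class TestMemory:
    def test_empty_memory_fills_with_best(self):
        enc = np.array([[0, 1], [2, 3], [4, 5]])
        memory = update_memory([], enc, np.array([0.3, 0.1, 0.2]), capacity=2)
        assert [m[0] for m in memory] == [(2, 3), (4, 5)]

    def test_better_antibody_evicts_worst(self):
        memory = [((0, 1), 0.1), ((2, 3), 0.5)]
        memory = update_memory(memory, np.array([[4, 5]]), np.array([0.2]), 2)
        assert [m[0] for m in memory] == [(0, 1), (4, 5)]

    def test_duplicates_not_stored_twice(self):
        memory = [((0, 1), 0.1)]
        memory = update_memory(memory, np.array([[0, 1]]), np.array([0.1]), 4)
        assert len(memory) == 1


class TestRunMIA:
    def test_degenerate_single_iteration_runs(self, small):
        instance, p, _ = small
        result = run_mia(instance, MIAParams(p=p, pop_size=10, t_max=1, seed=0))
        assert result.trace.shape[0] == 1
        assert result.best_F > 0

    def test_seed_reproducibility(self, small):
        instance, p, _ = small
        a = run_mia(instance, MIAParams(p=p, pop_size=15, t_max=30, seed=9))
        b = run_mia(instance, MIAParams(p=p, pop_size=15, t_max=30, seed=9))
        assert np.array_equal(a.best_encoding, b.best_encoding)
        assert a.best_F == b.best_F
        assert a.trace.equals(b.trace)

    def test_incumbent_trace_non_increasing(self, small):
        instance, p, _ = small
        result = run_mia(instance, MIAParams(p=p, pop_size=20, t_max=60, seed=4))
        best = result.trace["best_F"].to_numpy()
        assert np.all(np.diff(best) <= 0)

    def test_returned_configuration_is_feasible(self, small):
        instance, p, _ = small
        result = run_mia(instance, MIAParams(p=p, pop_size=20, t_max=60, seed=4))
        assert check_constraints(instance, result.best_config).feasible

    def test_finds_exhaustive_optimum(self, small):
        instance, p, optimum = small
        result = run_mia(instance, MIAParams(p=p, pop_size=30, t_max=200, seed=1))
        assert result.best_F == pytest.approx(optimum.F, abs=1e-12)
        assert np.array_equal(result.best_encoding, optimum.encoding)
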
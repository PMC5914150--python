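import numpy as np
import pytest

from connsel import (
    GAConfig,
    GAFeatureSelection,
    HyperGrid,
    ManualFeatureSelection,
    SelectionMask,
    bit_flip_mutation,
    evaluate_fitness,
    grid_search,
    manual_selection,
    run_ga,
    tournament_select,
    two_point_crossover,
)

from conftest import make_feature_table


class FixedCuts:
    """rng stub returning predetermined crossover cut points."""

    def __init__(self, lo, hi):
        self.cuts = np.array([lo, hi])

    def integers(self, *a, **k):
        return self.cuts


class TestCrossover:
    def test_fixed_cuts_example(self):
        p1 = SelectionMask([0, 0, 0, 0, 0, 0])
        p2 = SelectionMask([1, 1, 1, 1, 1, 1])
        c1, c2 = two_point_crossover(p1, p2, FixedCuts(2, 4))
        assert c1.bits.tolist() == [0, 0, 1, 1, 0, 0]
        assert c2.bits.tolist() == [1, 1, 0, 0, 1, 1]

    def test_identical_parents_and_empty_segment(self, rng):
        p = SelectionMask(rng.integers(0, 2, 8))
        c1, c2 = two_point_crossover(p, SelectionMask(p.bits.copy()), rng)
        assert np.array_equal(c1.bits, p.bits) and np.array_equal(c2.bits, p.bits)
        q = SelectionMask(1 - p.bits)
        c1, c2 = two_point_crossover(p, q, FixedCuts(3, 3))
        assert np.array_equal(c1.bits, p.bits) and np.array_equal(c2.bits, q.bits)

    def test_positionwise_bit_conservation(self, rng):
        for _ in range(100):
            d = int(rng.integers(2, 40))
            p1 = SelectionMask(rng.integers(0, 2, d))
            p2 = SelectionMask(rng.integers(0, 2, d))
            c1, c2 = two_point_crossover(p1, p2, rng)
            np.testing.assert_array_equal(c1.bits + c2.bits, p1.bits + p2.bits)


class TestMutation:
    def test_prob_zero_and_one(self, rng):
        m = SelectionMask(rng.integers(0, 2, 20))
        assert np.array_equal(bit_flip_mutation(m, 0.0, rng).bits, m.bits)
        assert np.array_equal(bit_flip_mutation(m, 1.0, rng).bits, 1 - m.bits)

    def test_flip_count_binomial_mean(self, rng):
        d, p, trials = 116, 0.1, 2000
        m = SelectionMask(np.zeros(d, int))
        flips = [bit_flip_mutation(m, p, rng).n_selected for _ in range(trials)]
        se = np.sqrt(d * p * (1 - p) / trials)
        assert abs(np.mean(flips) - d * p) < 3 * se


class TestTournament:
    def test_dominant_individual_wins_whenever_drawn(self):
        pop = [SelectionMask(np.eye(4, dtype=int)[i]) for i in range(4)]
        fits = [0.0, 1.0, 0.0, 0.0]
        sel = tournament_select(pop, fits, k=3, count=100,
                                rng=np.random.default_rng(8))
        replay = np.random.default_rng(8)  # same draw sequence
        for m in sel:
            drawn = replay.integers(0, 4, size=3)
            if 1 in drawn:
                assert np.array_equal(m.bits, pop[1].bits)
            else:
                assert any(np.array_equal(m.bits, pop[i].bits) for i in drawn)

    def test_seeded_determinism(self):
        pop = [SelectionMask(np.eye(5, dtype=int)[i]) for i in range(5)]
        fits = [0.1, 0.9, 0.3, 0.9, 0.2]
        a = tournament_select(pop, fits, 3, 20, np.random.default_rng(42))
        b = tournament_select(pop, fits, 3, 20, np.random.default_rng(42))
        assert all(np.array_equal(x.bits, y.bits) for x, y in zip(a, b))

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="empty"):
            tournament_select([], [], 2, 1, rng)
        pop = [SelectionMask([1, 0])]
        with pytest.raises(ValueError, match="exceeds"):
            tournament_select(pop, [0.5], 2, 1, rng)


class TestFitness:
    def test_all_zeros_is_zero(self, rng):
        ft = make_feature_table(rng, n_subjects=5, d=4)
        assert evaluate_fitness(SelectionMask(np.zeros(4, int)), ft, HyperGrid.coarse()) == 0.0

    def test_all_ones_equals_plain_grid_search(self, rng):
        ft = make_feature_table(rng, n_subjects=6, d=4, delta=1.0, planted=(0,))
        grid = HyperGrid.coarse()
        fit = evaluate_fitness(SelectionMask(np.ones(4, int)), ft, grid)
        assert fit == pytest.approx(grid_search(ft, grid=grid).accuracy)


SMALL_GRID = HyperGrid(C_values=(1.0, 16.0), gamma_values=(0.05, 0.5))


class TestRunGA:
    def _table(self, seed=0):
        return make_feature_table(
            np.random.default_rng(seed), n_subjects=8, d=10, delta=2.0, planted=(1, 4, 7)
        )

    def test_seeded_determinism(self):
        ft = self._table()
        cfg = GAConfig(population_size=8, generations=4, rng_seed=11)
        r1 = run_ga(ft, cfg, SMALL_GRID, SMALL_GRID)
        r2 = run_ga(ft, cfg, SMALL_GRID, SMALL_GRID)
        assert np.array_equal(r1.best_mask.bits, r2.best_mask.bits)
        assert r1.best_fitness == r2.best_fitness
        assert r1.fitness_history.equals(r2.fitness_history)

    def test_best_ever_trajectory_non_decreasing(self):
        ft = self._table(1)
        res = run_ga(
            ft, GAConfig(population_size=8, generations=6, rng_seed=2), SMALL_GRID, SMALL_GRID
        )
        best = res.fitness_history["best"].to_numpy()
        assert np.all(np.diff(best) >= 0)

    def test_best_fitness_is_recomputable(self):
        ft = self._table(2)
        res = run_ga(
            ft, GAConfig(population_size=6, generations=3, rng_seed=5), SMALL_GRID, SMALL_GRID
        )
        assert res.best_fitness == pytest.approx(
            evaluate_fitness(res.best_mask, ft, SMALL_GRID)
        )

    def test_selection_cannot_lose_seeded_optimum(self):
        ft = self._table(3)
        planted_mask = SelectionMask.from_indices((1, 4, 7), 10)
        planted_fit = evaluate_fitness(planted_mask, ft, SMALL_GRID)
        pop = [planted_mask] + [
            SelectionMask(np.zeros(10, int)) for _ in range(5)
        ]
        pop[1] = SelectionMask(np.ones(10, int))
        for m in pop[2:]:
            m.bits[0] = 1
        res = run_ga(
            ft,
            GAConfig(
                population_size=6,
                generations=3,
                crossover_rate=0.0,
                mutation_rate=0.0,
                rng_seed=9,
            ),
            SMALL_GRID,
            SMALL_GRID,
            initial_population=pop,
        )
        assert res.best_fitness >= planted_fit


class TestManualSelection:
    def test_identical_condition_tables_select_nothing(self, rng):
        ft = make_feature_table(rng, n_subjects=6, d=5)
        X = ft.X.copy()
        # make condition B identical to condition A per subject
        for s in np.unique(ft.groups):
            rows = np.flatnonzero(ft.groups == s)
            X[rows[1]] = X[rows[0]]
        ft2 = type(ft)(ft.metric_name, X, ft.labels, ft.groups, ft.region_names)
        with pytest.warns(UserWarning, match="no region significant"):
            mask, cv = manual_selection(ft2)
        assert mask.n_selected == 0
        assert cv.accuracy == 0.0

    def test_planted_regions_recovered(self):
        rng = np.random.default_rng(12)
        ft = make_feature_table(
            rng, n_subjects=20, d=12, delta=2.0, planted=(0, 3, 9)
        )
        mask, cv = manual_selection(ft, grid=SMALL_GRID)
        assert {0, 3, 9} <= set(mask.indices().tolist())
        assert cv.accuracy > 0.7


class TestModelInterface:
    def test_ga_model_results_surface(self):
        ft = make_feature_table(
            np.random.default_rng(3), n_subjects=8, d=8, delta=2.0, planted=(2, 5)
        )
        model = GAFeatureSelection(
            ft,
            GAConfig(population_size=6, generations=3, rng_seed=1),
            fitness_grid=SMALL_GRID,
            final_grid=SMALL_GRID,
        )
        res = model.fit()
        assert 0.0 <= res.accuracy <= 1.0
        assert res.selected_regions == [
            ft.region_names[i] for i in res.mask.indices()
        ]
        txt = res.summary()
        assert "LOSOCV accuracy" in txt and ft.metric_name in txt
        d = res.to_dict()
        assert set(d) >= {"accuracy", "cost", "gamma", "selected_regions", "best_fitness"}

    def test_manual_model_results_surface(self):
        ft = make_feature_table(
            np.random.default_rng(4), n_subjects=10, d=8, delta=2.0, planted=(1,)
        )
        res = ManualFeatureSelection(ft, grid=SMALL_GRID).fit()
        assert res.method == "manual"
        assert 1 in res.mask.indices()
        assert "selected regions" in res.summary()

    def test_from_dataframe_constructor(self):
        ft = make_feature_table(np.random.default_rng(5), n_subjects=6, d=5)
        model = ManualFeatureSelection.from_dataframe(ft.to_dataframe())
        assert model.table.d == 5
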
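import numpy as np
import pytest
from scipy import stats

from veh import (
    FitnessConfig,
    HHOConfig,
    VehError,
    evaluate_fitness,
    hho_minimize,
    hho_select,
)
from veh.hho import (
    EnergyState,
    binarize,
    escape_energy,
    exploration_update,
    fitness_from_accuracy,
    hard_besiege,
    hard_besiege_dive,
    initialize_population,
    levy_flight,
    levy_sigma,
    make_knn_fitness,
    repair_empty_mask,
    soft_besiege,
    soft_besiege_dive,
)

CFG = HHOConfig()


class TestEscapeEnergy:
    @pytest.mark.parametrize(
        "E0,t,T,expected",
        [(0.8, 25, 100, 1.2), (0.6, 100, 100, 0.0), (-0.5, 50, 100, -0.5)],
    )
    def test_direct_substitution(self, E0, t, T, expected):
        assert escape_energy(E0, t, T) == pytest.approx(expected)

    def test_zero_iterations_rejected(self):
        with pytest.raises(VehError):
            escape_energy(0.5, 0, 0)


class TestExplorationUpdate:
    def test_zero_r1_returns_random_hawk(self):
        x = np.array([0.2, 0.8])
        x_rand = np.array([0.9, 0.1])
        draws = EnergyState(q=0.7, r1=0.0, r2=0.3)
        out = exploration_update(x, x_rand, x, x, draws, CFG)
        np.testing.assert_allclose(out, x_rand)

    def test_zero_r3_returns_rabbit_minus_mean(self):
        x_rabbit = np.array([0.9, 0.7])
        x_mean = np.array([0.4, 0.9])
        draws = EnergyState(q=0.2, r3=0.0)
        out = exploration_update(x_rabbit, x_rabbit, x_rabbit, x_mean, draws, CFG)
        np.testing.assert_allclose(out, np.clip(x_rabbit - x_mean, 0, 1))

    def test_hand_arithmetic(self):
        # x_rand - r1*|x_rand - 2*r2*x| with the pinned draws below
        x = np.array([0.2, 0.8])
        x_rand = np.array([0.9, 0.1])
        draws = EnergyState(q=0.9, r1=0.5, r2=0.25)
        out = exploration_update(x, x_rand, x, x, draws, CFG)
        np.testing.assert_allclose(out, [0.5, 0.0])

    def test_dimension_mismatch(self):
        with pytest.raises(VehError):
            exploration_update(
                np.zeros(2), np.zeros(3), np.zeros(2), np.zeros(2),
                EnergyState(), CFG,
            )


class TestBesiege:
    def test_soft_zero_energy_moves_to_distance(self):
        x = np.array([0.4, 0.6])
        x_rabbit = np.array([0.8, 0.2])
        out = soft_besiege(x, x_rabbit, E=0.0, r5=0.3)
        np.testing.assert_allclose(out, np.clip(x_rabbit - x, 0, 1))

    def test_soft_hand_arithmetic(self):
        x = np.array([0.4, 0.6])
        x_rabbit = np.array([0.8, 0.2])
        out = soft_besiege(x, x_rabbit, E=0.4, r5=0.5)  # J = 1
        np.testing.assert_allclose(out, [0.24, 0.0])

    def test_soft_zero_jump_strength(self):
        x = np.array([0.3, 0.9])
        x_rabbit = np.array([0.7, 0.5])
        out = soft_besiege(x, x_rabbit, E=0.2, r5=1.0)  # J = 0
        np.testing.assert_allclose(
            out, np.clip((x_rabbit - x) - 0.2 * np.abs(x), 0, 1)
        )

    def test_hard_zero_energy_is_rabbit(self):
        out = hard_besiege(np.array([0.1]), np.array([0.5]), E=0.0)
        np.testing.assert_allclose(out, [0.5])

    def test_hard_hand_arithmetic(self):
        out = hard_besiege(np.array([0.1]), np.array([0.5]), E=0.2)
        np.testing.assert_allclose(out, [0.42])

    def test_hard_fixed_point_at_rabbit(self):
        x_rabbit = np.array([0.3, 0.8])
        out = hard_besiege(x_rabbit.copy(), x_rabbit, E=0.7)
        np.testing.assert_allclose(out, x_rabbit)


class TestLevyFlight:
    def test_deterministic_given_seed(self):
        a = levy_flight(8, 1.5, 0.01, np.random.default_rng(11))
        b = levy_flight(8, 1.5, 0.01, np.random.default_rng(11))
        np.testing.assert_array_equal(a, b)

    def test_mantegna_ratio_from_pinned_draws(self):
        # recompute each element independently from the logged u, v draws
        rng = np.random.default_rng(42)
        out = levy_flight(5, 1.5, 0.01, rng)
        rng2 = np.random.default_rng(42)
        u = rng2.standard_normal(5)
        v = rng2.standard_normal(5)
        expected = 0.01 * u * levy_sigma(1.5) / np.abs(v) ** (1 / 1.5)
        np.testing.assert_allclose(out, expected)

    def test_tail_exponent_near_beta(self):
        # Hill estimator over the top order statistics of 1e5 |draws|
        rng = np.random.default_rng(7)
        draws = np.abs(levy_flight(100_000, 1.5, 1.0, rng))
        top = np.sort(draws)[-2000:]
        hill = 1.0 / np.mean(np.log(top[1:] / top[0]))
        assert abs(hill - 1.5) < 0.2

    def test_invalid_beta(self):
        with pytest.raises(VehError):
            levy_flight(3, 1.0, 0.01, np.random.default_rng(0))


class TestBinarizeRepair:
    def test_half_rounds_up(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.49, 0.5, 1.0])), [0, 1, 1]
        )

    def test_identity_on_binary(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.0, 1.0, 1.0])), [0, 1, 1]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(VehError):
            binarize(np.array([1.2]))

    def test_repair_sets_exactly_one_bit(self):
        rng = np.random.default_rng(0)
        mask, x = repair_empty_mask(np.zeros(5, dtype=np.int8), np.full(5, 0.1), rng)
        assert mask.sum() == 1
        assert x[np.argmax(mask)] == 1.0
        assert (x[mask == 0] == 0.1).all()

    def test_repair_coordinate_uniform(self):
        rng = np.random.default_rng(123)
        D = 5
        counts = np.zeros(D)
        for _ in range(10_000):
            mask, _ = repair_empty_mask(
                np.zeros(D, dtype=np.int8), np.zeros(D), rng
            )
            counts[np.argmax(mask)] += 1
        assert stats.chisquare(counts).pvalue > 0.01


class TestFitness:
    @pytest.mark.parametrize(
        "acc,f_num,F_num,expected",
        [
            (1.0, 5, 100, 0.0005),
            (0.0, 200, 200, 1.0),
            (0.9, 10, 200, 0.0995),
        ],
    )
    def test_hand_arithmetic(self, acc, f_num, F_num, expected):
        assert fitness_from_accuracy(acc, f_num, F_num, 0.99) == pytest.approx(
            expected
        )

    def test_empty_subset_rejected(self):
        with pytest.raises(VehError):
            fitness_from_accuracy(0.5, 0, 10)

    def test_monotone_in_accuracy_and_size(self):
        base = fitness_from_accuracy(0.8, 10, 100)
        assert fitness_from_accuracy(0.9, 10, 100) < base
        assert fitness_from_accuracy(0.8, 5, 100) < base

    def test_perfect_gene_reaches_size_penalty_floor(self, toy):
        ds, _ = toy
        mask = np.zeros(ds.n_genes, dtype=np.int8)
        mask[0] = 1  # the label-encoding gene: KNN_acc = 1
        fit = evaluate_fitness(mask, ds, FitnessConfig(eval_seed=0))
        assert fit == pytest.approx(0.01 * 1 / ds.n_genes)

    def test_cache_transparent(self, toy):
        ds, _ = toy
        rng = np.random.default_rng(5)
        masks = (rng.uniform(size=(10, ds.n_genes)) < 0.3).astype(np.int8)
        masks[:, 0] = 1
        fcfg = FitnessConfig(eval_seed=3)
        cached = make_knn_fitness(ds, fcfg, cache=True)
        plain = make_knn_fitness(ds, fcfg, cache=False)
        for m in masks:
            assert cached(m) == plain(m)
            assert cached(m) == plain(m)  # repeat hits the cache


def popcount_fitness(mask):
    """One-max surrogate: minimized by the all-ones mask (fitness 0)."""
    return 1.0 - mask.sum() / mask.shape[0]


class TestDives:
    def test_accepts_better_first_candidate(self):
        # rabbit at all-ones; E=0 makes Y = rabbit, which scores best
        D = 6
        x = np.full(D, 0.2)
        x[0] = 1.0
        rabbit = np.ones(D)
        out, fout = soft_besiege_dive(
            x, rabbit, x, 0.0, EnergyState(r5=0.5), popcount_fitness,
            CFG, np.random.default_rng(0), fx=popcount_fitness(binarize(x)),
        )
        np.testing.assert_allclose(out, rabbit)
        assert fout == 0.0

    def test_rejection_keeps_position(self):
        # current position is already optimal: nothing can improve
        D = 6
        x = np.ones(D)
        rabbit = np.full(D, 0.4)
        out, fout = soft_besiege_dive(
            x, rabbit, x, 0.9, EnergyState(r5=0.2), popcount_fitness,
            CFG, np.random.default_rng(1), fx=0.0,
        )
        np.testing.assert_array_equal(out, x)
        assert fout == 0.0

    def test_as_printed_hard_dive_equals_soft_dive(self):
        D = 5
        x = np.full(D, 0.3)
        rabbit = np.full(D, 0.8)
        x_mean = np.full(D, 0.6)
        draws = EnergyState(r5=0.4)
        cfg_printed = HHOConfig(dive_variant="as_printed")
        a, _ = soft_besiege_dive(
            x, rabbit, x_mean, 0.3, draws, popcount_fitness,
            cfg_printed, np.random.default_rng(3), fx=0.5,
        )
        b, _ = hard_besiege_dive(
            x, rabbit, x_mean, 0.3, draws, popcount_fitness,
            cfg_printed, np.random.default_rng(3), fx=0.5,
        )
        np.testing.assert_array_equal(a, b)

    def test_original_hard_dive_collapses_when_mean_equals_hawk(self):
        D = 5
        x = np.full(D, 0.3)
        rabbit = np.full(D, 0.8)
        draws = EnergyState(r5=0.4)
        a, _ = soft_besiege_dive(
            x, rabbit, x, 0.3, draws, popcount_fitness,
            CFG, np.random.default_rng(4), fx=0.5,
        )
        b, _ = hard_besiege_dive(
            x, rabbit, x, 0.3, draws, popcount_fitness,
            CFG, np.random.default_rng(4), fx=0.5,
        )
        np.testing.assert_array_equal(a, b)

    def test_greedy_never_worsens(self):
        # candidate-set oracle: outcome fitness <= fitness of the start
        D = 8
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(size=D)
            rabbit = rng.uniform(size=D)
            x_mean = rng.uniform(size=D)
            draws = EnergyState(r5=rng.uniform())
            E = rng.uniform(-1, 1)
            fx = popcount_fitness(binarize(x))
            dive = soft_besiege_dive if seed % 2 else hard_besiege_dive
            out, fout = dive(
                x, rabbit, x_mean, E, draws, popcount_fitness,
                CFG, rng, fx=fx,
            )
            assert fout <= fx


class TestInitializePopulation:
    def test_deterministic_and_bounded(self):
        cfg = HHOConfig(seed=17)
        a = initialize_population(cfg, 10)
        b = initialize_population(cfg, 10)
        for ha, hb in zip(a, b):
            np.testing.assert_array_equal(ha.x, hb.x)
            assert ((ha.x >= 0) & (ha.x <= 1)).all()
            assert ha.mask.sum() >= 1

    def test_uniform_mean(self):
        cfg = HHOConfig(n_hawks=100, seed=3)
        hawks = initialize_population(cfg, 1000)
        coords = np.concatenate([h.x for h in hawks])
        se = np.sqrt(1 / 12 / coords.size)
        assert abs(coords.mean() - 0.5) < 3 * se


class TestHHOMinimize:
    def test_returned_fitness_is_min_over_evaluated_candidates(self):
        log = []

        def logged(mask):
            f = popcount_fitness(mask)
            log.append(f)
            return f

        best, trace = hho_minimize(logged, D=10, cfg=HHOConfig(n_iter=1, seed=2))
        assert best.fitness == min(log)
        assert trace.evaluations == len(log)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_trace_non_increasing(self, seed):
        _, trace = hho_minimize(
            popcount_fitness, D=15, cfg=HHOConfig(n_iter=30, seed=seed)
        )
        assert len(trace.best_fitness_per_iter) == 31
        diffs = np.diff(trace.best_fitness_per_iter)
        assert (diffs <= 0).all()

    def test_one_max_reaches_enumerated_optimum(self):
        # exhaustive-enumeration oracle over all 2^12 masks
        D = 12
        optimum = min(
            popcount_fitness(np.array([(m >> j) & 1 for j in range(D)]))
            for m in range(1, 2**D)
        )
        hits = 0
        for seed in range(20):
            best, _ = hho_minimize(
                popcount_fitness, D=D, cfg=HHOConfig(n_iter=100, seed=seed)
            )
            hits += best.fitness == optimum
        assert hits >= 19  # >= 95% of 20 seeds


class TestHHOSelect:
    def test_recovers_planted_gene_and_is_deterministic(self, toy):
        ds, truth = toy
        hcfg = HHOConfig(n_iter=15, seed=8)
        fcfg = FitnessConfig(eval_seed=8)
        sub1, trace1 = hho_select(ds, hcfg, fcfg)
        sub2, _ = hho_select(ds, hcfg, fcfg)
        assert sub1.feature_ids == sub2.feature_ids
        assert sub1.fitness == sub2.fitness
        assert "g0" in sub1.feature_ids
        assert sub1.fitness < 0.05
        assert set(sub1.feature_ids) <= set(ds.feature_ids)
        assert trace1.best_fitness_per_iter[-1] == sub1.fitness
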
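"""DE/PSO selector mechanics, the 1-NN fitness, and replay oracles.

The oracle tests reimplement the update equations step by step in the test
body and replay the selectors' documented random stream, so any deviation in
draw order or arithmetic fails at 1e-12.
"""

import numpy as np
import pytest

from brainfuse import (DEConfig, FitnessSpec, PSOConfig, SelectionMask,
                       SyntheticFeatureSpec, de_run, decode_mask,
                       knn_error_fitness, make_feature_fixture, pso_run)
from brainfuse.dataio import FeatureMatrix
from brainfuse.optimize import (Candidate, Particle, _one_nn_error,
                                de_crossover, de_initialize, de_mutate,
                                pso_initialize, pso_step)


def _mask(indices, d):
    return SelectionMask(np.isin(np.arange(d), indices))


@pytest.fixture(scope="module")
def tiny_fm():
    """4-column fixture for fast full-trajectory oracle runs."""
    fm, _ = make_feature_fixture(SyntheticFeatureSpec(
        n_per_class=10, d=4, n_informative=2, n_redundant=1, seed=8))
    return fm


class TestDecodeMask:
    def test_all_above_threshold(self):
        assert decode_mask(np.ones(6), 0.5).count == 6

    def test_argmax_fallback_first_index_on_ties(self):
        mask = decode_mask(np.zeros(5), 0.5)
        assert mask.count == 1
        assert mask.indices[0] == 0

    def test_count_matches_brute_force(self, rng):
        for _ in range(20):
            pos = rng.random(40)
            t = rng.uniform(0.1, 0.9)
            expected = sum(1 for v in pos if v > t)
            assert decode_mask(pos, t).count == max(expected, 1)


class TestKnnErrorFitness:
    def test_perfectly_separable_two_classes(self):
        X = np.concatenate([np.zeros(20), np.full(20, 10.0)])[:, None]
        X = X + np.linspace(0, 0.1, 40)[:, None]
        fm = FeatureMatrix(X=X, y=np.repeat(["a", "b"], 20),
                           feature_ids=["f0"])
        err = knn_error_fitness(fm, _mask([0], 1), FitnessSpec(seed=0))
        assert err == 0.0

    def test_random_labels_on_noise_near_chance(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((400, 10))
            y = rng.permutation(np.repeat(["a", "b"], 200))
            fm = FeatureMatrix(X=X, y=y,
                               feature_ids=[f"f{j}" for j in range(10)])
            errs.append(knn_error_fitness(fm, _mask(range(10), 10),
                                          FitnessSpec(seed=seed)))
        assert abs(np.mean(errs) - 0.5) < 0.06

    def test_informative_mask_beats_noise_mask(self, feature_fixture):
        fm, truth = feature_fixture
        spec = FitnessSpec(seed=0)
        e_inf = knn_error_fitness(fm, _mask(truth["informative"], fm.d), spec)
        e_noise = knn_error_fitness(fm, _mask(truth["noise"], fm.d), spec)
        assert e_inf < e_noise

    def test_single_class_fatal(self):
        fm = FeatureMatrix(X=np.random.default_rng(0).random((10, 2)),
                           y=np.repeat(["a"], 10), feature_ids=["f0", "f1"])
        with pytest.raises(ValueError, match="classes"):
            knn_error_fitness(fm, _mask([0], 2), FitnessSpec())

    def test_matches_sklearn_one_nn(self, rng):
        """Dual route: our cdist/argmin 1-NN vs sklearn on the same split."""
        from sklearn.neighbors import KNeighborsClassifier
        X_tr = rng.standard_normal((60, 5))
        y_tr = rng.choice(["a", "b", "c"], 60)
        X_te = rng.standard_normal((30, 5))
        y_te = rng.choice(["a", "b", "c"], 30)
        ours = _one_nn_error(X_tr, y_tr, X_te, y_te, "euclidean")
        mu, sd = X_tr.mean(0), X_tr.std(0)
        knn = KNeighborsClassifier(n_neighbors=1).fit((X_tr - mu) / sd, y_tr)
        theirs = 1.0 - knn.score((X_te - mu) / sd, y_te)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_kfold_scheme(self, feature_fixture):
        fm, truth = feature_fixture
        spec = FitnessSpec(eval_scheme="kfold", folds=4, seed=1)
        err = knn_error_fitness(fm, _mask(truth["informative"], fm.d), spec)
        assert 0.0 <= err <= 1.0


class TestDEPrimitives:
    def test_init_uniform_within_bounds(self):
        rng = np.random.default_rng(0)
        pop = de_initialize(200, DEConfig(population=50), rng)
        flat = np.concatenate([c.position for c in pop])
        assert flat.min() >= 0 and flat.max() <= 1
        assert abs(flat.mean() - 0.5) < 0.02

    def test_degenerate_bounds_collapse(self):
        rng = np.random.default_rng(0)
        pop = de_initialize(5, DEConfig(population=4, bounds=(0.3, 0.3)), rng)
        for c in pop:
            np.testing.assert_array_equal(c.position, np.full(5, 0.3))

    def test_init_deterministic(self):
        a = de_initialize(6, DEConfig(), np.random.default_rng(5))
        b = de_initialize(6, DEConfig(), np.random.default_rng(5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.position, y.position)

    def test_population_too_small_fatal(self):
        with pytest.raises(ValueError, match="population"):
            DEConfig(population=3)

    def test_zero_scale_factor_donors_are_members(self, rng):
        cfg = DEConfig(population=6, scale_factor=0.0)
        pop = de_initialize(4, cfg, rng)
        donors = de_mutate(pop, cfg, rng)
        members = np.array([c.position for c in pop])
        for donor in donors:
            assert any(np.array_equal(donor, m) for m in members)

    def test_identical_population_invariant_under_mutation(self, rng):
        cfg = DEConfig(population=5, scale_factor=0.8)
        base = rng.random(3)
        pop = [Candidate(position=base.copy()) for _ in range(5)]
        donors = de_mutate(pop, cfg, rng)
        for donor in donors:
            np.testing.assert_allclose(donor, base, atol=1e-15)

    def test_mutation_matches_scripted_oracle(self):
        cfg = DEConfig(population=5, scale_factor=0.2)
        rng_impl = np.random.default_rng(77)
        pop = de_initialize(3, cfg, rng_impl)
        donors = de_mutate(pop, cfg, rng_impl)

        rng_oracle = np.random.default_rng(77)
        positions = rng_oracle.random((5, 3))  # replay initialization
        for i in range(5):
            others = np.delete(np.arange(5), i)
            r1, r2, r3 = rng_oracle.choice(others, size=3, replace=False)
            expected = np.clip(positions[r1]
                               + 0.2 * (positions[r2] - positions[r3]), 0, 1)
            np.testing.assert_allclose(donors[i], expected, atol=1e-12)

    def test_crossover_cr_one_takes_donor(self, rng):
        target = Candidate(position=np.zeros(6))
        donor = np.ones(6)
        trial = de_crossover(target, donor, DEConfig(crossover_rate=1.0), rng)
        np.testing.assert_array_equal(trial, donor)

    def test_crossover_cr_zero_takes_target_except_jrand(self, rng):
        target = Candidate(position=np.zeros(6))
        donor = np.ones(6)
        trial = de_crossover(target, donor, DEConfig(crossover_rate=0.0), rng)
        assert trial.sum() == 1.0  # exactly one coordinate from the donor

    def test_crossover_pattern_matches_oracle(self):
        d, cr = 6, 0.7
        target = Candidate(position=np.zeros(d))
        donor = np.ones(d)
        trial = de_crossover(target, donor, DEConfig(crossover_rate=cr),
                             np.random.default_rng(13))
        rng_oracle = np.random.default_rng(13)
        jrand = int(rng_oracle.integers(d))
        draws = rng_oracle.random(d)
        expected = np.where((draws <= cr) | (np.arange(d) == jrand), 1.0, 0.0)
        np.testing.assert_array_equal(trial, expected)


class TestDERun:
    def test_zero_generations_returns_initial_best(self, tiny_fm):
        cfg = DEConfig(population=6, max_generations=0, seed=21)
        spec = FitnessSpec(seed=4)
        result = de_run(tiny_fm, cfg, spec)
        # replay the initialization and pick the best by hand
        pop = de_initialize(tiny_fm.d, cfg, np.random.default_rng(21))
        fits = [knn_error_fitness(tiny_fm,
                                  decode_mask(c.position, 0.5), spec)
                for c in pop]
        assert result.best_fitness == min(fits)
        best = pop[int(np.argmin(fits))]
        np.testing.assert_array_equal(
            result.mask.selected, decode_mask(best.position, 0.5).selected)

    def test_full_trajectory_matches_scripted_oracle(self, tiny_fm):
        """Step-by-step DE oracle sharing the random stream, 3 generations."""
        cfg = DEConfig(population=6, max_generations=3, seed=5)
        spec = FitnessSpec(seed=9)
        result = de_run(tiny_fm, cfg, spec)

        rng = np.random.default_rng(5)
        pos = rng.random((6, tiny_fm.d))

        def fit(p):
            return knn_error_fitness(tiny_fm, decode_mask(p, 0.5), spec)

        fits = np.array([fit(p) for p in pos])
        trace = [fits.min()]
        for _ in range(3):
            donors = np.empty_like(pos)
            for i in range(6):
                others = np.delete(np.arange(6), i)
                r1, r2, r3 = rng.choice(others, size=3, replace=False)
                donors[i] = np.clip(pos[r1] + cfg.scale_factor
                                    * (pos[r2] - pos[r3]), 0, 1)
            for i in range(6):
                jrand = int(rng.integers(tiny_fm.d))
                draws = rng.random(tiny_fm.d)
                take = (draws <= cfg.crossover_rate) | \
                       (np.arange(tiny_fm.d) == jrand)
                trial = np.where(take, donors[i], pos[i])
                tf = fit(trial)
                if tf <= fits[i]:
                    pos[i], fits[i] = trial, tf
            trace.append(fits.min())
        np.testing.assert_allclose(result.trace, trace, atol=1e-12)
        best = pos[int(np.argmin(fits))]
        np.testing.assert_array_equal(
            result.mask.selected, decode_mask(best, 0.5).selected)

    def test_trace_non_increasing_and_determinism(self, tiny_fm):
        cfg = DEConfig(population=8, max_generations=10, seed=3)
        spec = FitnessSpec(seed=2)
        a = de_run(tiny_fm, cfg, spec)
        b = de_run(tiny_fm, cfg, spec)
        assert a.trace == b.trace
        assert np.all(np.diff(a.trace) <= 0)
        np.testing.assert_array_equal(a.mask.selected, b.mask.selected)


class TestPSOPrimitives:
    def test_init_zero_velocity(self):
        swarm = pso_initialize(100, PSOConfig(population=50),
                               np.random.default_rng(0))
        assert len(swarm) == 50
        for p in swarm:
            assert np.all(p.velocity == 0)

    def test_init_within_bounds(self):
        swarm = pso_initialize(200, PSOConfig(population=50),
                               np.random.default_rng(1))
        flat = np.concatenate([p.position for p in swarm])
        assert flat.min() >= 0 and flat.max() <= 1

    def test_init_deterministic(self):
        a = pso_initialize(5, PSOConfig(), np.random.default_rng(6))
        b = pso_initialize(5, PSOConfig(), np.random.default_rng(6))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.position, y.position)

    def test_population_too_small_fatal(self):
        with pytest.raises(ValueError, match="population"):
            PSOConfig(population=1)

    def test_frozen_swarm(self, tiny_fm, rng):
        cfg = PSOConfig(population=3, inertia=0.0, cognitive=0.0, social=0.0)
        spec = FitnessSpec(seed=0)
        swarm = pso_initialize(tiny_fm.d, cfg, rng)
        for p in swarm:
            p.fitness = p.best_fitness = 0.5
            p.best_position = p.position.copy()
        before = [p.position.copy() for p in swarm]
        pso_step(swarm, cfg, spec, tiny_fm, rng)
        for p, b in zip(swarm, before):
            np.testing.assert_array_equal(p.position, b)
            assert np.all(p.velocity == 0)

    def test_particle_at_global_best_is_stationary(self, tiny_fm, rng):
        cfg = PSOConfig(population=2)
        spec = FitnessSpec(seed=0)
        leader = Particle(position=np.full(tiny_fm.d, 0.9),
                          velocity=np.zeros(tiny_fm.d))
        leader.best_position = leader.position.copy()
        leader.fitness = leader.best_fitness = 0.0
        trailer = Particle(position=np.full(tiny_fm.d, 0.1),
                           velocity=np.zeros(tiny_fm.d))
        trailer.best_position = trailer.position.copy()
        trailer.fitness = trailer.best_fitness = 0.9
        pso_step([leader, trailer], cfg, spec, tiny_fm, rng)
        np.testing.assert_array_equal(leader.position, np.full(tiny_fm.d, 0.9))
        assert np.all(leader.velocity == 0)

    def test_step_matches_scripted_oracle(self, tiny_fm):
        """Two velocity/position updates replayed against the inertia form."""
        cfg = PSOConfig(population=3, seed=31, max_generations=2)
        spec = FitnessSpec(seed=6)
        result = pso_run(tiny_fm, cfg, spec)

        rng = np.random.default_rng(31)
        d = tiny_fm.d
        pos = rng.random((3, d))
        vel = np.zeros((3, d))

        def fit(p):
            return knn_error_fitness(tiny_fm, decode_mask(p, 0.5), spec)

        pbest = pos.copy()
        pfit = np.array([fit(p) for p in pos])
        trace = [pfit.min()]
        for _ in range(2):
            gb = pbest[int(np.argmin(pfit))]
            for i in range(3):
                r1, r2 = rng.random(d), rng.random(d)
                vel[i] = (cfg.inertia * vel[i]
                          + cfg.cognitive * r1 * (pbest[i] - pos[i])
                          + cfg.social * r2 * (gb - pos[i]))
                vel[i] = np.clip(vel[i], -cfg.velocity_clamp,
                                 cfg.velocity_clamp)
                pos[i] = np.clip(pos[i] + vel[i], 0, 1)
            for i in range(3):
                f = fit(pos[i])
                if f < pfit[i]:
                    pfit[i], pbest[i] = f, pos[i].copy()
            trace.append(pfit.min())
        np.testing.assert_allclose(result.trace, trace, atol=1e-12)
        gb = pbest[int(np.argmin(pfit))]
        np.testing.assert_array_equal(result.mask.selected,
                                      decode_mask(gb, 0.5).selected)


class TestPSORun:
    def test_zero_generations_decodes_initial_best(self, tiny_fm):
        cfg = PSOConfig(population=5, max_generations=0, seed=17)
        spec = FitnessSpec(seed=3)
        result = pso_run(tiny_fm, cfg, spec)
        swarm = pso_initialize(tiny_fm.d, cfg, np.random.default_rng(17))
        fits = [knn_error_fitness(tiny_fm, decode_mask(p.position, 0.5), spec)
                for p in swarm]
        best = swarm[int(np.argmin(fits))]
        np.testing.assert_array_equal(
            result.mask.selected, decode_mask(best.position, 0.5).selected)
        assert result.best_fitness == min(fits)

    def test_deterministic_replay(self, tiny_fm):
        cfg = PSOConfig(population=6, max_generations=8, seed=2)
        spec = FitnessSpec(seed=1)
        a = pso_run(tiny_fm, cfg, spec)
        b = pso_run(tiny_fm, cfg, spec)
        assert a.trace == b.trace
        assert a.to_dict() == b.to_dict()

    def test_trace_non_increasing(self, tiny_fm):
        result = pso_run(tiny_fm, PSOConfig(population=6, max_generations=10,
                                            seed=0), FitnessSpec(seed=0))
        assert np.all(np.diff(result.trace) <= 0)


class TestSelectionBeatsRandomMasks:
    def test_selector_fitness_below_random_mask_mean(self, feature_fixture):
        fm, _ = feature_fixture
        spec = FitnessSpec(seed=0)
        result = de_run(fm, DEConfig(population=20, max_generations=15,
                                     seed=1), spec)
        rng = np.random.default_rng(100)
        rand_fits = []
        for _ in range(50):
            idx = rng.choice(fm.d, size=result.mask.count, replace=False)
            rand_fits.append(knn_error_fitness(
                fm, SelectionMask(np.isin(np.arange(fm.d), idx)), spec))
        assert result.best_fitness < np.mean(rand_fits)
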
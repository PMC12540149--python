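"""Osprey optimizer: hand fixtures, a scripted-RNG trace oracle, bound and
monotonicity invariants, and a random-search sanity baseline."""

import numpy as np
import pytest

from laryngofuse.autoencoder import AEHyperparams
from laryngofuse.ooa import (
    FitnessSpec,
    OOAState,
    SearchSpace,
    exploitation_step,
    exploration_step,
    fish_set,
    init_population,
    optimize,
    tune_ae_hyperparams,
)


class ScriptedRNG:
    """Replays queued draws; sizes must match the algorithm's requests."""

    def __init__(self, uniforms, integers):
        self.uniforms = list(uniforms)
        self.ints = list(integers)

    def random(self, size=None):
        out = np.asarray(self.uniforms.pop(0), dtype=float)
        assert (np.shape(out) == ()) if size is None else out.shape == tuple(np.atleast_1d(size))
        return out

    def integers(self, low, high, size=None):
        out = np.asarray(self.ints.pop(0))
        assert np.all((out >= low) & (out < high))
        return out if size is not None else int(out)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def make_state(os, space, objective=sphere, rng=None, t=1):
    os = np.asarray(os, dtype=float)
    fitness = FitnessSpec(objective)
    ff = np.array([fitness.evaluate(x) for x in os])
    best = int(np.argmin(ff))
    return OOAState(os=os, ff=ff, os_best=os[best].copy(), ff_best=float(ff[best]),
                    t=t, T=1, space=space, fitness=fitness,
                    rng=rng or np.random.default_rng(0))


class TestFishSet:
    def test_enumerated_fixture(self):
        space = SearchSpace(np.array([-3.0]), np.array([3.0]))
        state = make_state([[np.sqrt(3)], [1.0], [np.sqrt(2)]], space)  # FF = (3, 1, 2)
        np.testing.assert_array_equal(fish_set(state, 0), [1, 2])

    def test_best_member_sees_only_itself(self):
        space = SearchSpace(np.array([-3.0]), np.array([3.0]))
        state = make_state([[2.0], [1.0], [0.5]], space)
        np.testing.assert_array_equal(fish_set(state, 2), [2])

    def test_ties_excluded_by_strictness(self):
        space = SearchSpace(np.array([-3.0]), np.array([3.0]))
        state = make_state([[1.0], [1.0], [-1.0], [1.0]], space)  # all FF = 1
        for i in range(4):
            np.testing.assert_array_equal(fish_set(state, i), [0])


class TestSteps:
    def test_exploration_hand_fixture(self):
        # 1-d sphere: x = 2 moving toward fish 0 with r = 1, I = 1 lands at 0
        space = SearchSpace(np.array([-5.0]), np.array([5.0]))
        rng = ScriptedRNG(uniforms=[[1.0]], integers=[0, [1]])
        state = make_state([[2.0], [0.0]], space, rng=rng)
        exploration_step(state, 0)
        assert state.os[0, 0] == 0.0
        assert state.ff[0] == 0.0

    def test_exploration_accepts_only_strict_improvement(self):
        space = SearchSpace(np.array([-5.0]), np.array([5.0]))
        # candidate 1 + 1*(0 - 2*1) = -1, same fitness as 1 -> rejected
        rng = ScriptedRNG(uniforms=[[1.0]], integers=[0, [2]])
        state = make_state([[1.0], [0.0]], space, rng=rng)
        exploration_step(state, 0)
        assert state.os[0, 0] == 1.0

    def test_exploitation_offset_is_inverse_iteration_scaled(self):
        space = SearchSpace(np.array([0.0]), np.array([1.0]))
        seen = []

        def spy(x):
            seen.append(x.copy())
            return sphere(x)

        rng = ScriptedRNG(uniforms=[[0.5]], integers=[])
        state = make_state([[0.3], [0.4]], space, objective=spy, rng=rng, t=10)
        seen.clear()
        exploitation_step(state, 0)
        np.testing.assert_allclose(seen[0], [0.35])  # 0.3 + (0 + 0.5*1)/10

    def test_candidates_clipped_exactly_to_bounds(self):
        space = SearchSpace(np.array([0.0]), np.array([1.0]))
        seen = []

        def spy(x):
            seen.append(x.copy())
            return -float(x[0])  # reward moving up so the clip is observable

        rng = ScriptedRNG(uniforms=[[1.0]], integers=[])
        state = make_state([[0.9], [0.95]], space, objective=spy, rng=rng, t=1)
        seen.clear()
        exploitation_step(state, 0)  # 0.9 + (0 + 1)/1 = 1.9 -> clipped to 1.0
        np.testing.assert_allclose(seen[0], [1.0])
        assert state.os[0, 0] == 1.0


def test_scripted_iteration_matches_hand_trace():
    """One full iteration (explore + exploit per member, n=3, m=2) replayed
    against an independent straight-line transcription of the update rules."""
    lb, ub = np.array([-2.0, -2.0]), np.array([2.0, 2.0])
    space = SearchSpace(lb, ub)
    os0 = np.array([[1.0, 1.0], [-0.5, 1.5], [0.25, -0.25]])

    draws_u = [[0.3, 0.8], [0.6, 0.1], [0.9, 0.2], [0.5, 0.5], [0.1, 0.7], [0.25, 0.75]]
    draws_i = [0, [1, 2], 1, [2, 1], 0, [1, 1]]

    # package run
    rng = ScriptedRNG([list(u) for u in draws_u], [d if np.ndim(d) else d for d in draws_i])
    state = make_state(os0.copy(), space, rng=rng, t=1)
    for i in range(3):
        exploration_step(state, i)
        exploitation_step(state, i)

    # independent trace
    os = os0.copy()
    ff = np.array([sphere(x) for x in os])
    u = [np.array(x) for x in draws_u]
    ii = list(draws_i)
    for i in range(3):
        best = int(np.argmin(ff))
        fs = np.unique(np.append(np.flatnonzero(ff < ff[i]), best))
        cf = os[fs[ii.pop(0)]]
        r = u.pop(0)
        I = np.array(ii.pop(0), dtype=float)
        cand = np.clip(os[i] + r * (cf - I * os[i]), lb, ub)
        f = sphere(cand)
        if f < ff[i]:
            os[i], ff[i] = cand, f
        r = u.pop(0)
        cand = np.clip(os[i] + (lb + r * (ub - lb)) / 1.0, lb, ub)
        f = sphere(cand)
        if f < ff[i]:
            os[i], ff[i] = cand, f

    np.testing.assert_allclose(state.os, os, atol=1e-12)
    np.testing.assert_allclose(state.ff, ff, atol=1e-12)


class TestOptimize:
    def test_init_population_within_bounds_and_deterministic(self):
        space = SearchSpace(np.array([-1.0, 0.0]), np.array([2.0, 5.0]))
        s1 = init_population(FitnessSpec(sphere), space, n=8, seed=3)
        s2 = init_population(FitnessSpec(sphere), space, n=8, seed=3)
        np.testing.assert_array_equal(s1.os, s2.os)
        assert np.all((s1.os >= space.lb) & (s1.os <= space.ub))
        assert s1.ff_best == s1.ff.min()

    def test_invalid_inputs(self):
        space = SearchSpace(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="population size"):
            init_population(FitnessSpec(sphere), space, n=1)
        with pytest.raises(ValueError, match="T must be >= 1"):
            optimize(sphere, space, n=4, T=0)
        with pytest.raises(ValueError, match="strictly below"):
            SearchSpace(np.array([1.0]), np.array([1.0]))

    def test_nonfinite_objective_named(self):
        space = SearchSpace(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="non-finite"):
            optimize(lambda x: float("nan"), space, n=4, T=1, seed=0)

    def test_single_iteration_contract(self):
        space = SearchSpace(np.full(3, -4.0), np.full(3, 4.0))
        init = init_population(FitnessSpec(sphere), space, n=6, seed=9)
        res = optimize(sphere, space, n=6, T=1, seed=9)
        assert np.all((res.best_position >= space.lb) & (res.best_position <= space.ub))
        assert res.best_fitness <= init.ff_best

    def test_history_monotone_and_bounds_held(self):
        space = SearchSpace(np.full(4, -3.0), np.full(4, 3.0))
        res = optimize(sphere, space, n=10, T=25, seed=1)
        assert np.all(np.diff(res.history["best_fitness"]) <= 1e-15)
        assert np.all((res.state.os >= space.lb) & (res.state.os <= space.ub))

    def test_per_member_fitness_never_increases(self):
        space = SearchSpace(np.full(2, -3.0), np.full(2, 3.0))
        fitness = FitnessSpec(sphere)
        state = init_population(fitness, space, n=6, seed=4)
        for t in range(1, 11):
            state.t = t
            before = state.ff.copy()
            for i in range(6):
                exploration_step(state, i)
                exploitation_step(state, i)
            assert np.all(state.ff <= before + 1e-15)

    @pytest.mark.parametrize("objective", [
        sphere,
        lambda x: float(10 * len(x) + np.sum(x**2 - 10 * np.cos(2 * np.pi * x))),  # Rastrigin
    ], ids=["sphere", "rastrigin"])
    def test_beats_random_search_at_equal_budget(self, objective):
        space = SearchSpace(np.full(2, -5.12), np.full(2, 5.12))
        n, T = 10, 20
        budget = n + 2 * n * T
        ooa_best, rand_best = [], []
        for seed in range(10):
            res = optimize(objective, space, n=n, T=T, seed=seed)
            ooa_best.append(res.best_fitness)
            rng = np.random.default_rng([seed, 77])
            xs = space.lb + rng.random((budget, 2)) * (space.ub - space.lb)
            rand_best.append(min(objective(x) for x in xs))
        assert np.median(ooa_best) < np.median(rand_best)

    def test_maximization_by_negation(self):
        space = SearchSpace(np.array([-1.0]), np.array([1.0]))
        res = optimize(FitnessSpec(lambda x: -sphere(x), direction="maximize"),
                       space, n=6, T=20, seed=2)
        assert res.best_fitness == pytest.approx(0.0, abs=1e-3)
        assert np.all(np.diff(res.history["best_fitness"]) >= -1e-15)


class TestTuning:
    def blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(4, 10)) * 8
        X = np.concatenate([c + 0.5 * rng.normal(size=(12, 10)) for c in centers])
        y = np.repeat(np.arange(4), 12)
        order = rng.permutation(48)
        return X[order], y[order]

    def test_tuned_hyperparams_within_bounds(self):
        X, y = self.blobs()
        dims = [
            {"name": "latent_dim", "low": 2, "high": 6, "type": "int"},
            {"name": "learning_rate", "low": 1e-3, "high": 1e-2, "type": "float"},
            {"name": "batch_size", "low": 8, "high": 16, "type": "int"},
            {"name": "dropout", "low": 0.0, "high": 0.3, "type": "float"},
        ]
        best, result = tune_ae_hyperparams(X[:32], y[:32], X[32:], y[32:],
                                           dims=dims, n=2, T=2, seed=0, ae_epochs=15)
        assert isinstance(best, AEHyperparams)
        assert 2 <= best.latent_dim <= 6 and isinstance(best.latent_dim, int)
        assert 1e-3 <= best.learning_rate <= 1e-2
        assert 8 <= best.batch_size <= 16 and isinstance(best.batch_size, int)
        assert 0.0 <= best.dropout <= 0.3
        # maximization: per-iteration best validation fitness never decreases
        assert np.all(np.diff(result.history["best_fitness"]) >= -1e-15)
        assert 0.0 <= result.best_fitness <= 1.0

    def test_failing_candidates_scored_worst_and_search_continues(self):
        X, y = self.blobs(seed=1)
        # latent bounds above the feature dimension force training failures
        dims = [{"name": "latent_dim", "low": 50, "high": 60, "type": "int"}]
        with pytest.warns(UserWarning, match="worst-possible"):
            best, result = tune_ae_hyperparams(X[:32], y[:32], X[32:], y[32:],
                                               dims=dims, n=2, T=1, seed=0, ae_epochs=5)
        assert result.best_fitness == 0.0

    def test_unknown_metric_rejected(self):
        X, y = self.blobs()
        with pytest.raises(ValueError, match="fitness_metric"):
            tune_ae_hyperparams(X, y, X, y, fitness_metric="f1")
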
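"""Unit and property tests for the whale optimizer and its strategies."""

import math

import numpy as np
import pytest
from scipy import stats

from kapurseg.optimizer import (
    SearchSpace,
    StrategyConfig,
    VARIANT_FLAGS,
    adn_agents,
    adn_step_update,
    clamp_bounds,
    cos_transform,
    cosi_initialize,
    greedy_merge,
    gs_update,
    lhs_sequence,
    optimize,
    random_initialize,
    variant_config,
    woa_phase_update,
)


class FakeRng:
    """Scripted generator: yields preset scalars/arrays in call order."""

    def __init__(self, values):
        self.values = list(values)

    def _next(self, size=None):
        v = self.values.pop(0)
        if size is None:
            return v
        return np.broadcast_to(np.asarray(v, dtype=float), size).copy()

    def random(self, size=None):
        return self._next(size)

    def uniform(self, lo, hi, size=None):
        return self._next(size)

    def integers(self, *args, **kwargs):
        return int(self._next())

    def choice(self, a, size=None, replace=True):
        return np.asarray([self._next() for _ in range(size)], dtype=int)


# ---------------------------------------------------------------------------
# initialization


@pytest.mark.parametrize("n", [1, 2, 7, 30, 100])
@pytest.mark.parametrize("dim", [1, 5, 30])
def test_lhs_one_sample_per_stratum(n, dim):
    rng = np.random.default_rng(42)
    p = lhs_sequence(n, dim, rng)
    assert p.shape == (n, dim)
    assert np.all((p > 0) & (p < 1))
    for j in range(dim):
        assert sorted(np.floor(n * p[:, j]).astype(int)) == list(range(n))


def test_lhs_rejects_bad_arguments():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        lhs_sequence(0, 2, rng)
    with pytest.raises(ValueError):
        lhs_sequence(3, 0, rng)


def test_lhs_beats_plain_uniform_on_ks_distance():
    """Stratification gives lower average KS distance to U(0,1) than i.i.d.
    draws of the same size (Monte-Carlo comparison over 50 seeds)."""
    n, n_seeds = 100, 50
    lhs_ks, unif_ks = [], []
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        p = lhs_sequence(n, 2, rng)
        u = np.random.default_rng(10_000 + seed).random((n, 2))
        for j in range(2):
            lhs_ks.append(stats.kstest(p[:, j], "uniform").statistic)
            unif_ks.append(stats.kstest(u[:, j], "uniform").statistic)
    assert np.mean(lhs_ks) <= np.mean(unif_ks)


def test_cos_transform_closed_forms():
    # p = 0.5 hits the upper bound regardless of b
    assert cos_transform(0.5, 0.7, 0.0, 10.0) == pytest.approx(10.0)
    # p = 1, b = 1: cos(-pi/2) = 0 -> lower bound
    assert cos_transform(1.0, 1.0, 0.0, 10.0) == pytest.approx(0.0, abs=1e-12)
    # p = 0.25, b = 1: cos(pi/4)
    assert cos_transform(0.25, 1.0, 0.0, 1.0) == pytest.approx(math.cos(math.pi / 4))


@pytest.mark.parametrize("init", [cosi_initialize, random_initialize])
def test_initializers_respect_bounds(init):
    space = SearchSpace(dim=4, lb=[-3, 0, 5, -1], ub=[-1, 2, 50, 1], max_evals=100)
    pos = init(space, 25, np.random.default_rng(7))
    assert pos.shape == (25, 4)
    assert np.all(pos >= space.lb) and np.all(pos <= space.ub)
    with pytest.raises(ValueError):
        init(space, 0, np.random.default_rng(0))


def test_random_initialize_mean_near_center():
    space = SearchSpace(dim=3, lb=0.0, ub=1.0, max_evals=10)
    pos = random_initialize(space, 1000, np.random.default_rng(1))
    assert np.all(np.abs(pos.mean(axis=0) - 0.5) < 0.05)


# ---------------------------------------------------------------------------
# per-individual update phases


def test_woa_encircle_with_zero_A_returns_best():
    # coin < 0.5 selects shrink branch; r1 = 0.5 makes A = 0 in every dim
    rng = FakeRng([0.3, 0.5, 0.7, 0])
    best = np.array([1.0, 2.0])
    out = woa_phase_update(np.array([5.0, 5.0]), best, np.array([[0.0, 0.0]]), 1.0, rng)
    np.testing.assert_allclose(out, best)


def test_woa_spiral_at_best_stays_at_best():
    rng = FakeRng([0.9, 0.37])  # coin >= 0.5 -> spiral; l = 0.37
    best = np.array([3.0, -2.0])
    out = woa_phase_update(best.copy(), best, np.array([[0.0, 0.0]]), 1.0, rng)
    np.testing.assert_allclose(out, best)


def test_woa_search_branch_hand_example():
    # X = (0,0), X_rand = (1,1), A = 2, C = 1 -> D = (1,1), X' = (-1,-1)
    rng = FakeRng([0.3, 1.0, 0.5, 0])
    pop = np.array([[1.0, 1.0]])
    out = woa_phase_update(np.zeros(2), np.array([9.0, 9.0]), pop, 2.0, rng)
    np.testing.assert_allclose(out, [-1.0, -1.0])


def test_woa_requires_nonempty_population():
    with pytest.raises(RuntimeError):
        woa_phase_update(np.zeros(2), np.zeros(2), np.empty((0, 2)), 1.0, FakeRng([0.3]))


def test_gs_zero_weight_returns_best():
    pop = np.arange(12.0).reshape(4, 3)
    best = np.array([9.0, 9.0, 9.0])
    out = gs_update(pop[0], best, pop, 0, 10, 100, FakeRng([0.0, 1, 2]))
    np.testing.assert_allclose(out, best)


def test_gs_identical_random_members_returns_best():
    pop = np.zeros((4, 3))
    best = np.array([1.0, 2.0, 3.0])
    out = gs_update(pop[0], best, pop, 0, 50, 100, FakeRng([0.8, 1, 2]))
    np.testing.assert_allclose(out, best)


def test_gs_weight_reaches_2e_at_budget_end():
    pop = np.zeros((4, 2))
    pop[1] = [1.0, 1.0]  # rand1 - rand2 = (1, 1)
    out = gs_update(pop[0], np.zeros(2), pop, 0, 100, 100, FakeRng([1.0, 1, 2]))
    np.testing.assert_allclose(out, 2 * (2 * math.e) * np.ones(2))


def test_gs_requires_three_members():
    with pytest.raises(RuntimeError):
        gs_update(np.zeros(2), np.zeros(2), np.zeros((2, 2)), 0, 0, 10, FakeRng([0.5]))


def test_adn_agents_enumeration():
    agents = adn_agents(np.array([5.0, 5.0]), np.array([1.0, 1.0]), 2)
    assert agents.shape == (4, 2)
    got = {tuple(a) for a in agents}
    assert got == {(6.0, 5.0), (4.0, 5.0), (5.0, 6.0), (5.0, 4.0)}


def test_adn_agents_zero_step_and_count():
    best = np.array([1.0, 2.0, 3.0])
    agents = adn_agents(best, np.zeros(3), 3)
    assert np.all(agents == best)
    assert adn_agents(np.array([0.0]), np.array([0.5]), 1).shape == (2, 1)


def test_adn_step_shrinks_then_reexpands():
    space = SearchSpace(dim=1, lb=0.0, ub=1.0, max_evals=10)
    cfg = StrategyConfig(L0_frac=1.0, shrink_s=0.5, Lmin_frac=0.1)
    rng = np.random.default_rng(0)
    out = adn_step_update(np.array([0.5]), cfg, space, False, rng)
    np.testing.assert_allclose(out, [0.25])
    # below Lmin after shrink -> reinitialized within (0, L0]
    out = adn_step_update(np.array([0.05]), cfg, space, False, rng)
    assert 0.0 <= out[0] <= 1.0 and out[0] != 0.025


def test_adn_step_never_stays_below_min_twice():
    space = SearchSpace(dim=3, lb=0.0, ub=10.0, max_evals=10)
    cfg = StrategyConfig(L0_frac=0.1, shrink_s=0.5, Lmin_frac=1e-3)
    rng = np.random.default_rng(3)
    L = cfg.L0_frac * space.range
    below_prev = np.zeros(3, dtype=bool)
    for _ in range(100):
        L = adn_step_update(L, cfg, space, False, rng)
        below = L < cfg.Lmin_frac * space.range
        assert not np.any(below & below_prev)
        below_prev = below


def test_greedy_merge_sort_truncate_oracle():
    pos = np.array([[1.0], [2.0], [3.0]])
    fit = np.array([1.0, 2.0, 3.0])
    cand = np.array([[0.5], [2.5]])
    cfit = np.array([0.5, 2.5])
    new_pos, new_fit = greedy_merge(pos, fit, cand, cfit)
    assert sorted(new_fit) == [0.5, 1.0, 2.0]
    # all candidates worse -> unchanged
    new_pos, new_fit = greedy_merge(pos, fit, cand, np.array([9.0, 9.0]))
    np.testing.assert_allclose(np.sort(new_fit), fit)


def test_greedy_merge_incumbents_win_ties():
    pos = np.array([[1.0], [2.0]])
    fit = np.array([1.0, 2.0])
    cand = np.array([[99.0]])
    new_pos, new_fit = greedy_merge(pos, fit, cand, np.array([2.0]))
    assert 99.0 not in new_pos


def test_clamp_bounds_projection():
    space = SearchSpace(dim=3, lb=0.0, ub=10.0, max_evals=10)
    np.testing.assert_allclose(
        clamp_bounds(np.array([5.0, 15.0, -5.0]), space), [5.0, 10.0, 0.0]
    )


# ---------------------------------------------------------------------------
# full optimizer


def sphere(x):
    return float(x @ x)


def test_optimize_constant_objective_flat_trace():
    space = SearchSpace(dim=3, lb=-1.0, ub=1.0, max_evals=500)
    best, trace = optimize(lambda x: 0.0, space, 10, StrategyConfig(seed=1))
    assert best.fitness == 0.0
    assert set(trace.best_fitness_per_iteration) == {0.0}


def test_optimize_sphere_reaches_small_values():
    space = SearchSpace(dim=10, lb=-100.0, ub=100.0, max_evals=30_000)
    finals = [
        optimize(sphere, space, 30, StrategyConfig(seed=s))[0].fitness
        for s in range(10)
    ]
    assert np.median(finals) < 1e-3


@pytest.mark.parametrize("variant", sorted(VARIANT_FLAGS))
def test_trace_monotone_and_budget_for_every_variant(variant):
    space = SearchSpace(dim=5, lb=-10.0, ub=10.0, max_evals=2_000)
    calls = 0

    def counted(x):
        nonlocal calls
        calls += 1
        assert np.all(x >= space.lb - 1e-12) and np.all(x <= space.ub + 1e-12)
        return sphere(x)

    best, trace = optimize(counted, space, 12, variant_config(variant, seed=3))
    diffs = np.diff(trace.best_fitness_per_iteration)
    assert np.all(diffs <= 0)
    assert calls == trace.evals_per_iteration[-1] <= space.max_evals
    assert best.fitness == trace.best_fitness_per_iteration[-1]


def test_optimize_is_deterministic():
    space = SearchSpace(dim=4, lb=-5.0, ub=5.0, max_evals=1_500)
    cfg = StrategyConfig(seed=11)
    b1, t1 = optimize(sphere, space, 10, cfg)
    b2, t2 = optimize(sphere, space, 10, cfg)
    np.testing.assert_array_equal(b1.position, b2.position)
    assert b1.fitness == b2.fitness
    assert t1.best_fitness_per_iteration == t2.best_fitness_per_iteration
    assert t1.evals_per_iteration == t2.evals_per_iteration


def test_optimize_rejects_budget_below_population():
    space = SearchSpace(dim=2, lb=0.0, ub=1.0, max_evals=5)
    with pytest.raises(ValueError):
        optimize(sphere, space, 10, StrategyConfig(seed=0))


def test_non_finite_objective_treated_as_worst():
    space = SearchSpace(dim=2, lb=-1.0, ub=1.0, max_evals=300)

    def spiky(x):
        return math.nan if x[0] > 0 else sphere(x)

    best, _ = optimize(spiky, space, 8, StrategyConfig(seed=2))
    assert math.isfinite(best.fitness)
    assert best.position[0] <= 0


def test_exactly_eight_distinct_variants():
    assert len(VARIANT_FLAGS) == 8
    assert len(set(VARIANT_FLAGS.values())) == 8
    assert VARIANT_FLAGS["CAGWOA"] == (True, True, True)
    assert VARIANT_FLAGS["WOA"] == (False, False, False)
    with pytest.raises(ValueError):
        variant_config("XWOA")


def test_oracle_equivalence_on_enumerable_1d_domain():
    """On a 64-value 1-D staircase objective the optimizer matches the
    enumerated global optimum in nearly every seeded run."""
    rng = np.random.default_rng(99)
    table = rng.random(64)
    target = float(table.min())

    def staircase(x):
        return float(table[int(np.clip(round(x[0]), 0, 63))])

    space = SearchSpace(dim=1, lb=0.0, ub=63.0, max_evals=640)
    hits = sum(
        optimize(staircase, space, 30, StrategyConfig(seed=s))[0].fitness == target
        for s in range(30)
    )
    assert hits >= 28


def test_trace_roundtrip_csv(tmp_path):
    space = SearchSpace(dim=2, lb=-1.0, ub=1.0, max_evals=200)
    _, trace = optimize(sphere, space, 5, StrategyConfig(seed=0))
    out = tmp_path / "trace.csv"
    trace.to_csv(out)
    import pandas as pd

    df = pd.read_csv(out)
    assert list(df.columns) == ["iteration", "evals", "best_fitness"]
    assert len(df) == len(trace.best_fitness_per_iteration)
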
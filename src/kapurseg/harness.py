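"""Repeated-trial benchmarking and statistical summaries.

Runs competing optimizers over analytic test functions for a fixed number
of repetitions and reduces the final-fitness matrix the way metaheuristic
comparison studies do: per-cell AVG/STD, Friedman mean ranks across
problems, and paired Wilcoxon signed-rank win/tie/loss counts against a
reference algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .optimizer import SearchSpace, optimize, variant_config, VARIANT_FLAGS

__all__ = [
    "BenchmarkFunction",
    "TrialMatrix",
    "test_function",
    "make_variant_algorithm",
    "run_trials",
    "avg_std",
    "friedman_mean_ranks",
    "wilcoxon_wtl",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    dim: int
    lb: float
    ub: float
    fn: Callable[[np.ndarray], float]

    def __call__(self, x: np.ndarray) -> float:
        return self.fn(x)


def _sphere(x):
    return float(np.dot(x, x))


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x):
    return float(10.0 * len(x) + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def _ackley(x):
    d = len(x)
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
        + 20.0
        + np.e
    )


def _griewank(x):
    i = np.arange(1, len(x) + 1)
    return float(np.sum(x**2) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


_FUNCTIONS = {
    "sphere": (_sphere, -100.0, 100.0),
    "rosenbrock": (_rosenbrock, -30.0, 30.0),
    "rastrigin": (_rastrigin, -5.12, 5.12),
    "ackley": (_ackley, -32.768, 32.768),
    "griewank": (_griewank, -600.0, 600.0),
}


def test_function(name: str, dim: int) -> BenchmarkFunction:
    """Standard analytic benchmark (global minimum 0).  Names: sphere,
    rosenbrock, rastrigin, ackley, griewank."""
    try:
        fn, lb, ub = _FUNCTIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown test function {name!r}; choose from {sorted(_FUNCTIONS)}"
        ) from None
    return BenchmarkFunction(name=name, dim=dim, lb=lb, ub=ub, fn=fn)


# An "algorithm" is a callable (objective, space, n, seed) -> final best fitness.
Algorithm = Callable[[Callable, SearchSpace, int, int], float]


def make_variant_algorithm(name: str, **config_kwargs) -> Algorithm:
    """Algorithm wrapper for one of the 8 named ablation variants
    (flag matrix in :data:`kapurseg.optimizer.VARIANT_FLAGS`)."""
    if name.upper() not in VARIANT_FLAGS:
        raise ValueError(f"unknown variant {name!r}")

    def run(objective, space, n, seed):
        cfg = variant_config(name, seed=seed, **config_kwargs)
        best, _ = optimize(objective, space, n, cfg)
        return best.fitness

    run.__name__ = f"run_{name.lower()}"
    return run


@dataclass
class TrialMatrix:
    """algorithms × problems × repetitions final best fitnesses."""

    results: np.ndarray
    algorithms: tuple[str, ...]
    problems: tuple[str, ...]
    seeds: tuple[int, ...]


def run_trials(
    algorithms: Mapping[str, Algorithm],
    problems: Sequence[BenchmarkFunction],
    reps: int = 30,
    budget: int = 300_000,
    n: int = 30,
    base_seed: int = 0,
) -> TrialMatrix:
    """Run every algorithm on every problem ``reps`` times.

    Repetition ``r`` uses seed ``base_seed + r`` for every algorithm, so
    comparisons are paired.  Defaults mirror common practice for this kind
    of study: population 30, 30 repetitions (the full-scale evaluation
    budget of 300,000 is configurable and typically scaled down).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    names = tuple(algorithms)
    res = np.empty((len(names), len(problems), reps))
    seeds = tuple(base_seed + r for r in range(reps))
    for ai, name in enumerate(names):
        algo = algorithms[name]
        for pi, prob in enumerate(problems):
            space = SearchSpace(dim=prob.dim, lb=prob.lb, ub=prob.ub, max_evals=budget)
            for r, seed in enumerate(seeds):
                res[ai, pi, r] = algo(prob.fn, space, n, seed)
    return TrialMatrix(
        results=res,
        algorithms=names,
        problems=tuple(p.name for p in problems),
        seeds=seeds,
    )


def avg_std(matrix: TrialMatrix) -> pd.DataFrame:
    """Per (algorithm, problem) mean and sample standard deviation
    (ddof=1; a single repetition reports STD 0)."""
    reps = matrix.results.shape[2]
    avg = matrix.results.mean(axis=2)
    std = matrix.results.std(axis=2, ddof=1) if reps > 1 else np.zeros_like(avg)
    rows = []
    for ai, a in enumerate(matrix.algorithms):
        for pi, p in enumerate(matrix.problems):
            rows.append({"algorithm": a, "problem": p, "avg": avg[ai, pi], "std": std[ai, pi]})
    return pd.DataFrame(rows)


def friedman_mean_ranks(matrix: TrialMatrix) -> pd.DataFrame:
    """Friedman-style mean ranks: per problem, rank the algorithms by AVG
    ascending (ties get the average rank); the mean rank averages across
    problems and final_rank ranks the means."""
    avg = matrix.results.mean(axis=2)  # (A, P)
    per_problem_ranks = np.apply_along_axis(stats.rankdata, 0, avg)
    mean_rank = per_problem_ranks.mean(axis=1)
    final_rank = stats.rankdata(mean_rank, method="min").astype(int)
    return pd.DataFrame(
        {
            "algorithm": matrix.algorithms,
            "mean_rank": mean_rank,
            "final_rank": final_rank,
        }
    )


def wilcoxon_wtl(
    matrix: TrialMatrix,
    reference: str,
    alpha: float = 0.05,
    zero_method: str = "wilcox",
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank win/tie/loss of ``reference`` against
    every other algorithm.

    Per problem, the per-repetition results are compared two-sided at
    level ``alpha``: significantly better → '+', significantly worse →
    '−', otherwise '='.  All-zero difference vectors count as '='.
    ``zero_method`` is forwarded to scipy ('wilcox' drops zeros, 'pratt'
    keeps them).
    """
    ri = matrix.algorithms.index(reference)
    rows = []
    for ai, name in enumerate(matrix.algorithms):
        if ai == ri:
            continue
        wins = ties = losses = 0
        for pi in range(len(matrix.problems)):
            x = matrix.results[ri, pi]
            y = matrix.results[ai, pi]
            d = x - y
            if np.all(d == 0):
                ties += 1
                continue
            try:
                _, p = stats.wilcoxon(x, y, zero_method=zero_method)
            except ValueError:  # e.g. all differences dropped
                ties += 1
                continue
            if p < alpha:
                if np.mean(x) < np.mean(y):
                    wins += 1
                else:
                    losses += 1
            else:
                ties += 1
        rows.append(
            {"opponent": name, "wins": wins, "losses": losses, "ties": ties}
        )
    return pd.DataFrame(rows)
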
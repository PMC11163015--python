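"""Whale optimization algorithm (WOA) and its enhanced variant.

The enhanced optimizer — CAGWOA — augments baseline WOA with three
independently toggleable strategies:

* **COSI** (COS sampling initialization): a cosine transform of a Latin
  hypercube sequence, mixing stratified coverage with per-entry randomness.
* **GS** (adaptive global search): a best-anchored differential move whose
  weight grows exponentially with the fraction of the evaluation budget
  already spent.
* **ADN** (all-dimensional neighborhood): ``2*dim`` probe agents displaced
  by ``±L`` along each single coordinate of the incumbent best, with a
  geometrically shrinking, randomly re-expanding step size.

Everything is expressed in the minimization convention; callers that
maximize (e.g. Kapur entropy) pass the negated objective.  All randomness
flows through a single :class:`numpy.random.Generator` seeded from
:class:`StrategyConfig`, so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "Individual",
    "Population",
    "StrategyConfig",
    "ConvergenceTrace",
    "lhs_sequence",
    "cosi_initialize",
    "random_initialize",
    "woa_phase_update",
    "gs_update",
    "adn_agents",
    "adn_step_update",
    "greedy_merge",
    "clamp_bounds",
    "optimize",
    "VARIANT_FLAGS",
    "variant_config",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SearchSpace:
    """Box-constrained problem container.

    Parameters
    ----------
    dim : int
        Number of decision variables, ``>= 1``.
    lb, ub : array-like
        Per-dimension lower/upper bounds; scalars broadcast.  ``lb < ub``
        elementwise.
    max_evals : int
        Objective-evaluation budget (MaxFEs).  Every single call to the
        objective counts one evaluation.
    """

    dim: int
    lb: np.ndarray
    ub: np.ndarray
    max_evals: int

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        lb = np.broadcast_to(np.asarray(self.lb, dtype=float), (self.dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, dtype=float), (self.dim,)).copy()
        if not np.all(lb < ub):
            raise ValueError("lb must be strictly below ub in every dimension")
        if self.max_evals < 1:
            raise ValueError("max_evals must be positive")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @property
    def range(self) -> np.ndarray:
        return self.ub - self.lb


@dataclass
class Individual:
    position: np.ndarray
    fitness: float = math.inf

    def copy(self) -> "Individual":
        return Individual(self.position.copy(), self.fitness)


@dataclass
class Population:
    """Positions, fitnesses and the best-so-far of a swarm."""

    positions: np.ndarray  # (n, dim)
    fitness: np.ndarray  # (n,)
    best: Individual
    evals_used: int = 0
    iteration: int = 0

    @property
    def size(self) -> int:
        return self.positions.shape[0]


@dataclass
class StrategyConfig:
    """Toggles and constants for the optimizer strategies.

    ``rho`` is the per-iteration execution probability of the ADN probe
    (1.0 by default, the setting found best in sensitivity analysis);
    ``spiral_b`` the logarithmic-spiral shape constant; ``L0_frac``,
    ``shrink_s`` and ``Lmin_frac`` govern the ADN step-size schedule as
    fractions of the per-dimension range.
    """

    use_cosi: bool = True
    use_gs: bool = True
    use_adn: bool = True
    rho: float = 1.0
    spiral_b: float = 1.0
    L0_frac: float = 0.1
    shrink_s: float = 0.5
    Lmin_frac: float = 1e-4
    gs_greedy: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 < self.shrink_s < 1.0:
            raise ValueError("shrink_s must lie in (0, 1)")
        if not 0.0 < self.Lmin_frac < self.L0_frac <= 1.0:
            raise ValueError("require 0 < Lmin_frac < L0_frac <= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StrategyConfig":
        return cls(**d)


@dataclass
class ConvergenceTrace:
    """Best fitness and cumulative evaluations recorded once per iteration."""

    best_fitness_per_iteration: list = field(default_factory=list)
    evals_per_iteration: list = field(default_factory=list)

    def append(self, best_fitness: float, evals: int) -> None:
        self.best_fitness_per_iteration.append(best_fitness)
        self.evals_per_iteration.append(evals)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.best_fitness_per_iteration)),
                "evals": self.evals_per_iteration,
                "best_fitness": self.best_fitness_per_iteration,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# initialization


def lhs_sequence(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Latin hypercube sequence: an ``(n, dim)`` matrix with exactly one
    uniform sample per equal-width stratum in every dimension.
    """
    if n < 1 or dim < 1:
        raise ValueError("n and dim must be >= 1")
    strata = np.arange(n, dtype=float)[:, None]  # (n, 1)
    u = rng.random((n, dim))
    p = (strata + u) / n
    # independently permute the strata in every dimension
    for j in range(dim):
        p[:, j] = p[rng.permutation(n), j]
    return p


def cos_transform(p, b, lb, ub):
    """The COSI map: ``cos(pi*(1/2 - p)*b)*(ub - lb) + lb``.

    For ``p``, ``b`` in [0, 1] the argument stays in ``[-pi/2, pi/2]``, so
    the output stays in ``[lb, ub]`` (skewed toward ``ub`` for small ``b``).
    """
    return np.cos(np.pi * (0.5 - np.asarray(p)) * np.asarray(b)) * (ub - lb) + lb


def cosi_initialize(space: SearchSpace, n: int, rng: np.random.Generator) -> np.ndarray:
    """COS sampling initialization.

    Each position is ``cos(pi*(1/2 - p)*b) * (ub - lb) + lb`` with ``p`` a
    Latin hypercube sequence and ``b ~ U[0,1]`` drawn independently per
    entry.  The cosine argument lies in ``[-pi/2, pi/2]`` so all positions
    fall inside the box.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    p = lhs_sequence(n, space.dim, rng)
    b = rng.random((n, space.dim))
    return cos_transform(p, b, space.lb, space.ub)


def random_initialize(space: SearchSpace, n: int, rng: np.random.Generator) -> np.ndarray:
    """Memoryless i.i.d. uniform initialization (baseline for ablation)."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    return rng.uniform(space.lb, space.ub, size=(n, space.dim))


# ---------------------------------------------------------------------------
# update phases (per-individual contracts)


def clamp_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Project a position onto the box ``[lb, ub]``."""
    return np.clip(position, space.lb, space.ub)


def woa_phase_update(
    position: np.ndarray,
    best: np.ndarray,
    population_positions: np.ndarray,
    a_t: float,
    rng: np.random.Generator,
    spiral_b: float = 1.0,
) -> np.ndarray:
    """One baseline WOA move for a single individual.

    With probability 1/2 the shrink/search branch is taken: ``A`` and
    ``C`` are drawn per dimension as ``A = 2*a_t*r1 - a_t`` (spanning
    ``[-2, 2]`` early, collapsing to 0 late) and ``C = 2*r2``; dimensions
    with ``|A| > 1`` search around a random member
    (``X' = X_rand - A*|C*X_rand - X|``) while the remaining dimensions
    encircle the best.  With probability 1/2 the logarithmic spiral move
    toward the best is taken:
    ``X' = |best - X| * exp(b*l) * cos(2*pi*l) + X`` with ``l ~ U[-1, 1]``.
    """
    if len(population_positions) == 0:
        raise RuntimeError("population is empty")
    position = np.asarray(position, dtype=float)
    best = np.asarray(best, dtype=float)
    if rng.random() < 0.5:
        A = 2.0 * a_t * rng.random(position.shape) - a_t
        C = 2.0 * rng.random(position.shape)
        idx = rng.integers(len(population_positions))
        x_rand = population_positions[idx]
        search = np.abs(A) > 1.0  # search for prey around a random member
        out = best - A * np.abs(C * best - position)
        out[search] = (x_rand - A * np.abs(C * x_rand - position))[search]
        return out
    l = rng.uniform(-1.0, 1.0)
    d_best = np.abs(best - position)
    return d_best * np.exp(spiral_b * l) * np.cos(2.0 * np.pi * l) + position


def gs_update(
    position: np.ndarray,
    best: np.ndarray,
    population_positions: np.ndarray,
    index: int,
    evals_used: int,
    max_evals: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Adaptive global search move for a single individual.

    ``X' = X_best + 2*C*(X_rand1 - X_rand2)`` with
    ``C = 2*b*exp(FEs/MaxFEs)``, ``b ~ U[0,1]`` and ``rand1 != rand2`` two
    random members distinct from the individual itself.  The weight grows
    from at most 2 toward ``2e`` as the budget is consumed, shifting
    influence from the incumbent best toward random pairs.
    """
    n = len(population_positions)
    if n < 3:
        raise RuntimeError("GS requires a population of at least 3 members")
    b = rng.random()
    c = 2.0 * b * math.exp(evals_used / max_evals)
    choices = [i for i in range(n) if i != index]
    r1, r2 = rng.choice(choices, size=2, replace=False)
    return np.asarray(best, dtype=float) + 2.0 * c * (
        population_positions[r1] - population_positions[r2]
    )


def adn_agents(best: np.ndarray, L: np.ndarray, dim: int) -> np.ndarray:
    """All-dimensional neighborhood probes.

    Returns ``2*dim`` agents; the pair ``(2k-1, 2k)`` equals the best in
    every dimension except ``k`` where it is displaced by ``+L[k]`` and
    ``-L[k]``.
    """
    best = np.asarray(best, dtype=float)
    L = np.broadcast_to(np.asarray(L, dtype=float), (dim,))
    agents = np.tile(best, (2 * dim, 1))
    for k in range(dim):
        agents[2 * k, k] = best[k] + L[k]
        agents[2 * k + 1, k] = best[k] - L[k]
    return agents


def adn_step_update(
    L: np.ndarray,
    config: StrategyConfig,
    space: SearchSpace,
    improved: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shrink / re-expand / maintain the ADN step-size vector.

    When the probe round improved the best, the current scale is kept
    (maintenance).  Otherwise every component contracts by the factor
    ``shrink_s``; any component that falls below ``Lmin`` is re-expanded to
    a fresh random step ``L0 * r`` with ``r ~ U[0,1]``, so the step never
    stays degenerate for two consecutive updates.
    """
    L = np.array(L, dtype=float, copy=True)
    L0 = config.L0_frac * space.range
    Lmin = config.Lmin_frac * space.range
    if not improved:
        L *= config.shrink_s
    small = L < Lmin
    if np.any(small):
        L[small] = L0[small] * rng.random(int(small.sum()))
    return L


def greedy_merge(
    positions: np.ndarray,
    fitness: np.ndarray,
    cand_positions: np.ndarray,
    cand_fitness: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Elitist merge: keep the ``n`` best of members ∪ candidates.

    Stable mergesort on fitness so incumbents win ties; the best fitness of
    the retained set can never be worse than before.
    """
    n = positions.shape[0]
    all_pos = np.vstack([positions, cand_positions])
    all_fit = np.concatenate([fitness, cand_fitness])
    order = np.argsort(all_fit, kind="stable")[:n]
    return all_pos[order], all_fit[order]


# ---------------------------------------------------------------------------
# driver


def _evaluate(objective, positions, start, budget_left):
    """Evaluate rows of ``positions`` one by one, at most ``budget_left``.
    Non-finite objective values are recorded as +inf.  Returns (fitness
    array for the evaluated prefix, number of evaluations spent)."""
    m = min(len(positions), budget_left)
    fit = np.empty(m)
    for i in range(m):
        v = float(objective(positions[i]))
        fit[i] = v if math.isfinite(v) else math.inf
    return fit, m


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    n: int,
    config: StrategyConfig | None = None,
) -> tuple[Individual, ConvergenceTrace]:
    """Run the (strategy-toggleable) whale optimizer.

    Per iteration: an optional GS pass rewrites every member anchored on
    the best, the baseline WOA phase moves every member with the control
    scalar ``a`` decaying linearly 2 → 0 over the evaluation budget, all
    members are clamped and re-evaluated, and (with probability ``rho``)
    the ADN probe round evaluates ``2*dim`` single-coordinate displacements
    of the best and merges them back elitistly.  The loop stops when the
    evaluation budget ``space.max_evals`` is exhausted; every objective
    call counts exactly one evaluation.

    Returns the best individual found and a per-iteration convergence
    trace whose best-fitness sequence is non-increasing.
    """
    if config is None:
        config = StrategyConfig()
    if space.max_evals < n:
        raise ValueError("evaluation budget must cover the initial population")
    rng = np.random.default_rng(config.seed)
    dim = space.dim

    if config.use_cosi:
        positions = cosi_initialize(space, n, rng)
    else:
        positions = random_initialize(space, n, rng)
    fitness, used = _evaluate(objective, positions, 0, space.max_evals)
    evals = used
    ibest = int(np.argmin(fitness))
    best = Individual(positions[ibest].copy(), float(fitness[ibest]))

    L = config.L0_frac * space.range * np.ones(dim)
    trace = ConvergenceTrace()
    trace.append(best.fitness, evals)
    iteration = 0

    while evals < space.max_evals:
        iteration += 1
        # --- GS: best-anchored differential rewrite of every member
        if config.use_gs and n >= 3:
            b = rng.random(n)
            c = 2.0 * b * math.exp(evals / space.max_evals)
            r1 = np.empty(n, dtype=int)
            r2 = np.empty(n, dtype=int)
            for i in range(n):
                choices = rng.choice(n - 1, size=2, replace=False)
                # map out of {i}: values >= i shift up by one
                r1[i] = choices[0] + (choices[0] >= i)
                r2[i] = choices[1] + (choices[1] >= i)
            proposal = best.position + (2.0 * c)[:, None] * (
                positions[r1] - positions[r2]
            )
            if config.gs_greedy:
                gs_fit, used = _evaluate(
                    objective, clamp_bounds(proposal, space), 0, space.max_evals - evals
                )
                evals += used
                better = gs_fit < fitness[: len(gs_fit)]
                positions[: len(gs_fit)][better] = clamp_bounds(proposal, space)[
                    : len(gs_fit)
                ][better]
                fitness[: len(gs_fit)][better] = gs_fit[better]
            else:
                positions = proposal

        # --- baseline WOA phase, a decaying linearly over the budget
        a_t = 2.0 * (1.0 - evals / space.max_evals)
        coin = rng.random(n) < 0.5
        A = 2.0 * a_t * rng.random((n, dim)) - a_t
        C = 2.0 * rng.random((n, dim))
        rand_idx = rng.integers(n, size=n)
        l = rng.uniform(-1.0, 1.0, size=n)
        xr = positions[rand_idx]
        search_move = xr - A * np.abs(C * xr - positions)
        encircle_move = best.position - A * np.abs(C * best.position - positions)
        d_best = np.abs(best.position - positions)
        ls = l[:, None]
        spiral_move = (
            d_best * np.exp(config.spiral_b * ls) * np.cos(2.0 * np.pi * ls)
            + positions
        )
        shrink_search = np.where(np.abs(A) > 1.0, search_move, encircle_move)
        new_positions = np.where(coin[:, None], shrink_search, spiral_move)
        new_positions = clamp_bounds(new_positions, space)
        new_fit, used = _evaluate(objective, new_positions, 0, space.max_evals - evals)
        evals += used
        positions[:used] = new_positions[:used]
        fitness[:used] = new_fit
        imin = int(np.argmin(fitness))
        if fitness[imin] < best.fitness:
            best = Individual(positions[imin].copy(), float(fitness[imin]))

        # --- ADN probe round around the best
        if config.use_adn and evals < space.max_evals and rng.random() < config.rho:
            agents = clamp_bounds(adn_agents(best.position, L, dim), space)
            agent_fit, used = _evaluate(objective, agents, 0, space.max_evals - evals)
            evals += used
            agents = agents[:used]
            improved = used > 0 and bool(np.min(agent_fit) < best.fitness)
            positions, fitness = greedy_merge(positions, fitness, agents, agent_fit)
            imin = int(np.argmin(fitness))
            if fitness[imin] < best.fitness:
                best = Individual(positions[imin].copy(), float(fitness[imin]))
            L = adn_step_update(L, config, space, improved, rng)

        trace.append(best.fitness, evals)

    return best, trace


# Table-style ablation naming: C = COSI, G = GS, A = ADN.
VARIANT_FLAGS: dict[str, tuple[bool, bool, bool]] = {
    "CAGWOA": (True, True, True),
    "AGWOA": (False, True, True),
    "CGWOA": (True, True, False),
    "CAWOA": (True, False, True),
    "GWOA": (False, True, False),
    "AWOA": (False, False, True),
    "CWOA": (True, False, False),
    "WOA": (False, False, False),
}


def variant_config(name: str, seed: int = 0, **kwargs) -> StrategyConfig:
    """StrategyConfig for one of the 8 named ablation variants."""
    try:
        cosi, gs, adn = VARIANT_FLAGS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown variant {name!r}; choose from {sorted(VARIANT_FLAGS)}"
        ) from None
    return StrategyConfig(use_cosi=cosi, use_gs=gs, use_adn=adn, seed=seed, **kwargs)
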
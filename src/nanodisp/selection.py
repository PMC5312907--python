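"""Descriptor-subset selection: a seeded genetic algorithm plus an exhaustive oracle.

The GA searches, separately for each model size ``s`` in
``[min_vars, max_vars]``, over size-``s`` descriptor subsets, maximising a
cross-validated (``q2``) or in-sample (``r2``) fitness.  Subsets containing a
pair of descriptors with |Pearson r| at or above the collinearity threshold
are inadmissible.  Fitness evaluations are memoised, so on small pools the
GA effectively enumerates; an early-stopping patience bounds wasted
generations.  Everything is driven by one integer seed and is
bit-reproducible.

Ties are broken deterministically: higher fitness first, then
lexicographically smaller descriptor-name tuple; across sizes, the smaller
subset wins at equal fitness.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .regression import DispersibilityMLR, MLRResults

__all__ = ["GAConfig", "ModelCandidate", "ga_select", "exhaustive_select", "best_overall"]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (all exposed; defaults chosen for reliable
    convergence on pools up to a few hundred columns)."""

    population: int = 100
    generations: int = 300
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    max_vars: int = 5
    min_vars: int = 1
    fitness: str = "q2"
    seed: int = 0
    tournament: int = 3
    elitism: int = 1
    patience: int = 50
    collinearity_threshold: float = 0.95

    def __post_init__(self):
        if not (1 <= self.min_vars <= self.max_vars):
            raise ValueError("need 1 <= min_vars <= max_vars")
        if self.max_vars > 5:
            raise ValueError("max_vars is capped at 5")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.fitness not in ("q2", "r2"):
            raise ValueError("fitness must be 'q2' or 'r2'")


@dataclass
class ModelCandidate:
    """A descriptor subset with its fitness and refitted model."""

    subset: tuple[str, ...]
    fitness: float
    model: MLRResults


def _frame_of(matrix) -> pd.DataFrame:
    return matrix.data if hasattr(matrix, "data") else pd.DataFrame(matrix)


class _FitnessCache:
    """Memoised subset -> fitness with a collinearity guard."""

    def __init__(self, df: pd.DataFrame, y, fitness: str, collinearity_threshold: float):
        self.df = df
        self.y = np.asarray(y, dtype=float).ravel()
        self.kind = fitness
        corr = df.corr().abs()
        self.corr = corr
        self.threshold = collinearity_threshold
        self._cache: dict[tuple[str, ...], float] = {}

    def admissible(self, subset: tuple[str, ...]) -> bool:
        for a, b in itertools.combinations(subset, 2):
            r = self.corr.loc[a, b]
            if not math.isnan(r) and r >= self.threshold:
                return False
        return True

    def __call__(self, subset: tuple[str, ...]) -> float:
        subset = tuple(sorted(subset))
        if subset in self._cache:
            return self._cache[subset]
        if not self.admissible(subset):
            value = -math.inf
        else:
            try:
                res = DispersibilityMLR(self.y, self.df[list(subset)]).fit()
                value = res.loo.q2 if self.kind == "q2" else res.rsquared
            except ValueError:  # rank-deficient subset
                value = -math.inf
        self._cache[subset] = value
        return value

    def refit(self, subset: tuple[str, ...]) -> MLRResults:
        return DispersibilityMLR(self.y, self.df[list(subset)]).fit()


def _better(fit_a: float, sub_a: tuple, fit_b: float, sub_b: tuple) -> bool:
    """Is (fit_a, sub_a) strictly preferred over (fit_b, sub_b)?"""
    if fit_a != fit_b:
        return fit_a > fit_b
    if len(sub_a) != len(sub_b):
        return len(sub_a) < len(sub_b)
    return sub_a < sub_b


def ga_select(matrix, y, config: GAConfig = GAConfig()) -> dict[int, ModelCandidate]:
    """Best descriptor subset per model size, found by the genetic algorithm.

    Parameters
    ----------
    matrix : DescriptorMatrix or DataFrame
        The descriptor pool (training rows only).
    y : array-like
        Response over the same rows.
    config : GAConfig

    Returns
    -------
    dict size -> :class:`ModelCandidate`

    Raises
    ------
    ValueError
        If the pool is smaller than ``min_vars``.
    """
    df = _frame_of(matrix)
    pool = list(df.columns)
    if len(pool) < config.min_vars:
        raise ValueError(
            f"pool of {len(pool)} column(s) smaller than min_vars={config.min_vars}"
        )
    cache = _FitnessCache(df, y, config.fitness, config.collinearity_threshold)
    out: dict[int, ModelCandidate] = {}
    for size in range(config.min_vars, min(config.max_vars, len(pool)) + 1):
        subset, fitness = _ga_one_size(pool, cache, size, config)
        if subset is not None:
            out[size] = ModelCandidate(subset, fitness, cache.refit(subset))
    return out


def _ga_one_size(
    pool: list[str], cache: _FitnessCache, size: int, config: GAConfig
) -> tuple[tuple[str, ...] | None, float]:
    rng = np.random.default_rng([max(config.seed, 0), size])
    n_pool = len(pool)

    def random_subset() -> tuple[str, ...]:
        idx = rng.choice(n_pool, size=size, replace=False)
        return tuple(sorted(pool[i] for i in idx))

    population = [random_subset() for _ in range(config.population)]
    best: tuple[str, ...] | None = None
    best_fit = -math.inf
    stall = 0
    for _ in range(config.generations):
        fits = [cache(ind) for ind in population]
        gen_best = max(range(len(population)), key=lambda i: (fits[i], population[i]))
        improved = False
        for i, f in enumerate(fits):
            if best is None or _better(f, population[i], best_fit, best):
                best, best_fit = population[i], f
                improved = True
        stall = 0 if improved else stall + 1
        if stall > config.patience:
            break

        def tournament() -> tuple[str, ...]:
            picks = rng.integers(0, len(population), size=config.tournament)
            w = max(picks, key=lambda i: (fits[i], population[i]))
            return population[w]

        next_pop: list[tuple[str, ...]] = []
        if config.elitism and best is not None:
            next_pop.append(best)
        while len(next_pop) < config.population:
            a, b = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                union = sorted(set(a) | set(b))
                idx = rng.choice(len(union), size=min(size, len(union)), replace=False)
                child = [union[i] for i in idx]
                while len(child) < size:  # parents overlapped heavily
                    extra = pool[rng.integers(n_pool)]
                    if extra not in child:
                        child.append(extra)
            else:
                child = list(a)
            if rng.random() < config.mutation_rate:
                out_i = rng.integers(size)
                candidates = [c for c in pool if c not in child]
                if candidates:
                    child[out_i] = candidates[rng.integers(len(candidates))]
            next_pop.append(tuple(sorted(child)))
        population = next_pop
    if best is not None and math.isinf(best_fit):
        return None, best_fit
    return best, best_fit


def exhaustive_select(
    matrix,
    y,
    max_vars: int,
    min_vars: int = 1,
    fitness: str = "q2",
    collinearity_threshold: float = 0.95,
    budget: int = 10**6,
) -> dict[int, ModelCandidate]:
    """Global optimum per size by enumerating every admissible subset.

    The independent oracle for :func:`ga_select`.  Refuses pools whose
    subset count exceeds ``budget`` (use the GA there).
    """
    df = _frame_of(matrix)
    pool = sorted(df.columns)
    if not pool:
        raise ValueError("empty descriptor pool")
    if min_vars < 1 or min_vars > max_vars:
        raise ValueError("need 1 <= min_vars <= max_vars")
    total = sum(math.comb(len(pool), s) for s in range(min_vars, max_vars + 1))
    if total > budget:
        raise ValueError(
            f"{total} subsets exceed the exhaustive budget {budget}; use ga_select"
        )
    cache = _FitnessCache(df, y, fitness, collinearity_threshold)
    out: dict[int, ModelCandidate] = {}
    for size in range(min_vars, min(max_vars, len(pool)) + 1):
        best, best_fit = None, -math.inf
        for combo in itertools.combinations(pool, size):
            f = cache(combo)
            if best is None or _better(f, combo, best_fit, best):
                best, best_fit = combo, f
        if best is not None and not math.isinf(best_fit):
            out[size] = ModelCandidate(best, best_fit, cache.refit(best))
    return out


def best_overall(candidates: dict[int, ModelCandidate]) -> ModelCandidate:
    """Across sizes: highest fitness; ties go to the smaller subset."""
    if not candidates:
        raise ValueError("no candidates")
    best = None
    for c in candidates.values():
        if best is None or _better(c.fitness, c.subset, best.fitness, best.subset):
            best = c
    return best
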
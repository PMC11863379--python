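"""Multi-objective suggestion via NSGA-II.

When an experiment is scored on several competing objectives (all
minimized), no single recipe is "best"; the useful answer is a Pareto front
of trade-offs.  This module implements the elitist NSGA-II generational
loop: fast non-dominated sorting, crowding-distance diversity preservation,
binary tournament selection, simulated binary crossover (SBX) and
polynomial mutation on the continuous relaxation of the design space, with
uniform crossover / category resampling for categorical factors.

Constraints are deliberately rejected here: constrained multi-objective
optimization is unsupported, and asking for it raises an explicit error
rather than silently ignoring the constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .space import SearchSpace, ValidationError

__all__ = [
    "Individual",
    "NSGAParams",
    "dominates",
    "non_dominated_sort",
    "crowding_distance",
    "evolve",
    "pareto_suggest",
]


@dataclass
class Individual:
    """A candidate recipe with its objective vector and NSGA-II bookkeeping.

    ``genome`` holds one gene per dimension: a unit-interval float for
    numeric dims, a category index for categorical dims.
    """

    genome: np.ndarray
    x: list
    objectives: np.ndarray
    rank: int | None = None
    crowding: float | None = None


@dataclass(frozen=True)
class NSGAParams:
    """Canonical NSGA-II operator parameters."""

    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    p_crossover: float = 0.9
    p_mutation: float | None = None  # defaults to 1/n_dims


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """True iff a is no worse than b in every objective and strictly better
    in at least one (minimization)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"objective length mismatch: {a.shape} vs {b.shape}")
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_sort(population: Sequence[Individual]) -> list[list[Individual]]:
    """Partition the population into fronts; front 0 is the Pareto set.

    Deb's fast non-dominated sort: each individual tracks its domination
    count and dominated set; ranks are assigned front by front.
    """
    pop = list(population)
    if not pop:
        raise ValidationError("empty population")
    n = len(pop)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(pop[i].objectives, pop[j].objectives):
                dominated_by[i].append(j)
                count[j] += 1
            elif dominates(pop[j].objectives, pop[i].objectives):
                dominated_by[j].append(i)
                count[i] += 1
    fronts: list[list[Individual]] = []
    current = [i for i in range(n) if count[i] == 0]
    rank = 0
    while current:
        for i in current:
            pop[i].rank = rank
        fronts.append([pop[i] for i in current])
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                count[j] -= 1
                if count[j] == 0:
                    nxt.append(j)
        current = nxt
        rank += 1
    return fronts


def crowding_distance(front: Sequence[Individual]) -> np.ndarray:
    """Crowding distance per individual (boundary points get +inf).

    Per objective the front is sorted; interior individuals accumulate the
    neighbour gap normalized by the objective's range (a zero range
    contributes nothing).  Distances are also written onto the individuals.
    """
    front = list(front)
    n = len(front)
    if n == 0:
        return np.array([])
    dist = np.zeros(n)
    if n <= 2:
        dist[:] = np.inf
    else:
        objs = np.array([ind.objectives for ind in front], dtype=float)
        for m in range(objs.shape[1]):
            order = np.argsort(objs[:, m], kind="stable")
            lo, hi = objs[order[0], m], objs[order[-1], m]
            dist[order[0]] = dist[order[-1]] = np.inf
            rng = hi - lo
            if rng <= 0:
                continue
            for k in range(1, n - 1):
                dist[order[k]] += (objs[order[k + 1], m] - objs[order[k - 1], m]) / rng
    for ind, d in zip(front, dist):
        ind.crowding = float(d)
    return dist


def _crowded_better(a: Individual, b: Individual) -> Individual:
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    return a if (a.crowding or 0) >= (b.crowding or 0) else b


def _rank_population(pop: list[Individual]) -> list[list[Individual]]:
    fronts = non_dominated_sort(pop)
    for f in fronts:
        crowding_distance(f)
    return fronts


# -- variation operators -------------------------------------------------------


def _sbx_pair(u1: float, u2: float, eta: float, rng) -> tuple[float, float]:
    """Simulated binary crossover on one unit-interval gene pair."""
    if abs(u1 - u2) < 1e-14:
        return u1, u2
    r = rng.random()
    beta = (2 * r) ** (1 / (eta + 1)) if r <= 0.5 else (1 / (2 * (1 - r))) ** (1 / (eta + 1))
    c1 = 0.5 * ((1 + beta) * u1 + (1 - beta) * u2)
    c2 = 0.5 * ((1 - beta) * u1 + (1 + beta) * u2)
    return float(np.clip(c1, 0, 1)), float(np.clip(c2, 0, 1))


def _poly_mutate(u: float, eta: float, rng) -> float:
    """Polynomial mutation of one unit-interval gene (bounds [0, 1])."""
    r = rng.random()
    if r < 0.5:
        delta = (2 * r + (1 - 2 * r) * (1 - u) ** (eta + 1)) ** (1 / (eta + 1)) - 1
    else:
        delta = 1 - (2 * (1 - r) + 2 * (r - 0.5) * u ** (eta + 1)) ** (1 / (eta + 1))
    return float(np.clip(u + delta, 0, 1))


def _genome_to_recipe(space: SearchSpace, genome: np.ndarray) -> list:
    point = []
    for d, g in zip(space.dims, genome):
        if d.kind == "categorical":
            point.append(d.categories[int(g)])
        else:
            point.append(d.from_unit(float(g)))
    return point


def _recipe_to_genome(space: SearchSpace, point: Sequence) -> np.ndarray:
    genome = np.empty(len(space.dims))
    for k, (d, v) in enumerate(zip(space.dims, point)):
        if d.kind == "categorical":
            genome[k] = d.categories.index(v)
        else:
            genome[k] = np.clip(d.to_unit(v), 0.0, 1.0)
    return genome


def _make_children(
    parents: list[Individual],
    space: SearchSpace,
    params: NSGAParams,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    n = len(parents)
    d = len(space.dims)
    p_mut = params.p_mutation if params.p_mutation is not None else 1.0 / d
    # binary tournaments to pick a mating pool, then pairwise SBX
    pool = []
    for _ in range(n):
        i, j = rng.integers(0, n, 2)
        pool.append(_crowded_better(parents[i], parents[j]))
    genomes = []
    for a in range(0, n, 2):
        g1 = pool[a].genome.copy()
        g2 = pool[(a + 1) % n].genome.copy()
        if rng.random() < params.p_crossover:
            for k, dim in enumerate(space.dims):
                if dim.kind == "categorical":
                    if rng.random() < 0.5:
                        g1[k], g2[k] = g2[k], g1[k]
                elif rng.random() < 0.5:
                    g1[k], g2[k] = _sbx_pair(g1[k], g2[k], params.eta_crossover, rng)
        for g in (g1, g2):
            for k, dim in enumerate(space.dims):
                if rng.random() < p_mut:
                    if dim.kind == "categorical":
                        g[k] = rng.integers(0, len(dim.categories))
                    else:
                        g[k] = _poly_mutate(g[k], params.eta_mutation, rng)
        genomes.extend([g1, g2])
    return genomes[:n]


def evolve(
    population: Sequence[Individual],
    space: SearchSpace,
    evaluator: Callable[[list], Sequence[float]],
    rng: np.random.Generator,
    params: NSGAParams | None = None,
    constraints=None,
) -> list[Individual]:
    """One elitist NSGA-II generation: variation then environmental selection
    of the best N from parents plus children by (rank, crowding)."""
    if constraints:
        raise ValidationError(
            "multi-objective optimization does not support constraints"
        )
    pop = list(population)
    if len(pop) < 4 or len(pop) % 2 != 0:
        raise ValidationError("population size must be even and >= 4")
    params = params or NSGAParams()
    _rank_population(pop)
    child_genomes = _make_children(pop, space, params, rng)
    children = []
    for g in child_genomes:
        x = _genome_to_recipe(space, g)
        children.append(Individual(g, x, np.asarray(evaluator(x), dtype=float)))
    combined = pop + children
    fronts = _rank_population(combined)
    survivors: list[Individual] = []
    for front in fronts:
        if len(survivors) + len(front) <= len(pop):
            survivors.extend(front)
        else:
            room = len(pop) - len(survivors)
            ordered = sorted(front, key=lambda ind: -(ind.crowding or 0))
            survivors.extend(ordered[:room])
            break
    return survivors


def pareto_suggest(
    evaluator: Callable[[list], Sequence[float]],
    space: SearchSpace,
    pop_size: int = 40,
    generations: int = 50,
    rng: np.random.Generator | None = None,
    params: NSGAParams | None = None,
    constraints=None,
) -> list[Individual]:
    """Run LHS-initialized NSGA-II and return the final Pareto front.

    ``evaluator`` maps a recipe to a vector of >= 2 objectives — typically
    per-objective surrogate means, or a benchmark model system's truth.
    """
    if constraints:
        raise ValidationError(
            "multi-objective optimization does not support constraints"
        )
    if pop_size < 4 or pop_size % 2 != 0:
        raise ValidationError("pop_size must be even and >= 4")
    if generations < 1:
        raise ValidationError("generations must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)

    init = space.lhs(pop_size, rng)
    pop = []
    for x in init:
        objs = np.asarray(evaluator(x), dtype=float)
        if objs.ndim != 1 or objs.size < 2:
            raise ValidationError(
                "evaluator must return >= 2 objectives; use the single-objective "
                "optimizer for scalar scores"
            )
        pop.append(Individual(_recipe_to_genome(space, x), list(x), objs))
    for _ in range(generations):
        pop = evolve(pop, space, evaluator, rng, params)
    front = non_dominated_sort(pop)[0]
    crowding_distance(front)
    return front


def front_to_frame(front: Sequence[Individual], space: SearchSpace) -> pd.DataFrame:
    """Export a front as a DataFrame: recipe columns plus one per objective."""
    rows = []
    for ind in front:
        row = {name: v for name, v in zip(space.names, ind.x)}
        for m, val in enumerate(ind.objectives):
            row[f"objective_{m}"] = float(val)
        rows.append(row)
    return pd.DataFrame(rows)
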
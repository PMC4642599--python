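"""Phase 1 — global optimization of edge probabilities by genetic algorithm.

A candidate solution psi is a vector of |E| edge probabilities.  Its fitness is

    F_psi = 1 - ||C - R_psi||_2 / |S x T|

(1 at a perfect match, since every squared entry difference is at most 1),
and its signed *gap*

    g_psi = sum_{s,t} C[s,t] - R_psi[s,t]

tells whether the solution underestimates (positive) or overestimates
(negative) edge probabilities in aggregate.  The gap sign drives the
crossover rule: when both parents underestimate, each child entry takes the
larger parent value; when both overestimate, the smaller; on mixed signs the
entry is drawn from either parent with probability proportional to parent
fitness.  Selection keeps the top 5 solutions outright and fills the
remaining 45 slots by fitness-proportional sampling without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import ReachabilityEngine
from .network import ProbabilisticNetwork, ReachabilityMatrix, ValidationError

__all__ = [
    "CandidateSolution",
    "Population",
    "GAResult",
    "fitness",
    "gap",
    "initialize",
    "crossover",
    "mutate",
    "select",
    "run_ga",
]

DEFAULT_POPULATION = 50
DEFAULT_MUTATION_RATE = 0.01
DEFAULT_ELITE = 5
DEFAULT_ITERATIONS = 100


def _values(matrix) -> np.ndarray:
    if isinstance(matrix, ReachabilityMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def _conformable(C, R) -> tuple[np.ndarray, np.ndarray]:
    c, r = _values(C), _values(R)
    if c.shape != r.shape:
        raise ValidationError(f"matrix shapes {c.shape} and {r.shape} differ")
    return c, r


def fitness(C, R) -> float:
    """F = 1 - sqrt(sum of squared differences) / (|S| * |T|)."""
    c, r = _conformable(C, R)
    return 1.0 - float(np.sqrt(np.sum((c - r) ** 2))) / c.size


def gap(C, R) -> float:
    """Signed sum of C - R entries; positive means aggregate underestimation."""
    c, r = _conformable(C, R)
    return float(np.sum(c - r))


@dataclass
class CandidateSolution:
    """An edge-probability vector with its cached evaluation against C."""

    psi: np.ndarray
    fitness: float
    gap: float
    matrix: ReachabilityMatrix

    @classmethod
    def evaluate(
        cls, engine: ReachabilityEngine, C: ReachabilityMatrix, psi: np.ndarray
    ) -> "CandidateSolution":
        R = engine.matrix(psi)
        return cls(psi=psi, fitness=fitness(C, R), gap=gap(C, R), matrix=R)


@dataclass
class Population:
    solutions: list[CandidateSolution]
    generation: int = 0
    best_ever: CandidateSolution | None = None

    def best(self) -> CandidateSolution:
        return max(self.solutions, key=lambda s: s.fitness)


@dataclass
class GAResult:
    """Outcome of a GA run: the best-ever solution and the fitness trace."""

    best: CandidateSolution
    history: list[float] = field(default_factory=list)
    population: Population | None = None


def initialize(
    network: ProbabilisticNetwork,
    C: ReachabilityMatrix,
    size: int = DEFAULT_POPULATION,
    rng: np.random.Generator | int | None = None,
    engine: ReachabilityEngine | None = None,
) -> Population:
    """Seed the population with i.i.d. U[0,1] probability vectors, evaluated."""
    rng = np.random.default_rng(rng)
    engine = engine or ReachabilityEngine(network)
    solutions = [
        CandidateSolution.evaluate(engine, C, rng.random(network.n_edges))
        for _ in range(size)
    ]
    pop = Population(solutions=solutions)
    pop.best_ever = pop.best()
    return pop


def crossover(
    parent1: CandidateSolution,
    parent2: CandidateSolution,
    rng: np.random.Generator,
) -> np.ndarray:
    """Combine two parents entrywise, guided by their gap signs.

    A gap of exactly zero is treated as positive so the rule is total and
    deterministic.  On mixed signs each entry comes from parent 1 with
    probability F1 / (F1 + F2) (0.5 when both fitnesses are zero).
    """
    p1, p2 = parent1.psi, parent2.psi
    if p1.shape != p2.shape:
        raise ValidationError("parent solutions have different lengths")
    g1 = parent1.gap >= 0.0
    g2 = parent2.gap >= 0.0
    if g1 and g2:
        return np.maximum(p1, p2)
    if not g1 and not g2:
        return np.minimum(p1, p2)
    denom = parent1.fitness + parent2.fitness
    w1 = parent1.fitness / denom if denom > 0.0 else 0.5
    take1 = rng.random(p1.shape[0]) < w1
    return np.where(take1, p1, p2)


def mutate(
    psi: np.ndarray,
    rate: float = DEFAULT_MUTATION_RATE,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Independently resample each entry from U[0,1] with probability `rate`."""
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"mutation rate {rate} outside [0, 1]")
    rng = np.random.default_rng(rng)
    mask = rng.random(psi.shape[0]) < rate
    if not mask.any():
        return psi
    out = psi.copy()
    out[mask] = rng.random(int(mask.sum()))
    return out


def _proportional_weights(fits: np.ndarray, k: int) -> np.ndarray:
    """Fitness-proportional draw weights, degenerating to uniform when needed.

    All-zero fitness falls back to uniform; when fewer than k weights are
    strictly positive a tiny uniform floor keeps a without-replacement draw
    of k well-defined.
    """
    w = np.clip(fits.astype(float), 0.0, None)
    if w.sum() <= 0.0:
        w = np.ones_like(w)
    elif np.count_nonzero(w) < k:
        w = w + 1e-12
    return w / w.sum()


def select(
    solutions: list[CandidateSolution],
    rng: np.random.Generator,
    target: int = DEFAULT_POPULATION,
    elite: int = DEFAULT_ELITE,
) -> list[CandidateSolution]:
    """Reduce 2x`target` solutions to `target`: elites plus proportional draws."""
    if len(solutions) != 2 * target:
        raise ValidationError(
            f"selection expects exactly {2 * target} solutions, got {len(solutions)}"
        )
    order = sorted(range(len(solutions)), key=lambda i: solutions[i].fitness, reverse=True)
    elite_idx = order[:elite]
    rest_idx = np.array(order[elite:])
    fits = np.array([solutions[i].fitness for i in rest_idx])
    k = target - elite
    weights = _proportional_weights(fits, k)
    drawn = rng.choice(len(rest_idx), size=k, replace=False, p=weights)
    keep = list(elite_idx) + [int(rest_idx[i]) for i in drawn]
    return [solutions[i] for i in keep]


def _pick_parents(
    solutions: list[CandidateSolution], rng: np.random.Generator
) -> tuple[CandidateSolution, CandidateSolution]:
    fits = np.array([s.fitness for s in solutions])
    weights = _proportional_weights(fits, 2)
    i = int(rng.choice(len(solutions), p=weights))
    j = i
    for _ in range(1000):
        j = int(rng.choice(len(solutions), p=weights))
        if j != i:
            break
    else:  # pragma: no cover - only if one solution dominates numerically
        j = (i + 1) % len(solutions)
    return solutions[i], solutions[j]


def run_ga(
    network: ProbabilisticNetwork,
    C: ReachabilityMatrix,
    iterations: int = DEFAULT_ITERATIONS,
    *,
    population_size: int = DEFAULT_POPULATION,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    elite: int = DEFAULT_ELITE,
    rng: np.random.Generator | int | None = None,
    engine: ReachabilityEngine | None = None,
    progress: bool = False,
) -> GAResult:
    """Run initialize -> (crossover, mutate, select) x iterations.

    Each iteration appends `population_size` crossover children (parents
    drawn fitness-proportionally, distinct), applies mutation across the
    enlarged population, and selects back down.  The returned solution is
    the best ever archived, so its fitness is non-decreasing in the
    generation index regardless of late mutations.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    rng = np.random.default_rng(rng)
    engine = engine or ReachabilityEngine(network)
    pop = initialize(network, C, size=population_size, rng=rng, engine=engine)
    best = pop.best_ever
    history = [best.fitness]
    for gen in range(iterations):
        children: list[np.ndarray] = []
        for _ in range(population_size):
            p1, p2 = _pick_parents(pop.solutions, rng)
            children.append(crossover(p1, p2, rng))
        # mutation sweeps the enlarged population: incumbents then children
        enlarged: list[CandidateSolution] = []
        for sol in pop.solutions:
            mutated = mutate(sol.psi, mutation_rate, rng)
            if mutated is sol.psi:
                enlarged.append(sol)  # untouched: cached evaluation still valid
            else:
                enlarged.append(CandidateSolution.evaluate(engine, C, mutated))
        for child in children:
            enlarged.append(
                CandidateSolution.evaluate(engine, C, mutate(child, mutation_rate, rng))
            )
        pop.solutions = select(enlarged, rng, target=population_size, elite=elite)
        pop.generation = gen + 1
        gen_best = pop.best()
        if gen_best.fitness > best.fitness:
            best = gen_best
        history.append(best.fitness)
        pop.best_ever = best
    return GAResult(best=best, history=history, population=pop)
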
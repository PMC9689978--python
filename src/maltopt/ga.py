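"""Real-valued genetic algorithm over a box-constrained search space.

Operator suite (the standard real-coded GA toolkit):

* uniform random initialization within the per-gene bounds;
* fitness-proportionate selection after *linear fitness scaling*.  The
  default (``"goldberg"``) is Goldberg's scheme: fitness is mapped to
  ``a f + b`` so the scaled mean is preserved and the scaled maximum is
  ``P x mean`` (pressure ``P``, default 2), falling back to anchoring the
  minimum at zero when that would produce negative weights; negative
  scaled values are clipped via absolute value.  The alternative
  (``"bounded"``) shifts fitness by ``(f_max - f_min)/(P - 1)`` above the
  minimum, capping the best-to-worst selection-probability ratio at
  exactly P.  All-equal fitness degenerates to uniform sampling in both
  modes;
* local arithmetic crossover: per gene, with weight a ~ U(0,1),
  ``c1 = a p1 + (1-a) p2`` and ``c2 = a p2 + (1-a) p1`` (children stay in
  the convex hull of the parents, hence inside the box);
* random uniform mutation: with probability ``mutation_prob`` per
  chromosome, one uniformly chosen gene is redrawn ~ U(low, high)
  (a per-gene mode is available via ``per_gene_mutation``);
* elitism: the top ``round(elitism_fraction * population_size)``
  individuals survive each generation by replacing the worst of the
  offspring, making the best-so-far fitness non-decreasing.

Generation loop: evaluate (elites re-inserted over the worst offspring)
-> record trace -> select -> crossover -> mutate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GAConfig",
    "GATrace",
    "GAResult",
    "init_population",
    "linear_scaled_weights",
    "select_parents",
    "la_crossover",
    "ra_mutation",
    "run_ga",
]


@dataclass(frozen=True)
class GAConfig:
    """GA settings; defaults follow the malting-study optimization run."""

    bounds: tuple[tuple[float, float], ...]
    population_size: int = 100
    max_iterations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism_fraction: float = 0.05
    selection_pressure: float = 2.0
    selection_scaling: str = "goldberg"  # "goldberg" | "bounded"
    per_gene_mutation: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob, self.elitism_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.selection_pressure <= 1.0:
            raise ValidationError("selection_pressure must be > 1")
        if self.selection_scaling not in ("goldberg", "bounded"):
            raise ValidationError("selection_scaling must be 'goldberg' or 'bounded'")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValidationError("each gene needs low < high bounds")

    @property
    def n_genes(self) -> int:
        return len(self.bounds)

    @property
    def n_elite(self) -> int:
        return int(round(self.elitism_fraction * self.population_size))


@dataclass(frozen=True)
class GATrace:
    """Per-generation fitness statistics and the best-so-far chromosome."""

    frame: pd.DataFrame  # generation, best, mean, median
    best_history: np.ndarray  # (n_generations, n_genes)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class GAResult:
    best_point: np.ndarray
    best_fitness: float
    trace: GATrace

    def to_dict(self) -> dict:
        return {
            "best_point": list(map(float, self.best_point)),
            "best_fitness": float(self.best_fitness),
            "generations": int(len(self.trace.frame)),
        }


def init_population(config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform random population within the bounds, shape (N, n_genes)."""
    lows = np.array([b[0] for b in config.bounds])
    highs = np.array([b[1] for b in config.bounds])
    return rng.uniform(lows, highs, size=(config.population_size, config.n_genes))


def linear_scaled_weights(
    fitness, pressure: float = 2.0, mode: str = "goldberg"
) -> np.ndarray:
    """Selection weights after linear fitness scaling (see module docstring).

    Both modes shift fitness so the minimum maps to a nonnegative weight
    and bound the selection pressure: ``"goldberg"`` caps the scaled
    maximum at ``pressure x mean``, ``"bounded"`` caps the max/min weight
    ratio at exactly ``pressure``.
    """
    f = np.asarray(fitness, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValidationError("non-finite fitness in selection")
    fmin = f.min()
    fmax = f.max()
    if fmax == fmin:
        return np.full(len(f), 1.0 / len(f))
    if mode == "bounded":
        scaled = (f - fmin) + (fmax - fmin) / (pressure - 1.0)
    elif mode == "goldberg":
        if fmin < 0:
            f = f - fmin
            fmin, fmax = 0.0, fmax - fmin
        fave = f.mean()
        if fmin > (pressure * fave - fmax) / (pressure - 1.0):
            delta = fmax - fave
            a = (pressure - 1.0) * fave / delta
            b = fave * (fmax - pressure * fave) / delta
        else:
            delta = fave - fmin
            a = fave / delta
            b = -fmin * fave / delta
        scaled = np.abs(a * f + b)
    else:
        raise ValidationError(f"unknown scaling mode {mode!r}")
    return scaled / scaled.sum()


def select_parents(
    population: np.ndarray,
    fitness,
    rng: np.random.Generator,
    pressure: float = 2.0,
    mode: str = "goldberg",
) -> np.ndarray:
    """Fitness-proportionate mating pool of size N (with replacement)."""
    probs = linear_scaled_weights(fitness, pressure, mode)
    idx = rng.choice(len(population), size=len(population), p=probs)
    return population[idx]


def la_crossover(
    parent1: np.ndarray, parent2: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Local arithmetic crossover: per-gene convex combination."""
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    if p1.shape != p2.shape:
        raise ValidationError("parents must have equal length")
    a = rng.uniform(size=p1.shape)
    return a * p1 + (1 - a) * p2, a * p2 + (1 - a) * p1


def ra_mutation(
    chromosome: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random uniform mutation.

    Default mode: with probability ``mutation_prob`` per chromosome, one
    uniformly chosen gene is replaced by a fresh U(low, high) draw.
    ``per_gene_mutation`` instead redraws each gene independently with
    probability ``mutation_prob``.
    """
    out = np.array(chromosome, dtype=float)
    lows = np.array([b[0] for b in config.bounds])
    highs = np.array([b[1] for b in config.bounds])
    if config.per_gene_mutation:
        hit = rng.uniform(size=out.shape) < config.mutation_prob
        out[hit] = rng.uniform(lows, highs)[hit]
    elif rng.uniform() < config.mutation_prob:
        g = rng.integers(config.n_genes)
        out[g] = rng.uniform(lows[g], highs[g])
    return out


def _evaluate_fitness(fitness_fn, pop: np.ndarray) -> np.ndarray:
    fit = np.asarray(fitness_fn(pop), dtype=float)
    if fit.shape != (len(pop),):
        raise ValidationError("fitness_fn must return one value per chromosome")
    if not np.all(np.isfinite(fit)):
        i = int(np.argmax(~np.isfinite(fit)))
        raise ValidationError(f"non-finite fitness at chromosome {pop[i].tolist()}")
    return fit


def run_ga(fitness_fn, config: GAConfig) -> GAResult:
    """Maximize ``fitness_fn`` over the box.

    ``fitness_fn`` receives a (N, n_genes) array and must return N finite
    fitness values (vectorized evaluation keeps full runs cheap).  Elites
    of each generation replace the worst-evaluated offspring of the next,
    so the per-generation best never decreases.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng)
    records = []
    best_hist = []
    best_point = None
    best_fit = -np.inf
    n_elite = config.n_elite
    elites = elite_fit = None
    for gen in range(1, config.max_iterations + 1):
        fit = _evaluate_fitness(fitness_fn, pop)
        if elites is not None and n_elite > 0:
            worst = np.argsort(fit)[:n_elite]
            pop[worst] = elites
            fit[worst] = elite_fit
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_point = pop[gen_best].copy()
        records.append(
            dict(generation=gen, best=best_fit, mean=float(fit.mean()),
                 median=float(np.median(fit)))
        )
        best_hist.append(best_point.copy())
        if gen == config.max_iterations:
            break
        if n_elite > 0:
            keep = np.argsort(fit)[::-1][:n_elite]
            elites, elite_fit = pop[keep].copy(), fit[keep].copy()
        pool = select_parents(pop, fit, rng, config.selection_pressure,
                              config.selection_scaling)
        children = []
        for i in range(0, len(pool) - 1, 2):
            p1, p2 = pool[i], pool[i + 1]
            if rng.uniform() < config.crossover_prob:
                c1, c2 = la_crossover(p1, p2, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            children.extend([c1, c2])
        if len(pool) % 2 == 1:
            children.append(pool[-1].copy())
        children = [ra_mutation(c, config, rng) for c in children]
        pop = np.vstack(children)[: config.population_size]
    trace = GATrace(pd.DataFrame.from_records(records), np.array(best_hist))
    return GAResult(best_point, best_fit, trace)
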
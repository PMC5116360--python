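"""Genetic-algorithm feature-subset selection over the 16-bit mask space.

Each chromosome is a 16-bit inclusion mask over the feature vector; its
fitness is the 23-fold cross-validated KNN error rate theta (lower is
better).  The generational loop follows the study configuration:
population 300, up to 100 generations, linear rank selection (pressure
2.0) with 2-elitism, double-point crossover with probability 0.7,
per-bit mutation probability 0.05, and early stopping when the best-ever
fitness has not strictly decreased for 30 consecutive generations.

Fitness is memoised per unique mask (the space has only 2**16 points), so
the default 300 x 100 run costs far fewer cross-validations than it
schedules.  Empty masks are assigned the worst fitness (theta = 1) rather
than re-drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import FoldPlan, PerfMetrics, cross_validate

__all__ = [
    "GAConfig",
    "GARun",
    "init_population",
    "rank_select",
    "double_point_crossover",
    "mutate",
    "run_ga",
]


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 300
    generations: int = 100
    crossover_prob: float = 0.7
    mutation_prob: float = 0.05
    elitism: int = 2
    patience: int = 30
    seed: int = 0
    selection_pressure: float = 2.0  # linear ranking, in [1, 2]

    def __post_init__(self):
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.pop_size < 2 * self.elitism:
            raise ValueError("population must hold at least 2 x elitism members")


@dataclass
class GARun:
    """Best mask found, its metrics, and the per-generation history."""

    best_mask: np.ndarray
    best_theta: float
    best_metrics: PerfMetrics
    generation_best: list[float] = field(default_factory=list)
    best_ever_history: list[float] = field(default_factory=list)
    generations_run: int = 0
    n_evaluations: int = 0


def init_population(cfg: GAConfig, n_features: int = 16) -> np.ndarray:
    """Bernoulli(0.5) bits; all-zero chromosomes are re-drawn."""
    rng = np.random.default_rng(cfg.seed)
    pop = rng.integers(0, 2, size=(cfg.pop_size, n_features)).astype(bool)
    for i in range(cfg.pop_size):
        while not pop[i].any():
            pop[i] = rng.integers(0, 2, size=n_features).astype(bool)
    return pop


def _rank_probabilities(n: int, pressure: float) -> np.ndarray:
    # ranks: 0 = worst .. n-1 = best; linear ranking (Baker)
    ranks = np.arange(n, dtype=float)
    return (2 - pressure + 2 * (pressure - 1) * ranks / (n - 1)) / n


def rank_select(
    population: np.ndarray,
    fitness: np.ndarray,
    rng: np.random.Generator,
    n_pairs: int,
    pressure: float = 2.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw parent pairs with probability linear in fitness rank.

    Lower fitness (error) is better and receives the highest selection
    probability.  Ties in fitness are ranked by population index
    (deterministic).
    """
    if np.any(~np.isfinite(fitness)):
        raise ValueError("population has unevaluated or non-finite fitness")
    n = population.shape[0]
    order = np.argsort(-fitness, kind="stable")  # worst first -> rank 0
    probs = np.empty(n)
    probs[order] = _rank_probabilities(n, pressure)
    idx = rng.choice(n, size=(n_pairs, 2), p=probs)
    return [(population[i].copy(), population[j].copy()) for i, j in idx]


def double_point_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, pc: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the segment between two cut points with probability ``pc``."""
    if a.size != b.size:
        raise ValueError("chromosome length mismatch")
    c1, c2 = a.copy(), b.copy()
    if rng.random() < pc:
        i, j = np.sort(rng.choice(a.size + 1, size=2, replace=False))
        c1[i:j], c2[i:j] = b[i:j].copy(), a[i:j].copy()
    return c1, c2


def mutate(c: np.ndarray, pm: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``pm``."""
    flips = rng.random(c.size) < pm
    return np.logical_xor(c, flips)


def run_ga(
    table: pd.DataFrame,
    k_nn: int = 5,
    cfg: GAConfig | None = None,
    folds: FoldPlan | None = None,
    n_features: int = 16,
    minmax: str | None = "global",
) -> GARun:
    """Evolve feature masks against the cross-validated KNN error rate."""
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    if folds is None:
        from .classify import make_folds

        folds = make_folds(len(table), k=min(23, len(table)), seed=cfg.seed)

    cache: dict[bytes, tuple[float, PerfMetrics | None]] = {}
    n_evals = 0

    def fitness_of(mask: np.ndarray) -> float:
        nonlocal n_evals
        key = np.packbits(mask).tobytes()
        if key not in cache:
            if not mask.any():
                cache[key] = (1.0, None)
            else:
                m = cross_validate(table, mask=mask, k_nn=k_nn, folds=folds,
                                   minmax=minmax)
                cache[key] = (m.theta, m)
                n_evals += 1
        return cache[key][0]

    pop = init_population(cfg, n_features)
    run = GARun(best_mask=pop[0].copy(), best_theta=np.inf, best_metrics=None)
    stall = 0

    for gen in range(cfg.generations):
        fit = np.array([fitness_of(c) for c in pop])
        gen_best = float(fit.min())
        run.generation_best.append(gen_best)
        if gen_best < run.best_theta:
            run.best_theta = gen_best
            run.best_mask = pop[int(np.argmin(fit))].copy()
            stall = 0
        else:
            stall += 1
        run.best_ever_history.append(run.best_theta)
        run.generations_run = gen + 1
        if stall >= cfg.patience:
            break
        if gen == cfg.generations - 1:
            break

        # elitism: the cfg.elitism best chromosomes survive unchanged
        elite_idx = np.argsort(fit, kind="stable")[: cfg.elitism]
        next_pop = [pop[i].copy() for i in elite_idx]
        n_pairs = (cfg.pop_size - cfg.elitism + 1) // 2
        for pa, pb in rank_select(pop, fit, rng, n_pairs,
                                  pressure=cfg.selection_pressure):
            c1, c2 = double_point_crossover(pa, pb, rng, pc=cfg.crossover_prob)
            next_pop.append(mutate(c1, cfg.mutation_prob, rng))
            next_pop.append(mutate(c2, cfg.mutation_prob, rng))
        pop = np.array(next_pop[: cfg.pop_size])

    run.best_metrics = cache[np.packbits(run.best_mask).tobytes()][1]
    run.n_evaluations = n_evals
    return run
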
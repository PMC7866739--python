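"""Real-coded genetic algorithm used as the comparison optimizer.

Tournament selection, blend (BLX-alpha) crossover, Gaussian mutation
clipped to bounds, and elitist survival.  The incumbent best-so-far is
tracked separately from the population, so the reported trace is
non-decreasing for any configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["GAConfig", "GAResult", "ga_maximize"]


@dataclass
class GAConfig:
    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    crossover_alpha: float = 0.5
    mutation_rate: float = 0.1
    mutation_scale: float = 0.05  # fraction of each dimension's range
    tournament: int = 3
    elitism: int = 1
    seed: int | None = None

    def validate(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.elitism < self.population:
            raise ValueError("elitism must be in [0, population)")
        if self.tournament < 1:
            raise ValueError("tournament size must be >= 1")


@dataclass
class GAResult:
    x: np.ndarray
    fun: float
    trace: np.ndarray
    n_evals: int


def _evaluate(fitness, pop: np.ndarray) -> np.ndarray:
    out = np.full(len(pop), -np.inf)
    for i, ind in enumerate(pop):
        val = float(fitness(ind))
        if np.isfinite(val):
            out[i] = val
        else:
            warnings.warn(
                "non-finite fitness; individual excluded from selection",
                RuntimeWarning,
                stacklevel=3,
            )
    return out


def ga_maximize(
    fitness: Callable[[np.ndarray], float],
    bounds: Sequence[Sequence[float]],
    config: GAConfig | None = None,
) -> GAResult:
    """Maximize ``fitness`` over a box with a real-coded GA.

    Every individual is clipped into the box after each operator, so the
    whole population is feasible at all times.  Deterministic under a
    fixed seed.
    """
    cfg = config or GAConfig()
    cfg.validate()
    bounds = np.asarray(bounds, dtype=float)
    if not np.all(np.isfinite(bounds)) or not np.all(bounds[:, 0] < bounds[:, 1]):
        raise ValueError("bounds must be finite with lo < hi")
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = bounds.shape[0]
    rng = np.random.default_rng(cfg.seed)

    pop = rng.uniform(lo, hi, size=(cfg.population, d))
    fit = _evaluate(fitness, pop)
    n_evals = cfg.population

    best_i = int(np.argmax(fit))
    best_x, best_f = pop[best_i].copy(), fit[best_i]
    trace = np.empty(cfg.generations)

    def tournament() -> np.ndarray:
        idx = rng.integers(0, cfg.population, size=cfg.tournament)
        return pop[idx[np.argmax(fit[idx])]]

    for gen in range(cfg.generations):
        order = np.argsort(fit)[::-1]
        new = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new) < cfg.population:
            p1, p2 = tournament().copy(), tournament().copy()
            if rng.random() < cfg.crossover_rate:
                cmin = np.minimum(p1, p2)
                cmax = np.maximum(p1, p2)
                spread = cfg.crossover_alpha * (cmax - cmin)
                c1 = rng.uniform(cmin - spread, cmax + spread)
                c2 = rng.uniform(cmin - spread, cmax + spread)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                mask = rng.random(d) < cfg.mutation_rate
                if mask.any():
                    child[mask] += rng.normal(
                        0.0, cfg.mutation_scale * (hi - lo)[mask]
                    )
                if len(new) < cfg.population:
                    new.append(child)
        pop = np.clip(np.asarray(new), lo, hi)
        fit = _evaluate(fitness, pop)
        n_evals += cfg.population
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_f:
            best_f = fit[gen_best]
            best_x = pop[gen_best].copy()
        trace[gen] = best_f

    if not np.isfinite(best_f):
        raise RuntimeError("fitness was non-finite at every evaluated candidate")
    return GAResult(x=best_x, fun=best_f, trace=trace, n_evals=n_evals)
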
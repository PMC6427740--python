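"""Water wave optimization (WWO).

A population-based continuous maximizer in which every candidate solution is
a "wave" with a fitness-dependent wavelength.  Fitter waves get shorter
wavelengths and therefore propagate in smaller steps (exploitation), poorer
waves search more widely (exploration).  Whenever propagation produces a new
population best, that wave "breaks" into a few solitary waves — local
perturbations along randomly chosen dimensions — and keeps the best of them.

The update rules:

* wavelength:  lambda <- lambda * alpha^(-(f - f_min + eps)/(f_max - f_min + eps))
* propagation: x_i' = x_i + lambda * U(-1, 1) * L_i
* breaking:    x_i' = x*_i + N(0, 1) * beta * L_i   (k random dimensions)
* refraction:  x_i' ~ N((x*_i + x_i)/2, |x*_i - x_i|/2)  per dimension

where L_i is the length of the i-th dimension of the search box and x* the
population best.  Refraction fires when a wave has failed to improve for
h_max consecutive propagations: the stagnant wave is resampled between its
position and the best wave's, with dispersion shrinking as the two approach
— the operator that gives the method its late-stage precision.  Fitness is
maximized; wrap a loss with a sign flip or reciprocal to minimize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import OptimizationError, ValidationError

__all__ = ["WWOConfig", "WaveState", "OptimizeResult",
           "update_wavelength", "propagate", "break_wave", "refract", "optimize"]

Objective = Callable[[np.ndarray], float]


@dataclass
class WWOConfig:
    """WWO constants and the search box.

    ``bounds`` is an (D, 2) array of per-dimension (low, high); ``budget``
    counts objective evaluations *after* the initial population.  ``alpha``
    (wavelength-reduction coefficient) defaults to the recommended 1.0026 and
    ``lambda_init`` to 0.5.  ``beta`` decays linearly from ``beta_start`` to
    ``beta_end`` over the budget.  With ``recompute_from_init`` the
    wavelength update starts from ``lambda_init`` every generation instead of
    compounding.
    """

    bounds: np.ndarray
    population_size: int = 10
    alpha: float = 1.0026
    epsilon: float = 1e-12
    beta_start: float = 0.25
    beta_end: float = 0.001
    k_max: int = 12
    h_max: int = 6
    lambda_init: float = 0.5
    budget: int = 5000
    seed: int = 0
    recompute_from_init: bool = False

    def __post_init__(self):
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if self.bounds.shape[1] != 2 or np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValidationError("bounds must be (D, 2) with low < high")
        if self.alpha <= 1:
            raise ValidationError("alpha must exceed 1")
        if not 0 < self.beta_end <= self.beta_start:
            raise ValidationError("need 0 < beta_end <= beta_start")
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.h_max < 1:
            raise ValidationError("h_max must be >= 1")
        if self.budget < 0:
            raise ValidationError("budget must be nonnegative")

    @property
    def dim(self) -> int:
        return self.bounds.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        return self.bounds[:, 1] - self.bounds[:, 0]


@dataclass
class WaveState:
    """One candidate solution: position, wavelength, fitness (larger is better).

    ``height`` counts propagations remaining before the wave is deemed
    stagnant and refracted toward the population best.
    """

    position: np.ndarray
    wavelength: float
    fitness: float
    height: int = 6


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[tuple[int, float, float]] = field(default_factory=list)
    n_evaluations: int = 0


def update_wavelength(lam: float, f: float, f_min: float, f_max: float,
                      cfg: WWOConfig) -> float:
    """Shrink a wave's wavelength according to its relative fitness.

    Strictly decreasing in f for fixed lambda; the epsilon guard keeps the
    exponent finite when the whole population has equal fitness.
    """
    q = (f - f_min + cfg.epsilon) / (f_max - f_min + cfg.epsilon)
    return lam * cfg.alpha ** (-q)


def _evaluate(objective: Objective, x: np.ndarray) -> float:
    f = float(objective(x))
    if not np.isfinite(f):
        raise OptimizationError(f"objective returned non-finite value {f}", position=x)
    return f


def _repair(x: np.ndarray, cfg: WWOConfig, rng: np.random.Generator) -> np.ndarray:
    """Re-draw out-of-bound components uniformly inside the box."""
    lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]
    bad = (x < lo) | (x > hi)
    if np.any(bad):
        x = x.copy()
        x[bad] = rng.uniform(lo[bad], hi[bad])
    return x


def propagate(wave: WaveState, objective: Objective, cfg: WWOConfig,
              rng: np.random.Generator) -> WaveState:
    """Move a wave by a uniform offset of magnitude at most wavelength * L_i per axis."""
    u = rng.uniform(-1.0, 1.0, size=cfg.dim)
    x = wave.position + wave.wavelength * u * cfg.lengths
    x = _repair(x, cfg, rng)
    return WaveState(position=x, wavelength=wave.wavelength,
                     fitness=_evaluate(objective, x))


def break_wave(best: WaveState, objective: Objective, cfg: WWOConfig,
               rng: np.random.Generator, beta: float | None = None,
               max_evals: int | None = None) -> tuple[WaveState, int]:
    """Refine a new population best with k solitary waves; never returns worse.

    Each solitary wave perturbs one distinct random dimension by
    N(0,1) * beta * L_i.  Returns (best-of-candidates-and-input, evaluations
    used).  ``max_evals`` caps the number of solitary waves (budget guard).
    """
    if beta is None:
        beta = cfg.beta_start
    D = cfg.dim
    k = int(rng.integers(1, min(cfg.k_max, D) + 1))
    if max_evals is not None:
        k = min(k, max_evals)
    if k <= 0:
        return best, 0
    dims = rng.choice(D, size=k, replace=False)
    winner = best
    for i in dims:
        x = best.position.copy()
        x[i] = best.position[i] + rng.standard_normal() * beta * cfg.lengths[i]
        x = _repair(x, cfg, rng)
        f = _evaluate(objective, x)
        if f > winner.fitness:
            winner = WaveState(position=x, wavelength=best.wavelength, fitness=f,
                               height=cfg.h_max)
    return winner, k


def refract(wave: WaveState, best: WaveState, objective: Objective,
            cfg: WWOConfig, rng: np.random.Generator) -> WaveState:
    """Resample a stagnant wave between itself and the population best.

    Each component is drawn from N((x*_i + x_i)/2, |x*_i - x_i|/2), so the
    dispersion shrinks as the population converges; the refracted wave keeps
    its evolved wavelength (a sign-robust stand-in for the fitness-ratio
    rescaling, which assumes positive fitness) and its stagnation counter
    resets to h_max.
    """
    mid = 0.5 * (best.position + wave.position)
    sd = 0.5 * np.abs(best.position - wave.position)
    x = _repair(rng.normal(mid, sd), cfg, rng)
    return WaveState(position=x, wavelength=wave.wavelength,
                     fitness=_evaluate(objective, x), height=cfg.h_max)


def optimize(objective: Objective, cfg: WWOConfig,
             initial_positions: Sequence[np.ndarray] | None = None,
             generation_hook: Callable[[WaveState, int], None] | None = None,
             ) -> OptimizeResult:
    """Run WWO until the evaluation budget is spent.

    The population is initialized uniformly in the box (optionally replacing
    the first waves with ``initial_positions``, clipped into bounds) with
    wavelength ``lambda_init``.  Each generation every wave propagates and
    replaces its parent only if fitter (elitism); a strict improvement of the
    population best triggers breaking.  Wavelengths are updated from the
    population fitness spread at the end of each generation.

    ``generation_hook(best_wave, generation)`` runs at the start of every
    generation — used by evolutionary fine-tuning to refresh the output head
    (which may change the objective's scoring state between generations).
    Best-so-far fitness is non-decreasing and the whole run is deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds[:, 0], cfg.bounds[:, 1]

    positions = rng.uniform(lo, hi, size=(cfg.population_size, cfg.dim))
    if initial_positions is not None:
        for i, p in enumerate(initial_positions[:cfg.population_size]):
            positions[i] = np.clip(np.asarray(p, dtype=float), lo, hi)

    waves = [WaveState(position=positions[i].copy(), wavelength=cfg.lambda_init,
                       fitness=_evaluate(objective, positions[i]),
                       height=cfg.h_max)
             for i in range(cfg.population_size)]
    evals = 0  # budget counts post-initialization evaluations

    best = max(waves, key=lambda w: w.fitness)
    best = WaveState(best.position.copy(), best.wavelength, best.fitness)
    history: list[tuple[int, float, float]] = []
    generation = 0

    while evals < cfg.budget:
        if generation_hook is not None:
            generation_hook(best, generation)
        progress = evals / cfg.budget
        beta = cfg.beta_start + (cfg.beta_end - cfg.beta_start) * progress
        pop_best_fitness = max(w.fitness for w in waves)

        for idx in range(cfg.population_size):
            if evals >= cfg.budget:
                break
            new = propagate(waves[idx], objective, cfg, rng)
            evals += 1
            if new.fitness > waves[idx].fitness:
                new.height = cfg.h_max
                waves[idx] = new
                if new.fitness > pop_best_fitness:
                    # new population best: break it into solitary waves
                    refined, used = break_wave(
                        new, objective, cfg, rng, beta=beta,
                        max_evals=cfg.budget - evals)
                    evals += used
                    waves[idx] = refined
                    pop_best_fitness = refined.fitness
            else:
                waves[idx].height -= 1
                if waves[idx].height <= 0 and evals < cfg.budget:
                    pop_best = max(waves, key=lambda w: w.fitness)
                    waves[idx] = refract(waves[idx], pop_best, objective, cfg, rng)
                    evals += 1
                    if waves[idx].fitness > pop_best_fitness:
                        pop_best_fitness = waves[idx].fitness

        gen_best = max(waves, key=lambda w: w.fitness)
        if gen_best.fitness > best.fitness:
            best = WaveState(gen_best.position.copy(), gen_best.wavelength,
                             gen_best.fitness)

        f_vals = [w.fitness for w in waves]
        f_min, f_max = min(f_vals), max(f_vals)
        for w in waves:
            base = cfg.lambda_init if cfg.recompute_from_init else w.wavelength
            w.wavelength = update_wavelength(base, w.fitness, f_min, f_max, cfg)

        generation += 1
        history.append((generation, best.fitness,
                        float(np.mean([w.wavelength for w in waves]))))

    return OptimizeResult(best_position=best.position, best_fitness=best.fitness,
                          history=history, n_evaluations=evals)
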
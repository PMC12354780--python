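"""Gravitational Optimization: a population metaheuristic where candidate
solutions attract one another with forces proportional to fitness-derived
masses.

The update scheme is the canonical gravitational-search algorithm:

* masses  m_i = (worst - fit_i) / (worst - best), normalized to sum to 1;
* force on particle i from each of the Kbest heaviest particles j:
  rand_ij * G(t) * m_i m_j (x_j - x_i) / (||x_j - x_i|| + eps);
* G(t) = g0 * exp(-beta * t / T), so the search moves from exploration to
  exploitation as G decays;
* acceleration = force / m_i (the m_i cancels algebraically, which also keeps
  the worst particle, whose mass is 0, moving);
* velocity = rand_i * velocity + acceleration; position += velocity, clamped
  to bounds;
* Kbest shrinks linearly from the whole population to kbest_final * population.

Two variants share this loop: a continuous one for hyperparameter tuning and a
binary one for wrapper feature selection, where a bit flips with probability
|tanh(velocity)| and fitness is a cross-validated classifier loss plus a
sparsity penalty.  Minimization throughout; maximize by negating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("uigo.gravity_opt")

__all__ = ["GOConfig", "GOResult", "optimize", "select_features",
           "tune_hyperparameters", "decode_position"]

_DIST_EPS = 1e-12


@dataclass(frozen=True)
class GOConfig:
    population: int = 25
    iterations: int = 100
    g0: float = 100.0
    beta: float = 20.0
    kbest_final: float = 0.04
    bounds: tuple[tuple[float, float], ...] = ()
    mode: str = "continuous"           # "continuous" | "binary"
    seed: int = 0
    patience: int | None = None        # early stop after this many stagnant iterations

    def validate(self) -> None:
        if self.population < 2:
            raise ValueError(f"population must be >= 2, got {self.population}")
        if not 0.0 < self.kbest_final <= 1.0:
            raise ValueError(f"kbest_final must be in (0,1], got {self.kbest_final}")
        if self.g0 <= 0 or self.beta <= 0:
            raise ValueError("g0 and beta must be positive")
        if self.mode not in ("continuous", "binary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "continuous":
            for lo, hi in self.bounds:
                if not lo < hi:
                    raise ValueError(f"bad bound ({lo}, {hi})")


@dataclass
class GOResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    evaluations: int = 0
    converged_at: int | None = None
    trace: pd.DataFrame | None = None


def _masses(fitness: np.ndarray) -> np.ndarray:
    worst, best = fitness.max(), fitness.min()
    if worst == best:
        return np.full(len(fitness), 1.0 / len(fitness))
    m = (worst - fitness) / (worst - best)
    return m / m.sum()


def optimize(fitness, cfg: GOConfig) -> GOResult:
    """Minimize `fitness` over cfg.bounds with the gravitational-search loop."""
    cfg.validate()
    if not cfg.bounds:
        raise ValueError("continuous optimization needs bounds")
    rng = np.random.default_rng(cfg.seed)
    d = len(cfg.bounds)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    pop = cfg.population
    pos = rng.uniform(lo, hi, size=(pop, d))
    vel = np.zeros((pop, d))

    def evaluate(p):
        val = float(fitness(p))
        if not np.isfinite(val):
            raise ValueError(f"non-finite fitness {val} at position {p}")
        return val

    fit = np.array([evaluate(p) for p in pos])
    evals = pop
    best_i = int(fit.argmin())
    best_pos, best_fit = pos[best_i].copy(), float(fit[best_i])
    history = [best_fit]
    trace_rows = []
    stagnant, converged_at = 0, None

    T = cfg.iterations
    for t in range(T):
        g = cfg.g0 * np.exp(-cfg.beta * t / T)
        masses = _masses(fit)
        kbest = max(2, int(round(pop - (pop - cfg.kbest_final * pop) * t / max(T - 1, 1))))
        elite = np.argsort(fit)[:kbest]

        accel = np.zeros((pop, d))
        for j in elite:
            diff = pos[j] - pos                      # (pop, d)
            dist = np.linalg.norm(diff, axis=1, keepdims=True)
            r = rng.random((pop, d))
            accel += r * g * masses[j] * diff / (dist + _DIST_EPS)
        vel = rng.random((pop, d)) * vel + accel
        pos = np.clip(pos + vel, lo, hi)

        fit = np.array([evaluate(p) for p in pos])
        evals += pop
        i = int(fit.argmin())
        if fit[i] < best_fit:
            best_fit, best_pos = float(fit[i]), pos[i].copy()
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_fit)
        trace_rows.append({"iteration": t, "best_fitness": best_fit,
                           "mean_fitness": float(fit.mean()), "kbest": kbest, "G": g})
        if cfg.patience is not None and stagnant >= cfg.patience:
            converged_at = t
            logger.info("GO converged (patience) at iteration %d", t)
            break

    return GOResult(best_position=best_pos, best_fitness=best_fit, history=history,
                    evaluations=evals, converged_at=converged_at,
                    trace=pd.DataFrame(trace_rows))


# -- binary variant: wrapper feature selection --------------------------------

def _binary_loop(scorer, d: int, cfg: GOConfig):
    rng = np.random.default_rng(cfg.seed)
    pop = cfg.population
    pos = (rng.random((pop, d)) < 0.5).astype(float)
    vel = np.zeros((pop, d))
    worst_seen = -np.inf
    cache: dict[bytes, float] = {}

    def repair(bits):
        if bits.any():
            return bits
        # empty subset: fall back to the best single feature
        singles = []
        for j in range(d):
            e = np.zeros(d)
            e[j] = 1.0
            singles.append(evaluate(e))
        best_j = int(np.argmin(singles))
        out = np.zeros(d)
        out[best_j] = 1.0
        return out

    n_evals = 0

    def evaluate(bits):
        nonlocal worst_seen, n_evals
        key = bits.astype(np.uint8).tobytes()
        if key in cache:
            return cache[key]
        try:
            val = float(scorer(bits.astype(bool)))
        except Exception as exc:       # scorer failure: worst-so-far fitness
            logger.warning("scorer failed on subset (%s); assigning worst fitness", exc)
            val = worst_seen if np.isfinite(worst_seen) else 1e9
        worst_seen = max(worst_seen, val)
        cache[key] = val
        n_evals += 1
        return val

    pos = np.array([repair(p) for p in pos])
    fit = np.array([evaluate(p) for p in pos])
    best_i = int(fit.argmin())
    best_pos, best_fit = pos[best_i].copy(), float(fit[best_i])
    history = [best_fit]
    stagnant, converged_at = 0, None

    T = cfg.iterations
    for t in range(T):
        g = cfg.g0 * np.exp(-cfg.beta * t / T)
        masses = _masses(fit)
        kbest = max(2, int(round(pop - (pop - cfg.kbest_final * pop) * t / max(T - 1, 1))))
        elite = np.argsort(fit)[:kbest]
        accel = np.zeros((pop, d))
        for j in elite:
            diff = pos[j] - pos
            dist = np.linalg.norm(diff, axis=1, keepdims=True)
            r = rng.random((pop, d))
            accel += r * g * masses[j] * diff / (dist + _DIST_EPS)
        vel = rng.random((pop, d)) * vel + accel
        flip = rng.random((pop, d)) < np.abs(np.tanh(vel))
        pos = np.where(flip, 1.0 - pos, pos)
        pos = np.array([repair(p) for p in pos])
        fit = np.array([evaluate(p) for p in pos])
        i = int(fit.argmin())
        if fit[i] < best_fit:
            best_fit, best_pos = float(fit[i]), pos[i].copy()
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_fit)
        if cfg.patience is not None and stagnant >= cfg.patience:
            converged_at = t
            break

    return GOResult(best_position=best_pos, best_fitness=best_fit, history=history,
                    evaluations=n_evals, converged_at=converged_at)


def select_features(feature_table: pd.DataFrame, labels: np.ndarray, scorer,
                    cfg: GOConfig, sparsity: float = 0.05):
    """Binary GO search for the feature subset minimizing
    scorer(X[:, subset], y) + sparsity * |subset| / d.

    Returns (boolean mask over columns, GOResult).
    """
    cfg.validate()
    if cfg.mode != "binary":
        raise ValueError("select_features requires mode='binary'")
    d = feature_table.shape[1]
    if d < 2:
        raise ValueError(f"need at least 2 features, got {d}")
    X = feature_table.to_numpy(dtype=float)
    y = np.asarray(labels)

    def subset_fitness(mask: np.ndarray) -> float:
        return float(scorer(X[:, mask], y)) + sparsity * mask.sum() / d

    result = _binary_loop(subset_fitness, d, cfg)
    return result.best_position.astype(bool), result


# -- continuous variant: hyperparameter tuning --------------------------------

def decode_position(space: dict, position: np.ndarray) -> dict:
    """Map an encoded search position to named parameter values.

    log-kind coordinates live in log10 space; int-kind are rounded to the
    nearest integer (31.6 decodes to 32).
    """
    params = {}
    for name, x in zip(space, position):
        _, _, kind = space[name]
        if kind == "log":
            params[name] = 10.0 ** x
        elif kind == "int":
            params[name] = int(round(x))
        else:
            params[name] = float(x)
    return params


def tune_hyperparameters(train_fn, space: dict, cfg: GOConfig):
    """GO search over a named parameter space.

    `space` maps names to (low, high, kind) with kind in {"float", "log",
    "int"}: log-kind parameters are searched in log10 space, int-kind are
    rounded on decoding.  `train_fn(params dict) -> validation loss`; an
    exception is treated as the worst fitness seen so far and the search
    continues.  Returns (best params dict, GOResult).
    """
    names = list(space)
    bounds = []
    for name in names:
        lo, hi, kind = space[name]
        if kind == "log":
            bounds.append((np.log10(lo), np.log10(hi)))
        else:
            bounds.append((float(lo), float(hi)))
    cfg = replace(cfg, bounds=tuple(bounds), mode="continuous")

    def decode(position: np.ndarray) -> dict:
        return decode_position(space, position)

    worst_seen = -np.inf

    def fitness(position: np.ndarray) -> float:
        nonlocal worst_seen
        try:
            val = float(train_fn(decode(position)))
        except Exception as exc:
            logger.warning("train_fn failed (%s); assigning worst fitness", exc)
            val = worst_seen if np.isfinite(worst_seen) else 1e9
        worst_seen = max(worst_seen, val)
        return val

    result = optimize(fitness, cfg)
    return decode(result.best_position), result
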
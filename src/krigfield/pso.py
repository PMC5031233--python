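"""Bounded particle swarm maximizer.

Standard constricted PSO (inertia 0.72, cognitive/social 1.49) with
box-clipped positions, velocity clamping to the box width and velocity
zeroing at the boundary.  Deterministic for a given seed.  Objectives that
return NaN penalize the particle with -inf; the run continues.
"""
from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

__all__ = ["PSOConfig", "maximize"]


@dataclasses.dataclass
class PSOConfig:
    swarm_size: int = 50
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    max_iters: int = 200
    tol: float = 1e-8
    stagnation_iters: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be at least 2")
        if not 0 < self.inertia < 1:
            raise ValueError("inertia must lie in (0, 1)")


def maximize(
    objective: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    cfg: PSOConfig | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Maximize objective over the box [lower, upper].

    Returns (x_best, f_best, trace) where trace[k] is the best objective
    seen up to iteration k (non-decreasing).
    """
    cfg = cfg or PSOConfig()
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or np.any(~np.isfinite(lower)) or np.any(~np.isfinite(upper)):
        raise ValueError("bounds must be finite and of equal shape")
    if np.any(lower > upper):
        raise ValueError("lower bound exceeds upper bound")
    dim = lower.size
    width = upper - lower
    rng = np.random.default_rng(cfg.seed)

    def safe_eval(x: np.ndarray) -> float:
        v = objective(x)
        return -np.inf if (v is None or np.isnan(v)) else float(v)

    pos = lower + rng.uniform(size=(cfg.swarm_size, dim)) * width
    vel = (rng.uniform(size=(cfg.swarm_size, dim)) - 0.5) * width
    fvals = np.array([safe_eval(p) for p in pos])
    pbest, pbest_f = pos.copy(), fvals.copy()
    gi = int(np.argmax(pbest_f))
    gbest, gbest_f = pbest[gi].copy(), pbest_f[gi]
    if not np.isfinite(gbest_f) and np.all(np.isinf(pbest_f)):
        # give the swarm one shot to recover; if every particle is NaN the
        # objective is unusable
        raise ValueError("objective returned NaN for every initial particle")

    trace = [gbest_f]
    stagnant = 0
    for _ in range(cfg.max_iters):
        r1 = rng.uniform(size=(cfg.swarm_size, dim))
        r2 = rng.uniform(size=(cfg.swarm_size, dim))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive * r1 * (pbest - pos)
            + cfg.social * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -width, width)
        pos = pos + vel
        below, above = pos < lower, pos > upper
        vel[below | above] = 0.0
        pos = np.clip(pos, lower, upper)
        fvals = np.array([safe_eval(p) for p in pos])
        improved = fvals > pbest_f
        pbest[improved] = pos[improved]
        pbest_f[improved] = fvals[improved]
        gi = int(np.argmax(pbest_f))
        if pbest_f[gi] > gbest_f + cfg.tol:
            stagnant = 0
        else:
            stagnant += 1
        if pbest_f[gi] > gbest_f:
            gbest, gbest_f = pbest[gi].copy(), pbest_f[gi]
        trace.append(gbest_f)
        if stagnant >= cfg.stagnation_iters:
            break
    if not np.isfinite(gbest_f):
        raise ValueError("objective returned NaN everywhere the swarm looked")
    return gbest, gbest_f, np.array(trace)
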
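"""Particle swarm optimization of SVR hyperparameters.

Standard velocity-position PSO with a linearly decaying inertia weight

    w(iter) = w_min + (iter_max - iter) * (w_max - w_min) / iter_max

and the update

    v <- w*v + c1*rand*(pbest - x) + c2*rand*(gbest - x)
    x <- x + v

(``rand`` drawn per dimension by default).  Velocities are clamped to a
fraction of each dimension's range and positions clipped to the box.  The
search terminates at ``iter_max`` or when the global best has not improved
for ``stall_patience`` iterations.

The search space mirrors the SVR tuning problem: 3 dimensions for the
single (RBF) kernel (epsilon, C, sigma), 5 for the double kernel (+ RBF
weight a and polynomial order q), 6 for the triple kernel (+ polynomial
weight b, with b <= 1 - a enforced at decode).  The polynomial order is
searched continuously in [1, 3] and rounded to {1, 2, 3} when a position is
decoded.  Fitness is the k-fold cross-validated RMSE of the decoded SVR on
the training data (smaller is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .kernels import KernelSpec
from .svr import SvrConvergenceError, SvrHyperParams, fit_svr, predict

__all__ = [
    "PsoConfig",
    "Swarm",
    "SearchSpace",
    "inertia_weight",
    "init_swarm",
    "step_swarm",
    "optimize",
    "decode_position",
    "cv_rmse_objective",
]


@dataclass(frozen=True)
class PsoConfig:
    """Swarm size, learning factors, inertia schedule, bounds and seed."""

    swarm_size: int = 30
    iter_max: int = 100
    c1: float = 2.0
    c2: float = 2.0
    omega_max: float = 0.9
    omega_min: float = 0.4
    bounds: tuple[tuple[float, float], ...] = ()
    seed: int = 0
    v_clamp_frac: float = 0.5
    stall_patience: int = 20
    rand_mode: str = "per_dimension"  # or "per_particle"

    def __post_init__(self) -> None:
        if self.omega_min > self.omega_max:
            raise ValueError("omega_min must not exceed omega_max")
        if not (0 < self.v_clamp_frac <= 1):
            raise ValueError("v_clamp_frac must be in (0, 1]")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")
        if self.rand_mode not in ("per_dimension", "per_particle"):
            raise ValueError(f"unknown rand_mode {self.rand_mode!r}")


@dataclass
class Swarm:
    """Positions, velocities and personal bests of all particles."""

    positions: np.ndarray  # (swarm, dim)
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray


# The hyperparameter box: epsilon in [0, 0.8], C in [0.001, 200],
# sigma in [0.001, 5], a in [0, 1], q in {1, 2, 3}, b in [0, 1 - a].
_RANGES = {
    "epsilon": (0.0, 0.8),
    "c": (0.001, 200.0),
    "sigma": (0.001, 5.0),
    "a": (0.0, 1.0),
    "q": (1.0, 3.0),
    "b": (0.0, 1.0),
}
_FAMILY_DIMS = {
    "single": ("epsilon", "c", "sigma"),
    "double": ("epsilon", "c", "sigma", "a", "q"),
    "triple": ("epsilon", "c", "sigma", "a", "q", "b"),
}


@dataclass(frozen=True)
class SearchSpace:
    """Named, bounded dimensions of the SVR tuning problem for one family."""

    family: str = "triple"

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_DIMS:
            raise ValueError(f"unknown kernel family {self.family!r}")

    @property
    def dim_names(self) -> tuple[str, ...]:
        return _FAMILY_DIMS[self.family]

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple(_RANGES[d] for d in self.dim_names)

    @property
    def dimension(self) -> int:
        return len(self.dim_names)


def inertia_weight(cfg: PsoConfig, iteration: int) -> float:
    """Linearly decaying inertia: w_max at iteration 0, w_min at iter_max."""
    if not 0 <= iteration <= cfg.iter_max:
        raise ValueError(f"iteration {iteration} outside [0, {cfg.iter_max}]")
    return cfg.omega_min + (cfg.iter_max - iteration) * (cfg.omega_max - cfg.omega_min) / cfg.iter_max


def init_swarm(cfg: PsoConfig, rng: np.random.Generator) -> Swarm:
    """Uniform random positions in the box; velocities start at zero."""
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    pos = rng.uniform(lo, hi, size=(cfg.swarm_size, lo.size))
    vel = np.zeros_like(pos)
    return Swarm(pos, vel, pos.copy(), np.full(cfg.swarm_size, np.inf))


def step_swarm(swarm: Swarm, gbest: np.ndarray, cfg: PsoConfig, iteration: int,
               rng: np.random.Generator) -> Swarm:
    """One velocity/position update of every particle (in place).

    Uses the inertia weight for ``iteration``; random accelerations are drawn
    per dimension (or per particle under ``rand_mode="per_particle"``) from
    the given generator, so trajectories are reproducible from the seed.
    """
    w = inertia_weight(cfg, iteration)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    v_max = cfg.v_clamp_frac * (hi - lo)
    shape = swarm.positions.shape if cfg.rand_mode == "per_dimension" else (
        swarm.positions.shape[0], 1)
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    swarm.velocities = (
        w * swarm.velocities
        + cfg.c1 * r1 * (swarm.pbest_positions - swarm.positions)
        + cfg.c2 * r2 * (gbest[None, :] - swarm.positions)
    )
    np.clip(swarm.velocities, -v_max, v_max, out=swarm.velocities)
    swarm.positions = np.clip(swarm.positions + swarm.velocities, lo, hi)
    return swarm


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace | Sequence[tuple[float, float]],
    cfg: PsoConfig,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize ``objective`` over the box by PSO.

    Returns ``(best position, best fitness, gbest-fitness history)``; the
    history has one entry per completed iteration (including initialization)
    and is non-increasing.  Non-finite objective values are treated as +inf.
    """
    bounds = space.bounds if isinstance(space, SearchSpace) else tuple(space)
    cfg = PsoConfig(**{**cfg.__dict__, "bounds": bounds})
    rng = np.random.default_rng(cfg.seed)
    swarm = init_swarm(cfg, rng)

    def safe_eval(x: np.ndarray) -> float:
        val = float(objective(x))
        return val if np.isfinite(val) else np.inf

    fitness = np.array([safe_eval(x) for x in swarm.positions])
    swarm.pbest_fitness = fitness.copy()
    g_idx = int(np.argmin(fitness))
    gbest = swarm.positions[g_idx].copy()
    gbest_fit = float(fitness[g_idx])
    history = [gbest_fit]
    stall = 0
    for it in range(1, cfg.iter_max + 1):
        step_swarm(swarm, gbest, cfg, it, rng)
        fitness = np.array([safe_eval(x) for x in swarm.positions])
        improved = fitness < swarm.pbest_fitness
        swarm.pbest_positions[improved] = swarm.positions[improved]
        swarm.pbest_fitness[improved] = fitness[improved]
        b_idx = int(np.argmin(swarm.pbest_fitness))
        if swarm.pbest_fitness[b_idx] < gbest_fit:
            gbest_fit = float(swarm.pbest_fitness[b_idx])
            gbest = swarm.pbest_positions[b_idx].copy()
            stall = 0
        else:
            stall += 1
        history.append(gbest_fit)
        if stall >= cfg.stall_patience:
            break
    return gbest, gbest_fit, history


def decode_position(x, space: SearchSpace) -> tuple[SvrHyperParams, KernelSpec]:
    """Map a raw swarm position to (hyperparameters, kernel spec).

    Continuous dimensions pass through; q is rounded to the nearest of
    {1, 2, 3}; for the triple family b is clipped to [0, 1 - a] so the
    mixture weights stay on the simplex.
    """
    x = np.asarray(x, dtype=float).ravel()
    names = space.dim_names
    if x.size != len(names):
        raise ValueError(f"position of size {x.size} for {len(names)}-D space")
    v = dict(zip(names, x))
    hyper = SvrHyperParams(epsilon=float(v["epsilon"]), c=float(v["c"]))
    if space.family == "single":
        spec = KernelSpec("single", sigma=float(v["sigma"]))
    elif space.family == "double":
        q = int(np.clip(round(v["q"]), 1, 3))
        a = float(np.clip(v["a"], 0.0, 1.0))
        spec = KernelSpec("double", sigma=float(v["sigma"]), q=q, a=a, b=1.0 - a)
    else:
        q = int(np.clip(round(v["q"]), 1, 3))
        a = float(np.clip(v["a"], 0.0, 1.0))
        b = float(np.clip(v["b"], 0.0, 1.0 - a))
        spec = KernelSpec("triple", sigma=float(v["sigma"]), q=q, a=a, b=b)
    return hyper, spec


def cv_rmse_objective(
    X, y, space: SearchSpace, folds: int = 5, seed: int = 0, *,
    fitness: str = "cv", max_passes: int = 50_000,
) -> Callable[[np.ndarray], float]:
    """Build the PSO fitness function: mean validation-fold RMSE.

    The k-fold partition of the training data is fixed by ``seed``, so the
    objective is deterministic in (position, seed).  A fold whose SVR fit
    fails to converge contributes +inf.  ``fitness="train_rmse"`` instead
    scores the RMSE on the full training data (no held-out folds).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if fitness not in ("cv", "train_rmse"):
        raise ValueError(f"unknown fitness mode {fitness!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    parts = np.array_split(order, folds)

    def objective(position: np.ndarray) -> float:
        hyper, spec = decode_position(position, space)
        try:
            if fitness == "train_rmse":
                model = fit_svr(X, y, spec, hyper, max_passes=max_passes)
                resid = y - predict(model, X)
                return float(np.sqrt(np.mean(resid**2)))
            sq_errs = []
            for part in parts:
                mask = np.ones(n, dtype=bool)
                mask[part] = False
                model = fit_svr(X[mask], y[mask], spec, hyper, max_passes=max_passes)
                resid = y[part] - predict(model, X[part])
                sq_errs.append(float(np.sqrt(np.mean(resid**2))))
            return float(np.mean(sq_errs))
        except (SvrConvergenceError, ValueError):
            return np.inf

    return objective
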
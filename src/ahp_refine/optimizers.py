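"""Particle swarm, simulated-annealing acceptance, and the hybrid loop.

The hybrid minimizer runs a standard particle swarm and, whenever the swarm's
global best is still above the error threshold, performs one annealed
neighborhood sweep around it: candidate points are drawn uniformly in a
shrinking box around Gbest, a better candidate replaces Gbest outright, and a
worse one may replace the *working* Gbest with probability exp(-dE/T).  The
temperature follows a geometric schedule T <- gamma * T (cooled once per
generation, after the sweep) and the neighborhood radius decays geometrically
each generation.  A protected best-ever incumbent is tracked separately so
probabilistic acceptance can redirect the swarm without ever degrading the
reported result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Particle",
    "SwarmConfig",
    "AnnealConfig",
    "OptResult",
    "update_velocity",
    "update_position",
    "accept_probability",
    "cool",
    "generate_neighbors",
    "pso_run",
    "pso_sa_run",
]


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_value: float


@dataclass(frozen=True)
class SwarmConfig:
    """Particle-swarm parameters.

    ``vmax`` clamps each velocity component to +-vmax; ``None`` defaults to
    one quarter of the box width per dimension.  ``error_threshold`` is the
    objective level at which the search stops (and below which the hybrid
    skips its annealed neighborhood sweep).
    """

    swarm_size: int = 30
    inertia: float = 0.7
    c1: float = 2.0
    c2: float = 2.0
    vmax: np.ndarray | float | None = None
    max_iterations: int = 500
    error_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ValueError("swarm_size must be positive")
        if not 0.0 < self.inertia <= 1.0:
            raise ValueError("inertia must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.error_threshold < 0:
            raise ValueError("error_threshold must be non-negative")
        if self.vmax is not None and np.any(np.asarray(self.vmax) <= 0):
            raise ValueError("vmax must be positive")


@dataclass(frozen=True)
class AnnealConfig:
    """Annealed-neighborhood parameters for the hybrid loop.

    ``t0`` is the initial temperature, ``gamma`` the geometric cooling factor,
    ``radius0`` the initial half-width of the uniform neighborhood box around
    Gbest and ``radius_decay`` its per-generation shrink factor.
    """

    t0: float = 1.0
    gamma: float = 0.9
    neighborhood_size: int = 10
    radius0: float = 0.5
    radius_decay: float = 0.95

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        if self.neighborhood_size < 1:
            raise ValueError("neighborhood_size must be positive")
        if self.radius0 <= 0:
            raise ValueError("radius0 must be positive")
        if not 0.0 < self.radius_decay < 1.0:
            raise ValueError("radius_decay must be in (0, 1)")


@dataclass(frozen=True)
class OptResult:
    best_position: np.ndarray
    best_value: float
    trace: np.ndarray  # best-ever objective after each iteration (non-increasing)
    iterations_used: int
    seed: int
    accepted_uphill_moves: int = 0
    evaluations: int = 0


def _resolve_bounds(bounds, dim=None):
    lo, hi = bounds
    lo = np.atleast_1d(np.asarray(lo, dtype=float))
    hi = np.atleast_1d(np.asarray(hi, dtype=float))
    if dim is not None and lo.size == 1:
        lo = np.full(dim, lo[0])
        hi = np.full(dim, hi[0])
    if np.any(hi <= lo):
        raise ValueError("upper bounds must exceed lower bounds")
    return lo, hi


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Fold points into the box by reflection; returns (folded, flipped mask)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    over = y > width
    y = np.where(over, 2.0 * width - y, y)
    # odd number of wall bounces flips the travel direction
    bounces = np.floor_divide(x - lo, width).astype(int)
    flipped = (bounces % 2) != 0
    return lo + y, flipped


def update_velocity(
    p: Particle, gbest: np.ndarray, cfg: SwarmConfig, rng: np.random.Generator,
    vmax: np.ndarray | None = None,
) -> np.ndarray:
    """New velocity: inertia + cognitive pull to pbest + social pull to gbest.

    r1 and r2 are fresh uniform(0,1) draws per component; the result is
    clamped to +-vmax componentwise.
    """
    d = len(p.position)
    r1 = rng.random(d)
    r2 = rng.random(d)
    v = (
        cfg.inertia * p.velocity
        + cfg.c1 * r1 * (p.pbest_position - p.position)
        + cfg.c2 * r2 * (gbest - p.position)
    )
    if vmax is None and cfg.vmax is not None:
        vmax = np.broadcast_to(np.asarray(cfg.vmax, dtype=float), (d,))
    if vmax is not None:
        v = np.clip(v, -vmax, vmax)
    return v


def update_position(p: Particle, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Move the particle by its velocity, reflecting at the box walls.

    Reflection flips the corresponding velocity component so particles do
    not stick to the boundary.
    """
    x, flipped = _reflect(p.position + p.velocity, lo, hi)
    p.velocity = np.where(flipped, -p.velocity, p.velocity)
    return x


def accept_probability(delta_e: float, T: float) -> float:
    """Metropolis acceptance: 1 for an improving move, exp(-dE/T) otherwise."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_e < 0:
        return 1.0
    return math.exp(-delta_e / T)


def cool(T: float, gamma: float) -> float:
    """Geometric cooling step T <- gamma * T with gamma in (0, 1)."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must be in (0, 1)")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return gamma * T


def generate_neighbors(
    center: np.ndarray,
    radius: float,
    count: int,
    bounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform box perturbations of the center, reflected into bounds."""
    if count < 1:
        raise ValueError("count must be at least 1")
    lo, hi = _resolve_bounds(bounds, dim=len(center))
    pts = center[None, :] + rng.uniform(-radius, radius, size=(count, len(center)))
    pts, _ = _reflect(pts, lo, hi)
    return pts


def pso_run(
    objective,
    bounds,
    cfg: SwarmConfig,
    x0=None,
    callback=None,
    max_evals: int | None = None,
    vectorized: bool = False,
) -> OptResult:
    """Minimize ``objective`` over a box with a standard particle swarm.

    ``x0`` optionally seeds the first particles at given positions (warm
    start).  ``callback(iteration, best_value, best_position, temperature,
    radius)`` is invoked after each iteration (temperature and radius are
    None for the plain swarm).  ``max_evals`` optionally caps total objective
    evaluations (for function-evaluation-budget comparisons).  With
    ``vectorized=True`` the objective is called once per generation with a
    (batch, dim) array and must return a length-batch vector.
    """
    return _swarm_loop(objective, bounds, cfg, None, x0, callback, max_evals, vectorized)


def pso_sa_run(
    objective,
    bounds,
    swarm_cfg: SwarmConfig,
    anneal_cfg: AnnealConfig | None = None,
    x0=None,
    callback=None,
    max_evals: int | None = None,
    vectorized: bool = False,
) -> OptResult:
    """Hybrid swarm + annealed Gbest-neighborhood minimization."""
    if anneal_cfg is None:
        anneal_cfg = AnnealConfig()
    return _swarm_loop(
        objective, bounds, swarm_cfg, anneal_cfg, x0, callback, max_evals, vectorized
    )


def _swarm_loop(objective, bounds, cfg, anneal, x0, callback, max_evals, vectorized=False):
    rng = np.random.default_rng(cfg.seed)
    dim = None
    if x0 is not None:
        x0 = [np.asarray(x, dtype=float) for x in x0]
        dim = len(x0[0])
    lo, hi = _resolve_bounds(bounds, dim=dim)
    dim = len(lo)
    if cfg.vmax is None:
        vmax = 0.25 * (hi - lo)
    else:
        vmax = np.broadcast_to(np.asarray(cfg.vmax, dtype=float), (dim,)).copy()

    positions = rng.uniform(lo, hi, size=(cfg.swarm_size, dim))
    if x0 is not None:
        for k, x in enumerate(x0[: cfg.swarm_size]):
            positions[k] = np.clip(x, lo, hi)

    evals = 0

    def evaluate(X):
        """Objective values for a batch of points, honoring the eval budget."""
        nonlocal evals
        b = len(X)
        if max_evals is not None:
            b = min(b, max_evals - evals)
        if b <= 0:
            return np.empty(0)
        Xb = np.asarray(X[:b], dtype=float)
        if vectorized:
            vals = np.asarray(objective(Xb), dtype=float)
        else:
            vals = np.array([float(objective(x)) for x in Xb])
        evals += b
        return vals

    particles = [
        Particle(
            position=positions[i].copy(),
            velocity=np.zeros(dim),
            pbest_position=positions[i].copy(),
            pbest_value=math.inf,
        )
        for i in range(cfg.swarm_size)
    ]

    # working gbest steers the swarm; the incumbent is the protected best-ever
    gbest_pos = particles[0].position.copy()
    gbest_val = math.inf
    inc_pos = gbest_pos.copy()
    inc_val = math.inf

    T = anneal.t0 if anneal is not None else None
    radius = anneal.radius0 if anneal is not None else None
    uphill = 0
    trace = []
    iterations = 0

    def out_of_budget():
        return max_evals is not None and evals >= max_evals

    for _ in range(cfg.max_iterations):
        iterations += 1
        vals = evaluate(np.stack([p.position for p in particles]))
        for p, val in zip(particles, vals):
            if val < p.pbest_value:
                p.pbest_value = val
                p.pbest_position = p.position.copy()
            if val < gbest_val:
                gbest_val = val
                gbest_pos = p.position.copy()
            if val < inc_val:
                inc_val = val
                inc_pos = p.position.copy()

        if anneal is not None and gbest_val > cfg.error_threshold and not out_of_budget():
            neighbors = generate_neighbors(
                gbest_pos, radius, anneal.neighborhood_size, (lo, hi), rng
            )
            nb_vals = evaluate(neighbors)
            if len(nb_vals):
                k = int(np.argmin(nb_vals))
                nb_val, nb = float(nb_vals[k]), neighbors[k]
                if nb_val < inc_val:
                    inc_val = nb_val
                    inc_pos = nb.copy()
                delta = nb_val - gbest_val
                if delta < 0:
                    gbest_val = nb_val
                    gbest_pos = nb.copy()
                elif rng.random() < accept_probability(delta, T):
                    # no neighbor improved: one potential uphill move of the
                    # working gbest; the incumbent is never degraded
                    gbest_val = nb_val
                    gbest_pos = nb.copy()
                    uphill += 1
            T = cool(T, anneal.gamma)

        if anneal is not None:
            radius *= anneal.radius_decay

        trace.append(inc_val)
        if callback is not None:
            callback(iterations, inc_val, inc_pos, T, radius)
        if inc_val <= cfg.error_threshold or out_of_budget():
            break

        for p in particles:
            p.velocity = update_velocity(p, gbest_pos, cfg, rng, vmax=vmax)
            p.position = update_position(p, lo, hi)

    return OptResult(
        best_position=inc_pos,
        best_value=inc_val,
        trace=np.asarray(trace),
        iterations_used=iterations,
        seed=cfg.seed,
        accepted_uphill_moves=uphill,
        evaluations=evals,
    )
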
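"""Population metaheuristics: AOSMA, ESOA, and their adaptive hybrid.

Three bound-constrained minimizers over a box search space:

* **AOSMA** — the slime mould algorithm's position update (adaptive
  vibrate/approach coefficients, sorted-fitness weights, restart
  probability ``z``) augmented with an opposition-based adaptive decision
  step: candidates whose move did not improve also evaluate the point
  mirrored in the search box and keep the better of the two.
* **ESOA** — an egret-swarm scheme in which each candidate proposes three
  moves per iteration — a sit-and-wait step guided by an exponentially
  weighted pseudo-gradient (decay rates ``beta1``/``beta2``), an
  aggressive tangent random walk, and a discriminant sample in a
  shrinking box around the global best — and greedily accepts the best
  proposal only if it improves.
* **RPAOSM-ESO** — per iteration ``u`` the scalar ``RR = u / max_iter``
  is computed; when ``RR`` is divisible by ``switch_divisor`` (default
  0.02) the whole population takes an AOSMA step, otherwise an ESOA
  step.  With the default budget ``max_iter = 50`` this schedule
  degenerates to AOSMA at every iteration (``u/50`` is always a multiple
  of 1/50); with ``max_iter = 100`` odd iterations go to ESOA and even
  ones to AOSMA.  The degeneracy is logged, not hidden.

Decision variables flagged integer in the search space are carried as
continuous values and rounded only when the objective is called; objective
values are memoized per exact rounded position within a run.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SearchSpace",
    "Candidate",
    "OptimizerConfig",
    "OptimizerState",
    "OptimizeResult",
    "RunStats",
    "compute_rr",
    "select_update_branch",
    "opposition_of",
    "init_population",
    "aosma_update",
    "esoa_update",
    "optimize",
    "multi_run_stats",
    "METHODS",
]

METHODS = ("rpaosm-eso", "aosma", "esoa")


@dataclass(frozen=True)
class SearchSpace:
    """Box-constrained decision space with optional per-dimension rounding."""

    lower: np.ndarray
    upper: np.ndarray
    integer_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D and equal length")
        if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
            raise ValueError("bounds must be finite")
        if np.any(lower > upper):
            raise ValueError("need lower <= upper elementwise")
        mask = self.integer_mask
        if mask is None:
            mask = np.zeros(lower.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != lower.shape:
                raise ValueError("integer_mask length must match bounds")
        object.__setattr__(self, "integer_mask", mask)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    def round_integers(self, position: np.ndarray) -> np.ndarray:
        """Round integer-flagged dims to the nearest in-bounds integer."""
        pos = np.array(position, dtype=float)
        mask = self.integer_mask
        if mask.any():
            pos[mask] = np.clip(
                np.rint(pos[mask]), np.ceil(self.lower[mask]), np.floor(self.upper[mask])
            )
        return pos


@dataclass
class Candidate:
    position: np.ndarray
    fitness: float


@dataclass(frozen=True)
class OptimizerConfig:
    pop_size: int = 10
    max_iter: int = 50
    beta1: float = 0.9
    beta2: float = 0.99
    switch_divisor: float = 0.02
    aosma_z: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ValueError("beta1 and beta2 must lie in (0, 1)")
        if self.switch_divisor <= 0:
            raise ValueError("switch_divisor must be positive")


@dataclass
class OptimizerState:
    """Mutable per-run state shared by both update rules."""

    space: SearchSpace
    config: OptimizerConfig
    population: list[Candidate]
    best: Candidate
    u: int                      # completed iterations (0 after init)
    rng: np.random.Generator
    trace: list[float] = field(default_factory=list)
    grad_accum_1: np.ndarray | None = None  # ESOA first-moment estimate
    grad_accum_2: np.ndarray | None = None  # ESOA second-moment estimate
    esoa_steps: int = 0
    n_evaluations: int = 0
    n_errors: int = 0

    @property
    def max_iter(self) -> int:
        return self.config.max_iter


class _CachedObjective:
    """Round integer dims, memoize by exact rounded position, count errors."""

    def __init__(self, objective: Callable, space: SearchSpace):
        if not callable(objective):
            raise TypeError("objective must be callable")
        self.objective = objective
        self.space = space
        self.cache: dict[bytes, float] = {}
        self.n_calls = 0
        self.n_errors = 0

    def __call__(self, position: np.ndarray) -> float:
        pos = self.space.round_integers(self.space.clip(position))
        key = pos.tobytes()
        if key in self.cache:
            return self.cache[key]
        self.n_calls += 1
        try:
            value = float(self.objective(pos))
        except Exception:
            self.n_errors += 1
            logger.exception("objective raised at position %s", pos)
            value = math.inf
        if not math.isfinite(value):
            value = math.inf
        self.cache[key] = value
        return value


def compute_rr(u: int, max_iter: int) -> float:
    """Adaptive switching parameter ``RR = u / max_iter``.

    Deterministic and strictly increasing in ``u``; equals 1 at the final
    iteration.
    """
    if max_iter == 0:
        raise ZeroDivisionError("max_iter must be nonzero")
    if not 1 <= u <= max_iter:
        raise ValueError(f"need 1 <= u <= max_iter, got u={u}, max_iter={max_iter}")
    return u / max_iter


def select_update_branch(
    u: int, max_iter: int, switch_divisor: float = 0.02
) -> str:
    """Choose the update rule for iteration ``u``: AOSMA iff ``RR`` is
    divisible by ``switch_divisor``, else ESOA.

    When ``1/switch_divisor`` is integral the test is done in exact
    integer arithmetic (RR is a ratio of integers, so float modulo would
    misfire); otherwise a relative tolerance of 1e-9 on the float
    remainder is used.
    """
    if switch_divisor <= 0:
        raise ValueError("switch_divisor must be positive")
    compute_rr(u, max_iter)  # validate u / max_iter
    inv = 1.0 / switch_divisor
    if abs(inv - round(inv)) < 1e-9:
        divisible = (u * round(inv)) % max_iter == 0
    else:
        rr = u / max_iter
        rem = math.fmod(rr, switch_divisor)
        rem = min(rem, switch_divisor - rem)
        divisible = rem <= 1e-9 * max(1.0, rr)
    return "AOSMA" if divisible else "ESOA"


def opposition_of(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Point mirrored in the search box: ``lower + upper - position``.

    An involution that fixes the box midpoint.  Out-of-bounds input is
    clipped first (with a warning).
    """
    pos = np.asarray(position, dtype=float)
    if np.any(pos < space.lower) or np.any(pos > space.upper):
        logger.warning("opposition_of received out-of-bounds position; clipping")
        pos = space.clip(pos)
    return space.lower + space.upper - pos


def init_population(
    objective: Callable,
    space: SearchSpace,
    config: OptimizerConfig,
) -> OptimizerState:
    """Uniform random population in the box, all fitnesses evaluated."""
    rng = np.random.default_rng(config.seed)
    cached = objective if isinstance(objective, _CachedObjective) else _CachedObjective(objective, space)
    positions = rng.uniform(
        space.lower, space.upper, size=(config.pop_size, space.dim)
    )
    population = [Candidate(p, cached(p)) for p in positions]
    if all(math.isinf(c.fitness) for c in population):
        raise RuntimeError("objective non-finite on every initial candidate")
    best = min(population, key=lambda c: c.fitness)
    state = OptimizerState(
        space=space,
        config=config,
        population=population,
        best=Candidate(best.position.copy(), best.fitness),
        u=0,
        rng=rng,
        grad_accum_1=np.zeros((config.pop_size, space.dim)),
        grad_accum_2=np.zeros((config.pop_size, space.dim)),
    )
    state.n_evaluations = cached.n_calls
    state._cached = cached  # type: ignore[attr-defined]
    return state


def _cached_for(state: OptimizerState, objective: Callable) -> _CachedObjective:
    if isinstance(objective, _CachedObjective):
        state._cached = objective  # type: ignore[attr-defined]
        return objective
    cached = getattr(state, "_cached", None)
    if cached is not None and cached.objective is objective:
        return cached
    cached = _CachedObjective(objective, state.space)
    state._cached = cached  # type: ignore[attr-defined]
    return cached


def _update_best(state: OptimizerState, candidate: Candidate) -> None:
    if candidate.fitness < state.best.fitness:
        state.best = Candidate(candidate.position.copy(), candidate.fitness)


def aosma_update(state: OptimizerState, objective: Callable) -> OptimizerState:
    """One adaptive-opposition slime mould iteration (in place).

    Sorted-fitness weights, vibrate coefficient ``vb`` in
    ``[-arctanh(1 - u/T), +...]``, approach coefficient ``vc`` shrinking
    linearly, restart probability ``z``; then the adaptive decision:
    non-improving candidates also try their opposition point.
    """
    cached = _cached_for(state, objective)
    space, cfg, rng = state.space, state.config, state.rng
    n, d = cfg.pop_size, space.dim
    u_next = state.u + 1
    t_frac = u_next / cfg.max_iter

    fitness = np.array([c.fitness for c in state.population])
    positions = np.array([c.position for c in state.population])
    order = np.argsort(fitness)
    b_f = fitness[order[0]]
    w_f = fitness[order[-1]]
    spread = b_f - w_f  # <= 0
    eps = np.finfo(float).eps

    # sorted-fitness weights: better half amplified, worse half damped
    weights = np.empty((n, d))
    for rank, idx in enumerate(order):
        with np.errstate(invalid="ignore"):
            ratio = (b_f - fitness[idx]) / (spread - eps) if spread != 0 else 0.0
        if not math.isfinite(ratio):
            ratio = 0.0
        lw = np.log10(np.clip(ratio, 0.0, None) + 1.0)
        r = rng.random(d)
        if rank < n // 2 + n % 2:
            weights[idx] = 1.0 + r * lw
        else:
            weights[idx] = 1.0 - r * lw

    a = np.arctanh(min(1.0 - t_frac, 1.0 - eps))
    b = max(1.0 - t_frac, 0.0)

    for i, cand in enumerate(state.population):
        old_fitness = cand.fitness
        if rng.random() < cfg.aosma_z:
            new_pos = rng.uniform(space.lower, space.upper, d)
        else:
            p = math.tanh(abs(cand.fitness - state.best.fitness))
            vb = rng.uniform(-a, a, d)
            vc = rng.uniform(-b, b, d)
            ia, ib = rng.integers(0, n, size=2)
            guided = state.best.position + vb * (
                weights[i] * positions[ia] - positions[ib]
            )
            shrunk = vc * cand.position
            use_guided = rng.random(d) < p
            new_pos = np.where(use_guided, guided, shrunk)
        new_pos = space.clip(new_pos)
        new_fitness = cached(new_pos)

        if new_fitness <= old_fitness:
            cand.position, cand.fitness = new_pos, new_fitness
        else:
            # adaptive decision: probe the opposition point, keep the best
            opp = opposition_of(new_pos, space)
            opp_fitness = cached(opp)
            if opp_fitness <= new_fitness:
                new_pos, new_fitness = opp, opp_fitness
            cand.position, cand.fitness = new_pos, new_fitness
        _update_best(state, cand)

    state.u = u_next
    state.trace.append(state.best.fitness)
    state.n_evaluations = cached.n_calls
    state.n_errors = cached.n_errors
    return state


def esoa_update(state: OptimizerState, objective: Callable) -> OptimizerState:
    """One egret-swarm iteration (in place).

    Per candidate, three proposals — sit-and-wait (pseudo-gradient with
    ``beta1``/``beta2`` exponential accumulators), aggressive tangent
    walk, discriminant sample in a shrinking box around the global best —
    and the best proposal is adopted only if it improves on the current
    position.
    """
    cached = _cached_for(state, objective)
    space, cfg, rng = state.space, state.config, state.rng
    d = space.dim
    u_next = state.u + 1
    t_frac = u_next / cfg.max_iter
    hop = space.range
    state.esoa_steps += 1
    t = state.esoa_steps
    eps = 1e-12

    for i, cand in enumerate(state.population):
        # (a) sit-and-wait: descend an estimated gradient toward the best
        diff = cand.position - state.best.position
        gap = cand.fitness - state.best.fitness
        denom = float(diff @ diff) + eps
        grad = diff * (gap / denom) if math.isfinite(gap) else diff
        m = state.grad_accum_1[i] = (
            cfg.beta1 * state.grad_accum_1[i] + (1.0 - cfg.beta1) * grad
        )
        v = state.grad_accum_2[i] = (
            cfg.beta2 * state.grad_accum_2[i] + (1.0 - cfg.beta2) * grad ** 2
        )
        m_hat = m / (1.0 - cfg.beta1 ** t)
        v_hat = v / (1.0 - cfg.beta2 ** t)
        step = 0.1 * hop * math.exp(-u_next / (0.5 * cfg.max_iter))
        sit_wait = cand.position - step * m_hat / (np.sqrt(v_hat) + eps)

        # (b) aggressive random walk with heavy-tailed tangent steps
        theta = rng.uniform(-np.pi / 4, np.pi / 4, d)
        aggressive = cand.position + np.tan(theta) * hop / (1.0 + u_next)

        # (c) discriminant sampling in a box around the best, shrinking
        shrink = max(1.0 - t_frac, 1.0 / cfg.max_iter)
        discriminant = state.best.position + rng.uniform(-0.5, 0.5, d) * hop * shrink

        proposals = [space.clip(p) for p in (sit_wait, aggressive, discriminant)]
        values = [cached(p) for p in proposals]
        j = int(np.argmin(values))
        if values[j] < cand.fitness:
            cand.position, cand.fitness = proposals[j], values[j]
        _update_best(state, cand)

    state.u = u_next
    state.trace.append(state.best.fitness)
    state.n_evaluations = cached.n_calls
    state.n_errors = cached.n_errors
    return state


@dataclass
class OptimizeResult:
    """Outcome of one optimizer run."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    method: str
    config: OptimizerConfig
    branch_schedule: tuple[str, ...]
    n_evaluations: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "config": {
                    "pop_size": self.config.pop_size,
                    "max_iter": self.config.max_iter,
                    "beta1": self.config.beta1,
                    "beta2": self.config.beta2,
                    "switch_divisor": self.config.switch_divisor,
                    "aosma_z": self.config.aosma_z,
                    "seed": self.config.seed,
                },
                "best_position": self.best_position.tolist(),
                "best_fitness": self.best_fitness,
                "trace": self.trace.tolist(),
                "branch_schedule": list(self.branch_schedule),
                "n_evaluations": self.n_evaluations,
            },
            indent=2,
        )


def optimize(
    objective: Callable,
    space: SearchSpace,
    config: OptimizerConfig,
    method: str = "rpaosm-eso",
) -> OptimizeResult:
    """Run one optimizer to its iteration budget and return the best.

    ``method`` is one of ``rpaosm-eso`` (adaptive switch), ``aosma`` or
    ``esoa`` (single-branch).  Fully reproducible from ``config.seed``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    cached = _CachedObjective(objective, space)
    state = init_population(cached, space, config)
    schedule: list[str] = []
    degenerate_logged = False
    for u in range(1, config.max_iter + 1):
        if method == "aosma":
            branch = "AOSMA"
        elif method == "esoa":
            branch = "ESOA"
        else:
            branch = select_update_branch(u, config.max_iter, config.switch_divisor)
        schedule.append(branch)
        if branch == "AOSMA":
            aosma_update(state, cached)
        else:
            esoa_update(state, cached)
    if method == "rpaosm-eso" and len(set(schedule)) == 1 and not degenerate_logged:
        logger.info(
            "RPAOSM-ESO schedule is degenerate: every iteration chose %s "
            "(max_iter=%d, switch_divisor=%g)",
            schedule[0], config.max_iter, config.switch_divisor,
        )
    return OptimizeResult(
        best_position=state.space.round_integers(state.best.position),
        best_fitness=state.best.fitness,
        trace=np.array(state.trace),
        method=method,
        config=config,
        branch_schedule=tuple(schedule),
        n_evaluations=state.n_evaluations,
    )


@dataclass(frozen=True)
class RunStats:
    best: float
    worst: float
    mean: float
    median: float
    std: float
    finals: tuple[float, ...]


def multi_run_stats(
    objective: Callable,
    space: SearchSpace,
    config: OptimizerConfig,
    n_runs: int,
    method: str = "rpaosm-eso",
    seeds: Sequence[int] | None = None,
) -> RunStats:
    """Best/worst/mean/median/std of final fitness over repeated runs.

    Each run uses a distinct seed (``config.seed + k`` unless an explicit
    seed list is given).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = [config.seed + k for k in range(n_runs)]
    elif len(seeds) != n_runs:
        raise ValueError("len(seeds) must equal n_runs")
    finals = []
    for s in seeds:
        cfg = OptimizerConfig(
            pop_size=config.pop_size,
            max_iter=config.max_iter,
            beta1=config.beta1,
            beta2=config.beta2,
            switch_divisor=config.switch_divisor,
            aosma_z=config.aosma_z,
            seed=int(s),
        )
        finals.append(optimize(objective, space, cfg, method=method).best_fitness)
    arr = np.array(finals)
    return RunStats(
        best=float(arr.min()),
        worst=float(arr.max()),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        std=float(arr.std()),
        finals=tuple(finals),
    )
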
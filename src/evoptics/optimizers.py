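"""Box-bounded global optimizers behind a single ``minimize`` contract.

All algorithms evaluate a scalar objective on a box (:class:`Bounds`),
project every candidate onto the box before evaluation, count evaluations
against a fixed budget, and are bit-reproducible given (config, seed).

* DE — differential evolution of the current-to-best/1 family with
  coordinate-wise binomial crossover: a parent coordinate has one-in-two
  chances to be copied verbatim; otherwise it takes the mutant value built
  from four individuals (parent, two random distinct individuals, and the
  best so far). Offspring replace their parent only if at least as fit.
* OPO — (1+1) evolution strategy: isotropic Gaussian mutation in
  box-normalized coordinates, elitist acceptance, one-fifth success-rule
  step-size adaptation.
* PSO — global-best particle swarm with inertia, velocity clamping and box
  projection.
* NM — Nelder-Mead simplex (delegated to scipy) with seeded random restarts
  until the budget is exhausted.
* CMA — delegated to the external ``cma`` package when installed; raises
  :class:`AlgorithmUnavailableError` otherwise so campaigns can proceed
  without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .genomes import Bounds, clamp_to_bounds

__all__ = [
    "OptimizerConfig",
    "OptimizationResult",
    "AlgorithmUnavailableError",
    "minimize",
    "minimize_de",
    "minimize_opo",
    "minimize_pso",
    "minimize_nm",
    "minimize_cma",
    "ALGORITHMS",
]


class AlgorithmUnavailableError(RuntimeError):
    """The requested algorithm's backing implementation is not installed."""


@dataclass
class OptimizerConfig:
    """Shared optimizer settings; algorithm-specific knobs in ``params``."""

    algorithm: str = "DE"
    budget: int = 10_000
    population: int = 30
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class OptimizationResult:
    """Best point found, its score, and the best-so-far convergence trace.

    ``trace`` holds ``(evaluation_index, best_score_so_far)`` pairs recorded
    at every improvement (1-based indices); scores along it never increase.
    """

    x_best: np.ndarray
    f_best: float
    trace: list
    evaluations: int
    seed: int
    algorithm: str


class _Budget:
    """Evaluation counter wrapping the raw objective; enforces the budget."""

    class Exhausted(Exception):
        pass

    def __init__(self, objective, budget: int):
        self.objective = objective
        self.budget = int(budget)
        self.count = 0
        self.best = np.inf
        self.x_best = None
        self.trace = []

    def __call__(self, x) -> float:
        if self.count >= self.budget:
            raise _Budget.Exhausted
        self.count += 1
        f = float(self.objective(x))
        if f < self.best or self.x_best is None:
            self.best = f
            self.x_best = np.array(x, dtype=float)
            self.trace.append((self.count, f))
        return f

    @property
    def remaining(self) -> int:
        return self.budget - self.count

    def result(self, seed: int, algorithm: str) -> OptimizationResult:
        return OptimizationResult(
            self.x_best, self.best, self.trace, self.count, seed, algorithm
        )


def _uniform_population(rng, bounds: Bounds, size: int) -> np.ndarray:
    return rng.uniform(bounds.lower, bounds.upper, size=(size, bounds.dimension))


# ---------------------------------------------------------------------------
# Differential Evolution
# ---------------------------------------------------------------------------

def minimize_de(
    objective,
    bounds: Bounds,
    budget: int = 10_000,
    seed: int = 0,
    population: int = 30,
    F1: float = 0.8,
    F2: float = 0.8,
    CR: float = 0.5,
) -> OptimizationResult:
    """Differential evolution, current-to-best/1 with binomial crossover.

    The mutant for parent ``x_i`` is
    ``x_i + F1 (x_best - x_i) + F2 (x_r1 - x_r2)`` with ``r1 != r2 != i``;
    each offspring coordinate is copied from the parent with probability
    ``1 - CR`` (default one-half) and taken from the mutant otherwise, with
    one coordinate forced from the mutant so the offspring differs from its
    parent. Offspring replace the parent iff not worse (<=, drift allowed).
    """
    rng = np.random.default_rng(seed)
    wrapped = _Budget(objective, budget)
    D = bounds.dimension
    pop_n = max(4, int(population))
    try:
        pop = _uniform_population(rng, bounds, pop_n)
        scores = np.empty(pop_n)
        best_i = 0
        for i in range(pop_n):
            scores[i] = wrapped(pop[i])
            if scores[i] < scores[best_i]:
                best_i = i
        while True:
            for i in range(pop_n):
                r1, r2 = _two_distinct(rng, pop_n, i)
                mutant = (
                    pop[i]
                    + F1 * (pop[best_i] - pop[i])
                    + F2 * (pop[r1] - pop[r2])
                )
                take_mut = rng.random(D) < CR
                take_mut[rng.integers(D)] = True  # offspring != parent
                child = np.where(take_mut, mutant, pop[i])
                child = clamp_to_bounds(child, bounds)
                f_child = wrapped(child)
                if f_child <= scores[i]:
                    pop[i] = child
                    scores[i] = f_child
                    if f_child <= scores[best_i]:
                        best_i = i
    except _Budget.Exhausted:
        pass
    return wrapped.result(seed, "DE")


def _two_distinct(rng, n: int, exclude: int):
    while True:
        r1, r2 = rng.integers(n, size=2)
        if r1 != r2 and r1 != exclude and r2 != exclude:
            return int(r1), int(r2)


# ---------------------------------------------------------------------------
# (1+1) evolution strategy
# ---------------------------------------------------------------------------

def minimize_opo(
    objective,
    bounds: Bounds,
    budget: int = 10_000,
    seed: int = 0,
    sigma0: float = 0.2,
    grow: float = 1.5,
    **_ignored,
) -> OptimizationResult:
    """(1+1)-ES: blind Gaussian mutation, elitism, one-fifth success rule.

    Mutations are isotropic in box-normalized coordinates with initial
    relative step ``sigma0``; the step multiplies by ``grow`` on success and
    by ``grow**(-1/4)`` on failure, stationary at a one-in-five success rate.
    """
    rng = np.random.default_rng(seed)
    wrapped = _Budget(objective, budget)
    span = bounds.span
    shrink = grow ** (-0.25)
    sigma = float(sigma0)
    try:
        x = rng.uniform(bounds.lower, bounds.upper)
        fx = wrapped(x)
        while True:
            y = clamp_to_bounds(x + sigma * span * rng.standard_normal(bounds.dimension), bounds)
            fy = wrapped(y)
            if fy <= fx:
                x, fx = y, fy
                sigma *= grow
            else:
                sigma *= shrink
            sigma = min(max(sigma, 1e-12), 1.0)
    except _Budget.Exhausted:
        pass
    return wrapped.result(seed, "OPO")


# ---------------------------------------------------------------------------
# Particle swarm
# ---------------------------------------------------------------------------

def minimize_pso(
    objective,
    bounds: Bounds,
    budget: int = 10_000,
    seed: int = 0,
    population: int = 30,
    inertia: float = 0.7298,
    cognitive: float = 1.49618,
    social: float = 1.49618,
    **_ignored,
) -> OptimizationResult:
    """Global-best PSO with Clerc-constriction defaults and velocity clamping."""
    rng = np.random.default_rng(seed)
    wrapped = _Budget(objective, budget)
    D = bounds.dimension
    n = max(2, int(population))
    span = bounds.span
    v_max = 0.5 * span
    try:
        x = _uniform_population(rng, bounds, n)
        v = rng.uniform(-v_max, v_max, size=(n, D))
        p_best = x.copy()
        p_score = np.array([wrapped(xi) for xi in x])
        g = int(np.argmin(p_score))
        while True:
            for i in range(n):
                r1, r2 = rng.random(D), rng.random(D)
                v[i] = (
                    inertia * v[i]
                    + cognitive * r1 * (p_best[i] - x[i])
                    + social * r2 * (p_best[g] - x[i])
                )
                v[i] = np.clip(v[i], -v_max, v_max)
                x[i] = clamp_to_bounds(x[i] + v[i], bounds)
                f = wrapped(x[i])
                if f <= p_score[i]:
                    p_score[i] = f
                    p_best[i] = x[i].copy()
                    if f <= p_score[g]:
                        g = i
    except _Budget.Exhausted:
        pass
    return wrapped.result(seed, "PSO")


# ---------------------------------------------------------------------------
# Nelder-Mead with restarts
# ---------------------------------------------------------------------------

def minimize_nm(
    objective,
    bounds: Bounds,
    budget: int = 10_000,
    seed: int = 0,
    simplex_scale: float = 0.1,
    **_ignored,
) -> OptimizationResult:
    """Simplex search (scipy Nelder-Mead) restarted from seeded random points.

    Each restart begins from a uniform in-box point with an axis-aligned
    initial simplex of edge length ``simplex_scale`` times the box span;
    canonical reflection/expansion/contraction/shrink coefficients
    (1, 2, 0.5, 0.5). Restarts continue until the budget is exhausted.
    """
    rng = np.random.default_rng(seed)
    wrapped = _Budget(objective, budget)
    D = bounds.dimension
    span = bounds.span

    def g(x):
        return wrapped(clamp_to_bounds(x, bounds))

    try:
        while True:
            x0 = rng.uniform(bounds.lower, bounds.upper)
            simplex = np.vstack([x0, x0 + np.diag(simplex_scale * span)])
            simplex = np.minimum(simplex, bounds.upper)
            _scipy_minimize(
                g,
                x0,
                method="Nelder-Mead",
                options={
                    "initial_simplex": simplex,
                    "maxfev": wrapped.remaining,
                    "xatol": 1e-9,
                    "fatol": 1e-12,
                },
            )
            if wrapped.remaining <= 0:
                break
    except _Budget.Exhausted:
        pass
    return wrapped.result(seed, "NM")


# ---------------------------------------------------------------------------
# CMA (delegated)
# ---------------------------------------------------------------------------

def minimize_cma(
    objective,
    bounds: Bounds,
    budget: int = 10_000,
    seed: int = 0,
    sigma0: float = 0.25,
    **_ignored,
) -> OptimizationResult:
    """Covariance-matrix adaptation via the external ``cma`` package.

    Raises :class:`AlgorithmUnavailableError` when the delegate is not
    installed; bound handling uses the shared clamp so CMA sees the same
    feasible set as every other algorithm.
    """
    try:
        import cma as _cma
    except ImportError as exc:
        raise AlgorithmUnavailableError(
            "CMA requires the external 'cma' package, which is not installed"
        ) from exc
    wrapped = _Budget(objective, budget)
    x0 = np.random.default_rng(seed).uniform(bounds.lower, bounds.upper)
    es = _cma.CMAEvolutionStrategy(
        x0,
        sigma0 * float(np.mean(bounds.span)),
        {"seed": seed, "verbose": -9, "maxfevals": budget},
    )
    try:
        while not es.stop() and wrapped.remaining > 0:
            xs = es.ask()
            fs = [wrapped(clamp_to_bounds(x, bounds)) for x in xs]
            es.tell(xs, fs)
    except _Budget.Exhausted:
        pass
    return wrapped.result(seed, "CMA")


ALGORITHMS = {
    "DE": minimize_de,
    "OPO": minimize_opo,
    "PSO": minimize_pso,
    "NM": minimize_nm,
    "CMA": minimize_cma,
}


def minimize(
    objective,
    bounds: Bounds,
    config: OptimizerConfig | None = None,
    **overrides,
) -> OptimizationResult:
    """Run the algorithm named in ``config`` under the shared contract."""
    config = config or OptimizerConfig()
    algo = config.algorithm.upper()
    if algo not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {config.algorithm!r}")
    kwargs = dict(budget=config.budget, seed=config.seed, **config.params, **overrides)
    if algo in ("DE", "PSO"):
        kwargs.setdefault("population", config.population)
    return ALGORITHMS[algo](objective, bounds, **kwargs)
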
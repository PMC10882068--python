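"""Marine Predators Algorithm with a quantum-theory position update,
wrapped as a feature selector for labeled feature matrices.

The optimizer is the classic three-phase Marine Predators Algorithm
(MPA): a population of agents ("prey") moves against a replicated
best-so-far position (the "elite"), with

* phase 1 (first third of iterations): Brownian exploration steps,
* phase 2 (middle third): the better half of the population takes Levy
  prey steps, the other half Brownian predator steps scaled by the
  adaptive factor CF = (1 - it/maxit)^(2 it/maxit),
* phase 3 (last third): Levy exploitation steps around the elite,

followed by the FADs (fish-aggregating-devices) long-jump perturbation
with probability 0.2, and a per-agent greedy memory that keeps the
better of each agent's current and previous position.

The quantum modification replaces half of the phase-2 motion with a
position sampled around the attractor C = theta*cBest + (1-theta)*gBest
at distance b * |Jbest - Z| * ln(1/u), u ~ U(0,1) — the characteristic
quantum-behaved-swarm move — where theta follows a logistic-map chaotic
sequence, Jbest is the mean of the per-agent bests and b contracts
linearly from b_max to b_min over the run.  In the remaining phases a
matching attractor-driven step C*(E - C*P) is blended in, and each
iteration the worst agent is resampled around the elite.  Setting
``quantum=False`` recovers the canonical MPA for ablation.

Feature selection runs the optimizer on [0,1]^d, thresholds positions at
tau = 0.5 into column masks, and scores masks by
alpha * (stratified 3-fold 5-NN error) + (1-alpha) * (subset fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma as _gamma_fn

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "MPAConfig",
    "PreyPopulation",
    "SelectionMask",
    "init_population",
    "random_motion",
    "compute_cf",
    "phase_update",
    "fads_perturbation",
    "quantum_update",
    "greedy_memory",
    "binarize_position",
    "selection_fitness",
    "optimize",
    "select_features",
]


@dataclass
class MPAConfig:
    """Optimizer and selection settings.

    T (0.5) and the FADs probability (0.2) are the algorithm's standard
    constants.  b_max/b_min bound the quantum contraction-expansion
    coefficient; tau is the position-binarization threshold and
    fitness_alpha weights classification error against subset size in
    the selection fitness.
    """

    n_agents: int = 30
    max_iter: int = 100
    T: float = 0.5
    fads: float = 0.2
    levy_exponent: float = 1.5
    b_max: float = 1.0
    b_min: float = 0.5
    tau: float = 0.5
    fitness_alpha: float = 0.99
    quantum: bool = True
    boundary: str = "clip"  # or "reflect"
    theta0: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1 or self.max_iter < 0:
            raise ValueError("n_agents >= 1 and max_iter >= 0 required")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if not 0 <= self.fitness_alpha <= 1:
            raise ValueError("fitness_alpha must lie in [0, 1]")


@dataclass
class PreyPopulation:
    """Search state: positions, fitness, elite, per-agent memory, bounds."""

    positions: np.ndarray          # (n, d)
    lb: np.ndarray                 # (d,)
    ub: np.ndarray                 # (d,)
    fitness: np.ndarray | None = None
    elite_position: np.ndarray | None = None
    elite_fitness: float = np.inf
    prev_positions: np.ndarray | None = None
    prev_fitness: np.ndarray | None = None
    cbest_positions: np.ndarray | None = None  # per-agent best ever
    cbest_fitness: np.ndarray | None = None

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]


@dataclass
class SelectionMask:
    selected: np.ndarray  # boolean (d,)

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.selected))

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


def init_population(n: int, d: int, lb, ub,
                    rng: np.random.Generator) -> PreyPopulation:
    """Uniform initialization Y0 = Ymin + rand * (Ymax - Ymin)."""
    lb = np.broadcast_to(np.asarray(lb, dtype=float), (d,)).copy()
    ub = np.broadcast_to(np.asarray(ub, dtype=float), (d,)).copy()
    if np.any(lb >= ub):
        raise ValueError("lower bounds must be strictly below upper bounds")
    pos = lb + rng.uniform(0.0, 1.0, size=(n, d)) * (ub - lb)
    return PreyPopulation(positions=pos, lb=lb, ub=ub)


def _mantegna_sigma(alpha: float) -> float:
    num = _gamma_fn(1 + alpha) * np.sin(np.pi * alpha / 2)
    den = _gamma_fn((1 + alpha) / 2) * alpha * 2 ** ((alpha - 1) / 2)
    return (num / den) ** (1 / alpha)


def random_motion(kind: str, shape, rng: np.random.Generator,
                  levy_exponent: float = 1.5) -> np.ndarray:
    """Brownian (standard normal) or Levy (Mantegna) random step fields."""
    if kind == "brownian":
        return rng.normal(0.0, 1.0, size=shape)
    if kind == "levy":
        sigma = _mantegna_sigma(levy_exponent)
        u = rng.normal(0.0, sigma, size=shape)
        v = rng.normal(0.0, 1.0, size=shape)
        return u / np.abs(v) ** (1.0 / levy_exponent)
    raise ValueError(f"unknown motion kind {kind!r}")


def compute_cf(iteration: int, max_iter: int) -> float:
    """Adaptive step factor CF = (1 - it/maxit)^(2 it/maxit) in [0, 1]."""
    if max_iter <= 0:
        return 1.0
    frac = iteration / max_iter
    base = 1.0 - frac
    if base == 0.0:
        return 0.0
    return float(base ** (2.0 * frac))


def _apply_bounds(pos: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                  mode: str = "clip") -> np.ndarray:
    if mode == "reflect":
        span = ub - lb
        pos = np.abs((pos - lb) % (2 * span))
        pos = np.where(pos > span, 2 * span - pos, pos) + lb
        return pos
    return np.clip(pos, lb, ub)


def _chaotic_theta(theta: float) -> float:
    return 4.0 * theta * (1.0 - theta)


def quantum_update(positions: np.ndarray, cbest: np.ndarray,
                   gbest: np.ndarray, b: float, theta: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample new positions around the quantum attractor.

    C = theta * cBest + (1 - theta) * gBest per agent; the new position is
    C +/- b * |Jbest - Z| * ln(1/u) with u ~ U(0,1), the sign positive
    when a second uniform draw is >= 0.5.  Jbest is the mean of the
    per-agent best positions.
    """
    jbest = cbest.mean(axis=0)
    C = theta * cbest + (1.0 - theta) * gbest
    u = rng.uniform(np.finfo(float).tiny, 1.0, size=positions.shape)
    sign = np.where(rng.uniform(0.0, 1.0, size=positions.shape) >= 0.5, 1.0, -1.0)
    return C + sign * b * np.abs(jbest - positions) * np.log(1.0 / u)


def _b_schedule(iteration: int, max_iter: int, b_max: float, b_min: float) -> float:
    if max_iter <= 0:
        return b_max
    return b_max - (b_max - b_min) / max_iter * iteration


def phase_update(pop: PreyPopulation, iteration: int, max_iter: int,
                 cfg: MPAConfig, rng: np.random.Generator,
                 theta: float | None = None) -> PreyPopulation:
    """One MPA velocity update (the three phases), with the quantum move
    spliced in when ``cfg.quantum`` is on.  Positions are re-bounded
    afterward."""
    if pop.elite_position is None or pop.fitness is None:
        raise ValueError("population must be evaluated before phase_update")
    if theta is None:
        theta = cfg.theta0
    n, d = pop.n_agents, pop.ndim
    P = pop.positions
    E = np.broadcast_to(pop.elite_position, (n, d))
    cf = compute_cf(iteration, max_iter)
    b = _b_schedule(iteration, max_iter, cfg.b_max, cfg.b_min)
    cbest = pop.cbest_positions if pop.cbest_positions is not None else P
    new = P.copy()

    if iteration < max_iter / 3.0:
        RB = random_motion("brownian", (n, d), rng)
        R = rng.uniform(0.0, 1.0, size=(n, d))
        step = RB * (E - RB * P)
        new = P + cfg.T * R * step
        if cfg.quantum:
            C = theta * cbest + (1.0 - theta) * pop.elite_position
            new = new + cfg.T * cf * C * (E - C * new)
    elif iteration < 2.0 * max_iter / 3.0:
        order = np.argsort(pop.fitness, kind="stable")
        half = int(np.ceil(n / 2))
        exploit, explore = order[:half], order[half:]
        RL = random_motion("levy", (len(exploit), d), rng, cfg.levy_exponent)
        R = rng.uniform(0.0, 1.0, size=(len(exploit), d))
        step = RL * (E[exploit] - RL * P[exploit])
        new[exploit] = P[exploit] + cfg.T * R * step
        if len(explore):
            if cfg.quantum:
                new[explore] = quantum_update(P[explore], cbest[explore],
                                              pop.elite_position, b, theta, rng)
            else:
                RB = random_motion("brownian", (len(explore), d), rng)
                step = RB * (RB * E[explore] - P[explore])
                new[explore] = E[explore] + cfg.T * cf * step
    else:
        RL = random_motion("levy", (n, d), rng, cfg.levy_exponent)
        step = RL * (RL * E - P)
        new = E + cfg.T * cf * step
        if cfg.quantum:
            C = theta * cbest + (1.0 - theta) * pop.elite_position
            new = new + cfg.T * cf * C * (E - C * new)

    pop.positions = _apply_bounds(new, pop.lb, pop.ub, cfg.boundary)
    return pop


def fads_perturbation(pop: PreyPopulation, iteration: int, max_iter: int,
                      cfg: MPAConfig, rng: np.random.Generator) -> PreyPopulation:
    """FADs long-jump: with probability 0.2 an agent takes a bounded random
    jump masked by a binary vector; otherwise it moves along the difference
    of two randomly chosen agents.  The swap branch needs n >= 3."""
    if pop.fitness is None:
        raise ValueError("population must be evaluated before fads_perturbation")
    n, d = pop.n_agents, pop.ndim
    P = pop.positions
    cf = compute_cf(iteration, max_iter)
    r = rng.uniform(0.0, 1.0, size=n)
    new = P.copy()
    jump = r < cfg.fads
    if np.any(jump):
        U = (rng.uniform(0.0, 1.0, size=(int(jump.sum()), d)) > cfg.fads).astype(float)
        R = rng.uniform(0.0, 1.0, size=(int(jump.sum()), d))
        new[jump] = P[jump] + cf * (pop.lb + R * (pop.ub - pop.lb)) * U
    swap = ~jump
    if np.any(swap) and n >= 3:
        idx = np.flatnonzero(swap)
        r1 = rng.integers(0, n, size=len(idx))
        r2 = rng.integers(0, n - 1, size=len(idx))
        r2 = np.where(r2 >= r1, r2 + 1, r2)  # r2 != r1
        coef = (cfg.fads * (1.0 - r[idx]) + r[idx])[:, None]
        new[idx] = P[idx] + coef * (P[r1] - P[r2])
    pop.positions = _apply_bounds(new, pop.lb, pop.ub, cfg.boundary)
    return pop


def greedy_memory(pop: PreyPopulation) -> PreyPopulation:
    """Per-agent greedy replacement: keep the better of (current, previous);
    refresh the per-agent bests and the elite."""
    if pop.prev_fitness is not None:
        worse = pop.fitness > pop.prev_fitness
        pop.positions[worse] = pop.prev_positions[worse]
        pop.fitness[worse] = pop.prev_fitness[worse]
    if pop.cbest_fitness is None:
        pop.cbest_positions = pop.positions.copy()
        pop.cbest_fitness = pop.fitness.copy()
    else:
        better = pop.fitness < pop.cbest_fitness
        pop.cbest_positions[better] = pop.positions[better]
        pop.cbest_fitness[better] = pop.fitness[better]
    i = int(np.argmin(pop.fitness))
    if pop.fitness[i] < pop.elite_fitness:
        pop.elite_fitness = float(pop.fitness[i])
        pop.elite_position = pop.positions[i].copy()
    pop.prev_positions = pop.positions.copy()
    pop.prev_fitness = pop.fitness.copy()
    return pop


def binarize_position(position: np.ndarray, tau: float = 0.5) -> SelectionMask:
    """Threshold a [0,1] position into a column mask; an empty mask falls
    back to the single largest-valued dimension."""
    position = np.asarray(position, dtype=float)
    selected = position >= tau
    if not selected.any():
        selected = np.zeros_like(selected)
        selected[int(np.argmax(position))] = True
    return SelectionMask(selected=selected)


def selection_fitness(mask: SelectionMask, X: np.ndarray, y: np.ndarray,
                      cfg: MPAConfig, folds=None) -> float:
    """alpha * (stratified 3-fold 5-NN error on the masked columns)
    + (1 - alpha) * (n_selected / d); lower is better."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("fitness needs at least two classes")
    if mask.n_selected < 1:
        raise ValueError("mask selects no features")
    if folds is None:
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=cfg.seed)
        folds = list(skf.split(X, y))
    Xm = X[:, mask.selected]
    errors = []
    for tr, te in folds:
        clf = KNeighborsClassifier(n_neighbors=5)
        clf.fit(Xm[tr], y[tr])
        errors.append(np.mean(clf.predict(Xm[te]) != y[te]))
    err = float(np.mean(errors))
    frac = mask.n_selected / X.shape[1]
    return cfg.fitness_alpha * err + (1.0 - cfg.fitness_alpha) * frac


@dataclass
class MPAResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray       # elite fitness per iteration (incl. initial)
    n_evaluations: int


def optimize(objective, d: int, lb, ub, cfg: MPAConfig,
             rng: np.random.Generator | None = None) -> MPAResult:
    """Minimize a continuous objective with the (quantum) MPA.

    objective : callable mapping a (d,) position to a scalar fitness.
    Returns the elite position/fitness and the per-iteration elite-fitness
    history (non-increasing by construction of the greedy memory).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop = init_population(cfg.n_agents, d, lb, ub, rng)
    n_evals = 0

    def evaluate():
        nonlocal n_evals
        pop.fitness = np.array([objective(p) for p in pop.positions], dtype=float)
        n_evals += pop.n_agents

    evaluate()
    greedy_memory(pop)
    history = [pop.elite_fitness]
    theta = cfg.theta0
    b = cfg.b_max
    for it in range(1, cfg.max_iter + 1):
        theta = _chaotic_theta(theta)
        phase_update(pop, it, cfg.max_iter, cfg, rng, theta=theta)
        fads_perturbation(pop, it, cfg.max_iter, cfg, rng)
        if cfg.quantum:
            # elite refinement: resample the worst agent around the elite
            b = _b_schedule(it, cfg.max_iter, cfg.b_max, cfg.b_min)
            worst = int(np.argmax(pop.prev_fitness))
            z = quantum_update(pop.positions[worst:worst + 1],
                               pop.elite_position[None, :],
                               pop.elite_position, b, theta, rng)
            pop.positions[worst] = _apply_bounds(z, pop.lb, pop.ub,
                                                 cfg.boundary)[0]
        evaluate()
        greedy_memory(pop)
        history.append(pop.elite_fitness)
    return MPAResult(best_position=pop.elite_position.copy(),
                     best_fitness=pop.elite_fitness,
                     history=np.asarray(history), n_evaluations=n_evals)


def select_features(X: np.ndarray, y: np.ndarray,
                    cfg: MPAConfig | None = None):
    """Wrapper feature selection over the columns of ``X``.

    Runs the quantum MPA on [0,1]^d with threshold binarization; the
    fitness of a candidate mask is cached so repeated masks (common once
    the swarm contracts) cost nothing.  Returns ``(SelectionMask,
    history)`` with the per-iteration best-fitness history.
    """
    if cfg is None:
        cfg = MPAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 10 or X.shape[1] < 2:
        raise ValueError("need at least 10 rows and 2 feature columns")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    d = X.shape[1]
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(X, y))
    cache: dict[bytes, float] = {}

    def objective(position):
        mask = binarize_position(position, cfg.tau)
        key = np.packbits(mask.selected).tobytes()
        if key not in cache:
            cache[key] = selection_fitness(mask, X, y, cfg, folds)
        return cache[key]

    rng = np.random.default_rng(cfg.seed)
    result = optimize(objective, d, 0.0, 1.0, cfg, rng)
    return binarize_position(result.best_position, cfg.tau), result.history
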
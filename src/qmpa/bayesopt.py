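"""Gaussian-process Bayesian optimization with an ARD Matern-5/2 kernel.

Minimizes a black-box objective over a box-bounded search space.  Each
dimension may be searched on a linear or logarithmic scale; internally
all coordinates live in the unit cube.  The surrogate is a zero-mean GP
with the ARD Matern-5/2 covariance

    k(x, x') = sigma_f^2 (1 + sqrt(5) r + 5/3 r^2) exp(-sqrt(5) r),
    r^2 = sum_m (x_m - x'_m)^2 / sigma_m^2,

plus independent Gaussian observation noise.  Kernel hyperparameters are
refit each iteration by maximizing the log marginal likelihood over their
logs with a multi-start simplex search.  Acquisition is expected
improvement (EI) or EI per second, where a second GP fitted on log
evaluation times predicts the cost denominator.

The loop follows the classic recipe: a handful of random seed points,
then alternately fit the posterior, maximize the acquisition over a
random multi-start candidate set with local refinement, and evaluate the
objective, until the evaluation budget is spent.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "Dimension",
    "SearchSpace",
    "Observation",
    "GaussianProcessPosterior",
    "BOState",
    "matern52_ard",
    "fit_gp",
    "gp_posterior",
    "expected_improvement",
    "ei_per_second",
    "propose_next",
    "run_bayes_opt",
    "demo_space",
    "make_demo_objective",
]

_JITTER = 1e-10
_MIN_SECONDS = 1e-6


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    transform: str = "linear"  # or "log"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.transform not in ("linear", "log"):
            raise ValueError(f"{self.name}: unknown transform {self.transform}")
        if self.transform == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log transform requires low > 0")


class SearchSpace:
    """Box search space; maps between original scale and the unit cube."""

    def __init__(self, dimensions):
        self.dimensions = [d if isinstance(d, Dimension) else Dimension(**d)
                           for d in dimensions]

    @property
    def ndim(self) -> int:
        return len(self.dimensions)

    def to_unit(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = np.empty_like(x)
        for i, d in enumerate(self.dimensions):
            if d.transform == "log":
                z[i] = (np.log(x[i]) - np.log(d.low)) / (np.log(d.high) - np.log(d.low))
            else:
                z[i] = (x[i] - d.low) / (d.high - d.low)
        return z

    def from_unit(self, z) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        x = np.empty_like(z)
        for i, d in enumerate(self.dimensions):
            if d.transform == "log":
                x[i] = np.exp(np.log(d.low) + z[i] * (np.log(d.high) - np.log(d.low)))
            else:
                x[i] = d.low + z[i] * (d.high - d.low)
        return x


@dataclass
class Observation:
    x: np.ndarray            # unit-cube coordinates
    y: float
    eval_seconds: float = 1.0
    failed: bool = False


def matern52_ard(xi, xj, sigma_f: float, length_scales) -> float:
    """ARD Matern-5/2 covariance between two points."""
    ls = np.atleast_1d(np.asarray(length_scales, dtype=float))
    if sigma_f <= 0 or np.any(ls <= 0):
        raise ValueError("sigma_f and all length scales must be > 0")
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    xj = np.atleast_1d(np.asarray(xj, dtype=float))
    if xi.shape != xj.shape:
        raise ValueError("dimension mismatch")
    r = np.sqrt(np.sum(((xi - xj) / ls) ** 2))
    s5r = np.sqrt(5.0) * r
    return sigma_f ** 2 * (1.0 + s5r + (5.0 / 3.0) * r ** 2) * np.exp(-s5r)


def _kernel_matrix(A: np.ndarray, B: np.ndarray, sigma_f: float,
                   ls: np.ndarray) -> np.ndarray:
    d = (A[:, None, :] - B[None, :, :]) / ls
    r = np.sqrt(np.sum(d * d, axis=-1))
    s5r = np.sqrt(5.0) * r
    return sigma_f ** 2 * (1.0 + s5r + (5.0 / 3.0) * r ** 2) * np.exp(-s5r)


class GaussianProcessPosterior:
    """Zero-prior-mean GP posterior conditioned on noisy observations."""

    def __init__(self, X: np.ndarray, y: np.ndarray, sigma_f: float,
                 length_scales, noise_var: float = 0.0):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float)
        self.sigma_f = float(sigma_f)
        self.length_scales = np.atleast_1d(np.asarray(length_scales, dtype=float))
        self.noise_var = float(noise_var)
        if self.sigma_f <= 0 or np.any(self.length_scales <= 0) or self.noise_var < 0:
            raise ValueError("invalid GP hyperparameters")
        K = _kernel_matrix(self.X, self.X, self.sigma_f, self.length_scales)
        K[np.diag_indices_from(K)] += self.noise_var + _JITTER
        try:
            self._chol = cho_factor(K, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError("singular Gram matrix after jitter") from exc
        self._alpha = cho_solve(self._chol, self.y)

    def predict(self, Xs) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance at query points (rows)."""
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        Ks = _kernel_matrix(Xs, self.X, self.sigma_f, self.length_scales)
        mean = Ks @ self._alpha
        v = cho_solve(self._chol, Ks.T)
        var = self.sigma_f ** 2 - np.sum(Ks * v.T, axis=1)
        return mean, np.maximum(var, 0.0)

    def log_marginal_likelihood(self) -> float:
        L = self._chol[0]
        n = len(self.y)
        return float(-0.5 * self.y @ self._alpha
                     - np.sum(np.log(np.diag(L)))
                     - 0.5 * n * np.log(2 * np.pi))


def gp_posterior(observations, sigma_f: float, length_scales,
                 noise_var: float = 0.0) -> GaussianProcessPosterior:
    """Condition a GP on a list of :class:`Observation` (or (x, y) pairs)."""
    X, y = [], []
    for ob in observations:
        if isinstance(ob, Observation):
            X.append(ob.x)
            y.append(ob.y)
        else:
            X.append(ob[0])
            y.append(ob[1])
    return GaussianProcessPosterior(np.atleast_2d(X), np.asarray(y, dtype=float),
                                    sigma_f, length_scales, noise_var)


def fit_gp(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
           n_restarts: int = 2) -> GaussianProcessPosterior:
    """Fit kernel hyperparameters by maximizing the log marginal likelihood.

    Parameters are searched as logs (log sigma_m per dimension, log sigma_f,
    log noise std) with a multi-start Nelder-Mead simplex.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    d = X.shape[1]

    def neg_lml(theta):
        ls = np.exp(theta[:d])
        sf = np.exp(theta[d])
        nv = np.exp(theta[d + 1]) ** 2
        if np.any(ls > 1e3) or sf > 1e3:
            return 1e10
        try:
            gp = GaussianProcessPosterior(X, y, sf, ls, nv)
        except np.linalg.LinAlgError:
            return 1e10
        return -gp.log_marginal_likelihood()

    y_scale = max(np.std(y), 1e-3)
    base = np.concatenate([np.zeros(d) + np.log(0.3),
                           [np.log(y_scale)], [np.log(y_scale * 0.1)]])
    best_theta, best_val = base, neg_lml(base)
    for k in range(n_restarts):
        x0 = base + rng.normal(0, 1.0, size=d + 2) if k else base
        res = minimize(neg_lml, x0, method="Nelder-Mead",
                       options={"maxiter": 120, "xatol": 1e-3, "fatol": 1e-6})
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    ls = np.exp(best_theta[:d])
    sf = np.exp(best_theta[d])
    nv = np.exp(best_theta[d + 1]) ** 2
    return GaussianProcessPosterior(X, y, sf, ls, nv)


def _ei_values(mu: np.ndarray, s: np.ndarray, best: float) -> np.ndarray:
    out = np.maximum(best - mu, 0.0)
    pos = s > 0
    z = (best - mu[pos]) / s[pos]
    out[pos] = s[pos] * (z * norm.cdf(z) + norm.pdf(z))
    return out


def expected_improvement(x, posterior: GaussianProcessPosterior,
                         best_value: float):
    """Closed-form EI for minimization: s*(z*Phi(z) + phi(z)), z=(best-mu)/s.

    Accepts a single point (returns a float) or a batch of rows (returns
    an array).  Degenerates gracefully: with zero predictive spread EI
    equals max(best - mu, 0).
    """
    X = np.atleast_2d(x)
    mu, var = posterior.predict(X)
    vals = _ei_values(mu, np.sqrt(var), best_value)
    return float(vals[0]) if np.ndim(x) == 1 else vals


def ei_per_second(x, posterior: GaussianProcessPosterior,
                  timing_posterior: GaussianProcessPosterior,
                  best_value: float):
    """EI divided by the timing GP's predicted evaluation seconds.

    The timing GP is fitted on log seconds; the denominator is floored at
    a small positive constant so cheap-looking points cannot blow up.
    Accepts a single point or a batch of rows, like
    :func:`expected_improvement`.
    """
    X = np.atleast_2d(x)
    mu, var = posterior.predict(X)
    ei = _ei_values(mu, np.sqrt(var), best_value)
    mu_log_s, _ = timing_posterior.predict(X)
    pred_seconds = np.maximum(np.exp(mu_log_s), _MIN_SECONDS)
    vals = ei / pred_seconds
    return float(vals[0]) if np.ndim(x) == 1 else vals


@dataclass
class BOState:
    space: SearchSpace
    observations: list = field(default_factory=list)
    acquisition: str = "ei"
    seed: int = 0
    iteration: int = 0

    @property
    def best_index(self) -> int:
        ys = [ob.y for ob in self.observations]
        return int(np.argmin(ys))

    @property
    def best_value(self) -> float:
        return self.observations[self.best_index].y

    @property
    def best_point(self) -> np.ndarray:
        return self.space.from_unit(self.observations[self.best_index].x)


def propose_next(state: BOState, rng: np.random.Generator | None = None,
                 n_candidates: int = 2000) -> np.ndarray:
    """Maximize the acquisition over random candidates + local refinement.

    Returns a unit-cube point.  Ties resolve to the lowest candidate index
    (numpy argmax convention).  Deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(state.seed + state.iteration)
    d = state.space.ndim
    obs = [ob for ob in state.observations if not ob.failed]
    X = np.array([ob.x for ob in obs])
    y = np.array([ob.y for ob in obs])
    y_mean = y.mean()
    post = fit_gp(X, y - y_mean, rng)
    best = y.min() - y_mean

    if state.acquisition == "eips":
        log_s = np.log(np.maximum([ob.eval_seconds for ob in obs], _MIN_SECONDS))
        tpost = fit_gp(X, log_s, rng)

        def acq(z):
            return ei_per_second(z, post, tpost, best)
    else:
        def acq(z):
            return expected_improvement(z, post, best)

    cands = rng.uniform(0.0, 1.0, size=(n_candidates, d))
    vals = acq(cands)
    z0 = cands[int(np.argmax(vals))]

    res = minimize(lambda z: -acq(np.clip(z, 0.0, 1.0)[None, :])[0], z0,
                   method="Nelder-Mead",
                   options={"maxiter": 60, "xatol": 1e-4, "fatol": 1e-12})
    z_ref = np.clip(res.x, 0.0, 1.0)
    return z_ref if acq(z_ref[None, :])[0] > np.max(vals) else z0


def _call_objective(objective, x):
    t0 = time.perf_counter()
    out = objective(x)
    elapsed = time.perf_counter() - t0
    if isinstance(out, tuple):
        value, seconds = out
    else:
        value, seconds = out, elapsed
    return float(value), max(float(seconds), _MIN_SECONDS)


def run_bayes_opt(objective, space: SearchSpace, n_seed: int = 4,
                  max_evals: int = 30, seed: int = 0,
                  acquisition: str = "ei", tol: float | None = None) -> BOState:
    """Run the full BO loop: spends exactly ``max_evals`` evaluations
    (``n_seed`` uniform-random, the rest acquisition-driven).

    objective : callable mapping an original-scale point (1-D array) to a
        value, or to a (value, seconds) pair.  A raising objective is
        recorded as a failure and scored worst-so-far.
    tol : optional early stop when the improvement between consecutive
        incumbents drops below this threshold (off by default).
    """
    if not 1 <= n_seed <= max_evals:
        raise ValueError("need max_evals >= n_seed >= 1")
    if isinstance(space, (list, tuple)):
        space = SearchSpace(space)
    rng = np.random.default_rng(seed)
    state = BOState(space=space, acquisition=acquisition, seed=seed)

    def evaluate(z):
        x = space.from_unit(z)
        try:
            value, seconds = _call_objective(objective, x)
            failed = not np.isfinite(value)
        except Exception:
            value, seconds, failed = np.nan, _MIN_SECONDS, True
        if failed:
            finite = [ob.y for ob in state.observations if not ob.failed]
            value = max(finite) if finite else 0.0
        state.observations.append(Observation(np.asarray(z, dtype=float),
                                              value, seconds, failed))

    for _ in range(n_seed):
        evaluate(rng.uniform(0.0, 1.0, size=space.ndim))

    prev_best = state.best_value
    while len(state.observations) < max_evals:
        state.iteration += 1
        z = propose_next(state, rng)
        evaluate(z)
        if tol is not None:
            improvement = prev_best - state.best_value
            if 0 <= improvement < tol:
                break
            prev_best = state.best_value
    return state


def demo_space() -> SearchSpace:
    """The standard three-hyperparameter tuning space: initial learning rate
    0.01-0.9 (log scale), momentum 0.8-0.98 (linear), L2 regularization
    1e-10-1e-2 (log scale)."""
    return SearchSpace([
        Dimension("initial_learn_rate", 0.01, 0.9, "log"),
        Dimension("momentum", 0.8, 0.98, "linear"),
        Dimension("l2_regularization", 1e-10, 1e-2, "log"),
    ])


def make_demo_objective(seed: int = 0, n_per_class: int = 60, d: int = 20,
                        epochs: int = 80):
    """Stand-in tuning objective: validation error of a small softmax
    classifier trained by SGD with momentum and L2 decay on synthetic
    features, as a function of (learning rate, momentum, L2).
    """
    from .synthetic import FeatureSpec, make_feature_dataset

    spec = FeatureSpec(n_per_class=n_per_class, d=d, n_informative=5,
                       class_sep=1.0, seed=seed)
    data = make_feature_dataset(spec)
    X, y = data.values, data.labels
    classes, y_idx = np.unique(y, return_inverse=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    split = int(0.7 * len(y))
    tr, va = order[:split], order[split:]
    Y = np.eye(len(classes))[y_idx]

    def objective(x):
        lr, mom, l2 = x
        w = np.zeros((X.shape[1], len(classes)))
        v = np.zeros_like(w)
        for _ in range(epochs):
            logits = X[tr] @ w
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            g = X[tr].T @ (p - Y[tr]) / len(tr) + l2 * w
            v = mom * v - lr * g
            w = w + v
        pred = np.argmax(X[va] @ w, axis=1)
        return float(np.mean(pred != y_idx[va]))

    return objective
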
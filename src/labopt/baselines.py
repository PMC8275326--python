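"""Comparison strategies: batch GP optimization (TS/EI/PI/UCB), uniform
random selection without replacement, and Latin hypercube sampling.

The batch GP baselines operate on a finite candidate table: they draw a
random initial training set of size equal to the batch, then repeatedly
score all unused candidates with the chosen acquisition, evaluate the top
batch, and refit, until the evaluation budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc

from .space import ConfigSpace
from .surrogate import GPSurrogate, UCBPolicy

__all__ = [
    "BatchBOConfig",
    "TrialHistory",
    "batch_bo",
    "random_select",
    "lhs_sample",
    "expected_improvement",
    "probability_of_improvement",
]

ACQUISITIONS = ("ts", "ei", "pi", "ucb")


@dataclass
class BatchBOConfig:
    acquisition: str
    batch_size: int = 4
    budget: int = 25
    seed: int = 0
    eta: float = 0.05  # UCB confidence parameter
    n_restarts: int = 2  # hyperparameter refit restarts per iteration
    gp_sigma: float = 1.0
    gp_length_scale: float = 0.25
    gp_noise: float = 1e-6

    def __post_init__(self):
        self.acquisition = self.acquisition.lower()
        if self.acquisition not in ACQUISITIONS:
            raise ValueError(f"acquisition must be one of {ACQUISITIONS}")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.budget < self.batch_size:
            raise ValueError("budget must cover the initial training batch")


@dataclass
class TrialHistory:
    """Per-trial record of evaluation order and progress."""

    order: list[int]  # candidate row indices, in evaluation order
    values: list[float]
    best_so_far: list[float] = field(default_factory=list)
    found_optimum: bool = False
    evals_to_optimum: int | None = None

    def __post_init__(self):
        if not self.best_so_far:
            self.best_so_far = list(np.maximum.accumulate(self.values))

    @staticmethod
    def from_order(order, values, optimum_index) -> "TrialHistory":
        order = list(order)
        hist = TrialHistory(order=order, values=[float(v) for v in values])
        if optimum_index in order:
            hist.found_optimum = True
            hist.evals_to_optimum = order.index(optimum_index) + 1
        return hist


def expected_improvement(mean, std, best, xi: float = 0.0):
    """Closed-form EI of a Gaussian posterior over the incumbent ``best``."""
    mean = np.asarray(mean, dtype=float)
    std = np.asarray(std, dtype=float)
    imp = mean - best - xi
    out = np.where(imp > 0, imp, 0.0).astype(float)
    pos = std > 0
    z = np.zeros_like(mean)
    z[pos] = imp[pos] / std[pos]
    out[pos] = imp[pos] * norm.cdf(z[pos]) + std[pos] * norm.pdf(z[pos])
    return out


def probability_of_improvement(mean, std, best, xi: float = 0.0):
    """Closed-form PI of a Gaussian posterior over the incumbent ``best``."""
    mean = np.asarray(mean, dtype=float)
    std = np.asarray(std, dtype=float)
    imp = mean - best - xi
    out = (imp > 0).astype(float)
    pos = std > 0
    out[pos] = norm.cdf(imp[pos] / std[pos])
    return out


def _thompson_draw(gp: GPSurrogate, X: np.ndarray, rng) -> np.ndarray:
    """One exact joint posterior draw over the rows of ``X``."""
    from sklearn.gaussian_process import GaussianProcessRegressor

    if gp.n_observations == 0:
        cov = gp._kernel(X)
        mean = np.zeros(len(X))
    else:
        gpr = gp._ensure_fitted()
        mean, cov = gpr.predict(X, return_cov=True)
    jitter = 1e-10 * np.eye(len(X))
    L = np.linalg.cholesky(cov + jitter)
    return mean + L @ rng.standard_normal(len(X))


def batch_bo(scaled: np.ndarray, values: np.ndarray, cfg: BatchBOConfig) -> TrialHistory:
    """One batch-mode GP optimization trial over a finite candidate set.

    ``scaled`` is the (n, d) array of unit-hypercube candidate coordinates,
    ``values`` the objective value of each row (maximize).
    """
    scaled = np.asarray(scaled, dtype=float)
    values = np.asarray(values, dtype=float)
    n, d = scaled.shape
    if cfg.budget > n:
        raise ValueError("budget exceeds the candidate pool")
    rng = np.random.default_rng(cfg.seed)
    optimum_index = int(np.argmax(values))

    gp = GPSurrogate(
        d,
        sigma=cfg.gp_sigma,
        length_scale=cfg.gp_length_scale,
        noise=cfg.gp_noise,
        n_restarts=cfg.n_restarts,
        seed=cfg.seed,
    )
    policy = UCBPolicy(eta=cfg.eta)

    order = [int(i) for i in rng.choice(n, size=cfg.batch_size, replace=False)]
    for i in order:
        gp.add_observation(scaled[i], values[i])
    used = np.zeros(n, dtype=bool)
    used[order] = True

    while len(order) < cfg.budget:
        gp.refit()
        free = np.flatnonzero(~used)
        X = scaled[free]
        if cfg.acquisition == "ts":
            scores = _thompson_draw(gp, X, rng)
        else:
            mean, var = gp.posterior_many(X)
            std = np.sqrt(np.maximum(var, 0.0))
            best = float(gp.y.max())
            if cfg.acquisition == "ei":
                scores = expected_improvement(mean, std, best)
            elif cfg.acquisition == "pi":
                scores = probability_of_improvement(mean, std, best)
            else:  # ucb
                coef = policy.coefficient(policy.m + 1)
                policy.m += len(X)
                scores = mean + coef * std
        take = min(cfg.batch_size, cfg.budget - len(order))
        # stable top-`take` by score descending, candidate row order on ties
        top = free[np.argsort(-scores, kind="stable")[:take]]
        for i in top:
            order.append(int(i))
            used[i] = True
            gp.add_observation(scaled[i], values[i])

    return TrialHistory.from_order(order, values[order], optimum_index)


def random_select(n_candidates: int, values, budget: int, seed: int) -> TrialHistory:
    """Uniform selection of ``budget`` candidates without replacement."""
    if budget > n_candidates:
        raise ValueError("budget exceeds the candidate pool")
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    order = [int(i) for i in rng.choice(n_candidates, size=budget, replace=False)]
    return TrialHistory.from_order(order, values[order], int(np.argmax(values)))


def lhs_sample(space: ConfigSpace, n: int, seed: int) -> list[list]:
    """``n`` Latin-hypercube configurations in native space.

    One sample per axis stratum per dimension (random placement within each
    stratum); level/categorical axes are snapped to the nearest listed
    level.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=space.dim, seed=seed)
    unit = sampler.random(n)
    out = []
    for row in unit:
        # unscale_value snaps level/categorical axes to the nearest level
        out.append([p.unscale_value(z) for p, z in zip(space.params, row)])
    return out
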
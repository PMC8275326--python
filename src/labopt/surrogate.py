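"""Gaussian-process surrogate with Matérn-5/2 kernel and UCB queries.

Posterior inference and marginal-likelihood refits are delegated to
scikit-learn's ``GaussianProcessRegressor``; this module pins down the
conventions the optimizer relies on: a zero-mean prior, initial
hyperparameters ``sigma = 1`` and ``length_scale = 0.25``, a small fixed
jitter on the kernel diagonal, and a deterministic multi-restart refit.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, Matern

logger = logging.getLogger(__name__)

__all__ = ["GPSurrogate", "UCBPolicy"]


class IllConditionedKernelError(RuntimeError):
    """Kernel matrix could not be factorized; raise the jitter and retry."""


class UCBPolicy:
    """Upper-confidence-bound coefficient schedule.

    The coefficient ``B(M, eta) = sqrt(2 * ln(pi^2 M^2 / (12 eta)))`` is
    non-decreasing in the query counter ``M``, so confidence intervals widen
    slowly as more bounds are issued.  ``eta`` is the confidence parameter.
    """

    def __init__(self, eta: float = 0.05) -> None:
        if not 0.0 < eta < 1.0:
            raise ValueError("eta must lie in (0, 1)")
        self.eta = eta
        self.m = 0  # number of UCB queries issued so far

    def coefficient(self, m: int | None = None) -> float:
        m = self.m if m is None else m
        m = max(m, 1)
        return math.sqrt(2.0 * math.log(math.pi**2 * m**2 / (12.0 * self.eta)))

    def bound(self, mean: float, variance: float) -> float:
        """Issue one UCB query: ``mean + B(M) * sqrt(variance)``."""
        self.m += 1
        return mean + self.coefficient(self.m) * math.sqrt(max(variance, 0.0))

    def to_dict(self) -> dict:
        return {"eta": self.eta, "m": self.m}

    @classmethod
    def from_dict(cls, d: dict) -> "UCBPolicy":
        policy = cls(eta=d["eta"])
        policy.m = d["m"]
        return policy


def _make_kernel(kind: str, sigma: float, length_scale: float,
                 sigma_bounds: tuple, length_scale_bounds: tuple):
    const = ConstantKernel(
        constant_value=sigma**2,
        constant_value_bounds=(sigma_bounds[0] ** 2, sigma_bounds[1] ** 2),
    )
    if kind == "matern":
        return const * Matern(length_scale=length_scale,
                              length_scale_bounds=length_scale_bounds, nu=2.5)
    if kind == "rbf":
        return const * RBF(length_scale=length_scale,
                           length_scale_bounds=length_scale_bounds)
    raise ValueError(f"unknown kernel {kind!r}")


class GPSurrogate:
    """Zero-mean GP over the unit hypercube.

    Parameters
    ----------
    dim:
        Input dimension.
    sigma, length_scale:
        Initial signal scale and length scale of the kernel.
    noise:
        Observation noise variance added to the kernel diagonal (jitter).
    kernel:
        ``"matern"`` (smoothness 5/2, the default) or ``"rbf"``.
    n_restarts, seed:
        Restart count and seed for the marginal-likelihood refit.
    """

    def __init__(
        self,
        dim: int,
        sigma: float = 1.0,
        length_scale: float = 0.25,
        noise: float = 1e-6,
        kernel: str = "matern",
        sigma_bounds: tuple = (1e-3, 10.0),
        length_scale_bounds: tuple = (1e-3, 10.0),
        n_restarts: int = 5,
        seed: int = 0,
    ) -> None:
        self.dim = dim
        self.noise = float(noise)
        self.kernel_kind = kernel
        self.sigma_bounds = tuple(sigma_bounds)
        self.length_scale_bounds = tuple(length_scale_bounds)
        self.n_restarts = n_restarts
        self.seed = seed
        self._kernel = _make_kernel(kernel, sigma, length_scale,
                                    self.sigma_bounds, self.length_scale_bounds)
        self._X: list[np.ndarray] = []
        self._y: list[float] = []
        self._gpr: GaussianProcessRegressor | None = None

    # ------------------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return (np.asarray(self._X, dtype=float)
                if self._X else np.empty((0, self.dim)))

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self._y, dtype=float)

    @property
    def n_observations(self) -> int:
        return len(self._y)

    @property
    def sigma(self) -> float:
        return math.sqrt(self._kernel.k1.constant_value)

    @property
    def length_scale(self) -> float:
        return float(self._kernel.k2.length_scale)

    # ------------------------------------------------------------------
    def add_observation(self, x, y: float) -> None:
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != self.dim:
            raise ValueError(f"expected a {self.dim}-vector, got shape {x.shape}")
        self._X.append(x)
        self._y.append(float(y))
        self._gpr = None  # stale

    def _fit_fixed(self) -> GaussianProcessRegressor:
        """(Re)condition on the current observations at fixed hyperparameters."""
        gpr = GaussianProcessRegressor(
            kernel=self._kernel,
            alpha=self.noise,
            optimizer=None,
            normalize_y=False,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gpr.fit(self.X, self.y)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
            raise IllConditionedKernelError(
                "kernel matrix is ill-conditioned; increase the `noise` jitter"
            ) from exc
        return gpr

    def _ensure_fitted(self) -> GaussianProcessRegressor | None:
        if not self._y:
            return None
        if self._gpr is None:
            self._gpr = self._fit_fixed()
        return self._gpr

    def posterior(self, x) -> tuple[float, float]:
        """Posterior mean and variance at a single point.

        With no observations this is the prior: mean 0, variance
        ``sigma**2``.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        gpr = self._ensure_fitted()
        if gpr is None:
            return 0.0, float(self._kernel.diag(x)[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, std = gpr.predict(x, return_std=True)
        return float(mean[0]), float(std[0] ** 2)

    def posterior_many(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized posterior over rows of ``X``; returns (means, variances)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        gpr = self._ensure_fitted()
        if gpr is None:
            return np.zeros(len(X)), self._kernel.diag(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, std = gpr.predict(X, return_std=True)
        return mean, std**2

    def ucb(self, x, policy: UCBPolicy) -> float:
        mean, var = self.posterior(x)
        return policy.bound(mean, var)

    def log_marginal_likelihood(self) -> float:
        gpr = self._ensure_fitted()
        if gpr is None:
            raise ValueError("no observations")
        return float(gpr.log_marginal_likelihood(gpr.kernel_.theta))

    # ------------------------------------------------------------------
    def refit(self) -> "GPSurrogate":
        """Maximize the log marginal likelihood over (sigma, length_scale).

        Runs the scikit-learn L-BFGS optimizer from the current
        hyperparameters plus ``n_restarts`` seeded random starts, so the
        achieved likelihood is at least that of the incoming values and a
        refit with unchanged data is idempotent.  With fewer than two
        observations the hyperparameters are left untouched.
        """
        if self.n_observations < 2:
            logger.info("refit skipped: fewer than 2 observations")
            return self
        gpr = GaussianProcessRegressor(
            kernel=self._kernel,
            alpha=self.noise,
            n_restarts_optimizer=self.n_restarts,
            normalize_y=False,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpr.fit(self.X, self.y)
        self._kernel = gpr.kernel_
        self._gpr = gpr
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "sigma": self.sigma,
            "length_scale": self.length_scale,
            "noise": self.noise,
            "kernel": self.kernel_kind,
            "sigma_bounds": list(self.sigma_bounds),
            "length_scale_bounds": list(self.length_scale_bounds),
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "X": [x.tolist() for x in self._X],
            "y": list(self._y),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPSurrogate":
        gp = cls(
            dim=d["dim"],
            sigma=d["sigma"],
            length_scale=d["length_scale"],
            noise=d["noise"],
            kernel=d["kernel"],
            sigma_bounds=tuple(d["sigma_bounds"]),
            length_scale_bounds=tuple(d["length_scale_bounds"]),
            n_restarts=d["n_restarts"],
            seed=d["seed"],
        )
        for x, y in zip(d["X"], d["y"]):
            gp.add_observation(x, y)
        return gp
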
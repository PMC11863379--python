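"""Gaussian-process surrogate on unit-cube inputs.

The regression model standing in for the true experiment-to-score function:
a zero-mean GP with an anisotropic Matérn-5/2 kernel (one length scale per
encoded coordinate), a signal variance, and a learned white-noise variance.
Targets are standardized internally, inputs are expected on the unit cube
(see :mod:`labopt.space`), so hyperparameter bounds and defaults are
scale-free.

Hyperparameters are chosen by maximizing the log marginal likelihood from
multiple seeded restarts; a fixed fallback configuration is always included
as a start, so the fitted model is never worse (in marginal likelihood) than
that fallback.

Predictions can report the model (epistemic) standard deviation alone or
with the learned observation-noise standard deviation folded in — the latter
is what a repeated physical experiment would actually scatter like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = ["GaussianProcess", "PredictiveSummary", "matern52"]

_SQRT5 = np.sqrt(5.0)

# Hyperparameter box (standardized-y / unit-cube scale)
_LS_BOUNDS = (1e-3, 1e3)
_SF2_BOUNDS = (1e-3, 1e3)
_NOISE_FLOOR = 1e-10

# Fallback hyperparameters: moderate correlation length on the unit cube,
# unit signal variance, 1% noise.  The fit must beat or match these in LML.
_FALLBACK = {"length_scales": 0.3, "signal_variance": 1.0, "noise_variance": 0.01}


def matern52(
    U: np.ndarray,
    V: np.ndarray,
    length_scales: np.ndarray,
    signal_variance: float,
) -> np.ndarray:
    """Matérn-5/2 covariance between row sets U and V.

    k(u, v) = sf2 * (1 + sqrt(5) r + 5/3 r^2) * exp(-sqrt(5) r) with
    r the per-dimension length-scale-weighted Euclidean distance.
    """
    ls = np.asarray(length_scales, dtype=float)
    if np.any(ls <= 0):
        raise ValueError("length scales must be positive")
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    r = cdist(U / ls, V / ls)
    return signal_variance * (1.0 + _SQRT5 * r + (5.0 / 3.0) * r**2) * np.exp(-_SQRT5 * r)


@dataclass
class PredictiveSummary:
    """Posterior prediction at one point, in original response units."""

    mean: float
    std_model: float       # epistemic only
    std_with_noise: float  # includes the learned observation noise


class GaussianProcess:
    """GP regressor with learned anisotropic Matérn-5/2 hyperparameters.

    Parameters
    ----------
    length_scales, signal_variance, noise_variance
        Kernel hyperparameters on the standardized scale.  Usually set by
        :meth:`fit`; pass them explicitly to pin the model (useful for
        oracle comparisons).
    """

    def __init__(
        self,
        length_scales: np.ndarray,
        signal_variance: float,
        noise_variance: float,
    ):
        self.length_scales = np.atleast_1d(np.asarray(length_scales, dtype=float))
        self.signal_variance = float(signal_variance)
        self.noise_variance = float(noise_variance)
        self.X_train: np.ndarray | None = None
        self.y_train: np.ndarray | None = None
        self.y_mean: float = 0.0
        self.y_sd: float = 1.0
        self._chol = None
        self._alpha = None

    # -- fitting -------------------------------------------------------------

    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator | None = None,
        n_restarts: int = 5,
    ) -> "GaussianProcess":
        """Fit hyperparameters by multi-restart maximization of the log
        marginal likelihood.

        Restart starting points are drawn log-uniformly inside the
        hyperparameter box from ``rng``; the fixed fallback configuration is
        always among the starts, so the result's LML is >= the fallback's.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] == 0:
            raise ValueError("cannot fit a GP with zero observations")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite response values")
        if rng is None:
            rng = np.random.default_rng(0)

        n, d = X.shape
        y_mean = float(np.mean(y))
        y_sd = float(np.std(y))
        if y_sd < 1e-12:
            y_sd = 1.0
        z = (y - y_mean) / y_sd

        noise_hi = float(np.var(z) + 1.0)
        lo = np.log(np.r_[np.full(d, _LS_BOUNDS[0]), _SF2_BOUNDS[0], _NOISE_FLOOR])
        hi = np.log(np.r_[np.full(d, _LS_BOUNDS[1]), _SF2_BOUNDS[1], noise_hi])
        bounds = list(zip(lo, hi))

        sq_diffs = (X[:, None, :] - X[None, :, :]) ** 2  # (n, n, d)

        def neg_lml(theta: np.ndarray):
            """Negative LML and its analytic gradient in log hyperparameters."""
            ls = np.exp(theta[:d])
            sf2 = np.exp(theta[d])
            sn2 = np.exp(theta[d + 1])
            rho2 = sq_diffs / ls**2           # per-dim scaled squared distances
            r2 = np.sum(rho2, axis=2)
            r = np.sqrt(r2)
            E = np.exp(-_SQRT5 * r)
            K = sf2 * (1.0 + _SQRT5 * r + (5.0 / 3.0) * r2) * E
            Kn = K.copy()
            Kn[np.diag_indices_from(Kn)] += sn2 + 1e-12
            try:
                L = cholesky(Kn, lower=True)
            except np.linalg.LinAlgError:
                return 1e25, np.zeros_like(theta)
            alpha = cho_solve((L, True), z)
            lml = (
                -0.5 * z @ alpha
                - np.sum(np.log(np.diag(L)))
                - 0.5 * n * np.log(2.0 * np.pi)
            )
            if not np.isfinite(lml):
                return 1e25, np.zeros_like(theta)
            # dLML/dtheta_j = 0.5 tr((alpha alpha^T - K^-1) dK/dtheta_j)
            Kinv = cho_solve((L, True), np.eye(n))
            W = np.outer(alpha, alpha) - Kinv
            grad = np.empty(d + 2)
            dK_dr_factor = sf2 * (5.0 / 3.0) * (1.0 + _SQRT5 * r) * E
            for j in range(d):
                grad[j] = 0.5 * np.sum(W * (dK_dr_factor * rho2[:, :, j]))
            grad[d] = 0.5 * np.sum(W * K)
            grad[d + 1] = 0.5 * np.trace(W) * sn2
            return -lml, -grad

        fallback_theta = np.log(
            np.r_[
                np.full(d, _FALLBACK["length_scales"]),
                _FALLBACK["signal_variance"],
                _FALLBACK["noise_variance"],
            ]
        )
        starts = [fallback_theta]
        for _ in range(n_restarts):
            starts.append(lo + rng.random(d + 2) * (hi - lo))

        best_theta, best_obj = fallback_theta, neg_lml(fallback_theta)[0]
        for theta0 in starts:
            res = minimize(neg_lml, theta0, method="L-BFGS-B", jac=True, bounds=bounds)
            if np.isfinite(res.fun) and res.fun < best_obj:
                best_theta, best_obj = res.x, res.fun

        model = cls(
            length_scales=np.exp(best_theta[:d]),
            signal_variance=float(np.exp(best_theta[d])),
            noise_variance=float(np.exp(best_theta[d + 1])),
        )
        model._set_data(X, y, y_mean, y_sd)
        return model

    def _set_data(self, X: np.ndarray, y: np.ndarray, y_mean: float, y_sd: float) -> None:
        self.X_train = X
        self.y_train = np.asarray(y, dtype=float).ravel()
        self.y_mean = y_mean
        self.y_sd = y_sd
        z = (self.y_train - y_mean) / y_sd
        K = matern52(X, X, self.length_scales, self.signal_variance)
        K[np.diag_indices_from(K)] += self.noise_variance + 1e-12
        self._chol = cho_factor(K, lower=True)
        self._alpha = cho_solve(self._chol, z)

    def set_training_data(self, X: np.ndarray, y: np.ndarray) -> "GaussianProcess":
        """Condition this (fixed-hyperparameter) model on data without refitting."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        y_mean = float(np.mean(y))
        y_sd = float(np.std(y))
        if y_sd < 1e-12:
            y_sd = 1.0
        self._set_data(X, y, y_mean, y_sd)
        return self

    # -- prediction ----------------------------------------------------------

    @property
    def fitted(self) -> bool:
        return self._alpha is not None

    def log_marginal_likelihood(self) -> float:
        """LML of the current hyperparameters on the stored (standardized) data."""
        self._require_fitted()
        z = (self.y_train - self.y_mean) / self.y_sd
        L = self._chol[0]
        n = len(z)
        return float(
            -0.5 * z @ self._alpha
            - np.sum(np.log(np.diag(L)))
            - 0.5 * n * np.log(2.0 * np.pi)
        )

    def predict(
        self, U: np.ndarray, include_noise: bool = False, return_std: bool = True
    ):
        """Posterior mean (and std) at unit-cube rows U, original y units.

        With ``include_noise`` the returned std includes the learned
        observation-noise variance; without, it is the epistemic model std.
        """
        self._require_fitted()
        U = np.atleast_2d(np.asarray(U, dtype=float))
        Ks = matern52(U, self.X_train, self.length_scales, self.signal_variance)
        mean = self.y_mean + self.y_sd * (Ks @ self._alpha)
        if not return_std:
            return mean
        v = cho_solve(self._chol, Ks.T)
        var = self.signal_variance - np.einsum("ij,ji->i", Ks, v)
        var = np.maximum(var, 0.0)
        if include_noise:
            var = var + self.noise_variance
        std = np.sqrt(var) * self.y_sd
        return mean, std

    def predict_summary(self, u: np.ndarray) -> PredictiveSummary:
        """Full predictive summary at a single unit-cube point."""
        mean, std_model = self.predict([u], include_noise=False)
        _, std_noise = self.predict([u], include_noise=True)
        return PredictiveSummary(
            mean=float(mean[0]),
            std_model=float(std_model[0]),
            std_with_noise=float(std_noise[0]),
        )

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise ValueError("model has no training data; call fit() first")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        self._require_fitted()
        return {
            "length_scales": self.length_scales.tolist(),
            "signal_variance": self.signal_variance,
            "noise_variance": self.noise_variance,
            "X_train": self.X_train.tolist(),
            "y_train": self.y_train.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GaussianProcess":
        model = cls(
            np.asarray(data["length_scales"]),
            data["signal_variance"],
            data["noise_variance"],
        )
        model.set_training_data(np.asarray(data["X_train"]), np.asarray(data["y_train"]))
        return model
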
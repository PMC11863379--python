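"""Acquisition functions and their maximization over a design space.

All acquisitions follow the minimization convention: the optimizer is
looking for the recipe with the lowest score, and each acquisition assigns
higher values to more promising candidates (LCB is internally negated).

* EI — expected improvement below the incumbent minus a margin xi;
* PI — probability of improvement below the incumbent minus xi;
* LCB — lower confidence bound mu - kappa*sigma (lower is more promising).

Maximization evaluates the acquisition on a seeded batch of uniform feasible
candidates and polishes the best few with a bounded derivative-free search
in unit coordinates; integer and categorical dimensions are handled by
decoding the polished continuous point and re-scoring it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .space import SearchSpace, Constraint, ValidationError
from .surrogate import GaussianProcess

__all__ = [
    "AcquisitionSpec",
    "expected_improvement",
    "probability_of_improvement",
    "lcb",
    "argmax_acquisition",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Which acquisition to use and its exploration parameter.

    xi is the improvement margin for EI/PI (response units, on the
    standardized scale of mu/sigma as passed in); kappa the LCB multiplier.
    """

    kind: str = "EI"
    xi: float = 0.01
    kappa: float = 1.96

    def __post_init__(self):
        if self.kind not in ("EI", "PI", "LCB"):
            raise ValidationError(f"unknown acquisition kind {self.kind!r}")
        if self.xi < 0 or self.kappa < 0:
            raise ValidationError("xi and kappa must be >= 0")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "xi": self.xi, "kappa": self.kappa}

    @classmethod
    def from_dict(cls, data: dict) -> "AcquisitionSpec":
        return cls(
            kind=data.get("kind", "EI"),
            xi=float(data.get("xi", 0.01)),
            kappa=float(data.get("kappa", 1.96)),
        )


def _check_finite(*vals) -> None:
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite acquisition input")


def expected_improvement(mu, sigma, best, xi: float = 0.0):
    """E[max(best - xi - Y, 0)] for Y ~ Normal(mu, sigma^2), elementwise.

    The closed form is (best - mu - xi)*Phi(z) + sigma*phi(z) with
    z = (best - mu - xi)/sigma; the sigma -> 0 limit is the positive part of
    the deterministic improvement.  Always non-negative.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    _check_finite(mu, sigma, best, xi)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    imp = best - mu - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, imp / np.where(sigma > 0, sigma, 1.0), 0.0)
        ei = np.where(
            sigma > 0,
            imp * norm.cdf(z) + sigma * norm.pdf(z),
            np.maximum(imp, 0.0),
        )
    return np.maximum(ei, 0.0)


def probability_of_improvement(mu, sigma, best, xi: float = 0.0):
    """P(Y < best - xi) for Y ~ Normal(mu, sigma^2), elementwise."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    _check_finite(mu, sigma, best, xi)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    imp = best - mu - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(
            sigma > 0,
            norm.cdf(np.where(sigma > 0, imp / np.where(sigma > 0, sigma, 1.0), 0.0)),
            (imp > 0).astype(float),
        )


def lcb(mu, sigma, kappa: float = 1.96):
    """Lower confidence bound mu - kappa*sigma (lower is more promising)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    _check_finite(mu, sigma)
    return mu - kappa * sigma


def acquisition_values(
    spec: AcquisitionSpec, model: GaussianProcess, U: np.ndarray
) -> np.ndarray:
    """Evaluate the acquisition (higher = better) at unit-cube rows U."""
    mu, sigma = model.predict(U, include_noise=False)
    best = float(np.min(model.y_train))
    if spec.kind == "EI":
        return expected_improvement(mu, sigma, best, spec.xi)
    if spec.kind == "PI":
        return probability_of_improvement(mu, sigma, best, spec.xi)
    return -lcb(mu, sigma, spec.kappa)


def argmax_acquisition(
    model: GaussianProcess,
    space: SearchSpace,
    spec: AcquisitionSpec,
    rng: np.random.Generator,
    constraints: Sequence[Constraint] | None = None,
    n_candidates: int = 1000,
    n_polish: int = 5,
) -> list:
    """Return the feasible recipe maximizing the acquisition.

    Seeded uniform feasible candidates are scored in one vectorized pass; the
    best ``n_polish`` are refined by bounded Powell search on the continuous
    relaxation, decoded back to a recipe (rounding integers, argmax-decoding
    categoricals), constraint-checked and re-scored.  Deterministic given the
    rng state.
    """
    constraints = list(constraints or [])
    candidates = space.sample(n_candidates, rng, constraints=constraints)
    U = space.to_unit_many(candidates)
    scores = acquisition_values(spec, model, U)

    order = np.argsort(scores)[::-1]
    best_point = candidates[order[0]]
    best_score = float(scores[order[0]])

    def neg_acq(u: np.ndarray) -> float:
        return -float(acquisition_values(spec, model, u.reshape(1, -1))[0])

    bounds = [(0.0, 1.0)] * space.encoded_width
    for i in order[:n_polish]:
        res = minimize(
            neg_acq, U[i], method="Powell", bounds=bounds,
            options={"maxiter": 200, "xtol": 1e-4, "ftol": 1e-6},
        )
        point = space.from_unit(np.clip(res.x, 0.0, 1.0))
        if constraints and not all(c.holds(space, point) for c in constraints):
            continue
        # re-score the decoded point (rounding may have moved it)
        score = float(acquisition_values(spec, model, space.to_unit(point).reshape(1, -1))[0])
        if score > best_score:
            best_point, best_score = point, score
    return list(best_point)
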
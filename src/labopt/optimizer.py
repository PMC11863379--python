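"""Sequential ask/tell Bayesian optimization loop.

The :class:`Optimizer` proposes experiments and consumes their measured
scores.  The first ``n_initial_points`` suggestions come from a seeded
Latin-hypercube design with no model involvement; after that each suggestion
maximizes an acquisition function over a Gaussian-process surrogate fitted
to everything observed so far.  The loop is fully reproducible from
(space, configuration, seed, told data).

Conventions chosen for running *physical* experiments:

* ``ask`` is idempotent — repeated asks without an intervening ``tell``
  return the same recipe, so a lost notebook entry never wastes a run;
* scores are minimized throughout;
* batch suggestions use the constant-liar heuristic: each pending
  suggestion is temporarily imputed a pseudo-score (the min, mean or max of
  real observations) so later suggestions in the batch spread out;
* telling a recipe the optimizer never suggested is allowed (historical
  data import) and recorded with origin "manual".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec, argmax_acquisition
from .space import Constraint, SearchSpace, ValidationError
from .surrogate import GaussianProcess

__all__ = [
    "Optimizer",
    "OptResult",
    "ObservationRecord",
    "expected_min",
    "convergence_trace",
    "partial_dependence",
]

_BATCH_STRATEGIES = ("cl_min", "cl_mean", "cl_max")


@dataclass
class ObservationRecord:
    """One completed experiment: recipe, score and how the recipe arose."""

    x: list
    y: float
    origin: str  # "initial" | "model" | "manual"


@dataclass
class OptResult:
    """Queryable outcome of an optimization: data, incumbent and models."""

    space: SearchSpace
    observations: list[ObservationRecord]
    models: list[GaussianProcess] = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    seed: int = 0

    @property
    def best_index(self) -> int:
        if not self.observations:
            raise ValidationError("no observations yet")
        return int(np.argmin([o.y for o in self.observations]))

    @property
    def best_y(self) -> float:
        return self.observations[self.best_index].y

    @property
    def best_x(self) -> list:
        return self.observations[self.best_index].x

    @property
    def model(self) -> GaussianProcess | None:
        """Most recent surrogate, or None before the first fit."""
        return self.models[-1] if self.models else None

    # -- export --------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "space": self.space.to_dict(),
            "observations": [
                {"x": o.x, "y": o.y, "origin": o.origin} for o in self.observations
            ],
            "best_x": self.best_x if self.observations else None,
            "best_y": self.best_y if self.observations else None,
            "model_hyperparameters": [
                {
                    "length_scales": m.length_scales.tolist(),
                    "signal_variance": m.signal_variance,
                    "noise_variance": m.noise_variance,
                }
                for m in self.models
            ],
            "model": self.model.to_dict() if self.model is not None else None,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "OptResult":
        with open(path) as fh:
            data = json.load(fh)
        space = SearchSpace.from_dict(data["space"])
        obs = [ObservationRecord(o["x"], o["y"], o["origin"]) for o in data["observations"]]
        models = []
        if data.get("model") is not None:
            models = [GaussianProcess.from_dict(data["model"])]
        return cls(space=space, observations=obs, models=models, seed=data.get("seed", 0))

    def observations_frame(self) -> pd.DataFrame:
        """Observation log as a DataFrame: iteration, factors, score, origin."""
        rows = []
        for i, o in enumerate(self.observations, start=1):
            row = {"iteration": i}
            row.update({name: v for name, v in zip(self.space.names, o.x)})
            row["score"] = o.y
            row["origin"] = o.origin
            rows.append(row)
        return pd.DataFrame(rows)


class Optimizer:
    """Ask/tell Bayesian optimizer over a mixed design space.

    Parameters
    ----------
    space : SearchSpace
    n_initial_points : int
        Number of Latin-hypercube suggestions served before the first
        surrogate fit.
    acq : AcquisitionSpec, default EI with xi = 0.01
    seed : int
        Drives every random stream (LHS design, GP restarts, candidate
        sampling); replays are bit-identical.
    constraints : sequence of Constraint, optional
    """

    def __init__(
        self,
        space: SearchSpace,
        n_initial_points: int = 4,
        acq: AcquisitionSpec | None = None,
        seed: int = 0,
        constraints: Sequence[Constraint] | None = None,
    ):
        if n_initial_points < 1:
            raise ValidationError("n_initial_points must be >= 1")
        self.space = space
        self.n_initial_points = int(n_initial_points)
        self.acq = acq if acq is not None else AcquisitionSpec()
        self.seed = int(seed)
        self.constraints = list(constraints or [])
        for c in self.constraints:
            c.check_names(space)

        self.observations: list[ObservationRecord] = []
        self.models: list[GaussianProcess] = []
        self._cached_suggestion: list | None = None
        self._initial_queue: list[list] = self._initial_design()

    def _initial_design(self) -> list[list]:
        rng = np.random.default_rng([self.seed, 11])
        if self.constraints:
            # keep drawing LHS designs until one is fully feasible
            for attempt in range(1000):
                design = self.space.lhs(
                    self.n_initial_points, np.random.default_rng([self.seed, 11, attempt])
                )
                if all(
                    all(c.holds(self.space, p) for c in self.constraints) for p in design
                ):
                    return design
            # fall back to rejection-sampled uniform points
            return self.space.sample(self.n_initial_points, rng, self.constraints)
        return self.space.lhs(self.n_initial_points, rng)

    # -- core loop -----------------------------------------------------------

    def ask(self) -> list:
        """Suggest the next recipe (idempotent until the next ``tell``).

        While the initial queue is non-empty its head is served (the queue is
        consumed by ``tell``, so asks never burn design points); afterwards
        the suggestion maximizes the acquisition of the current surrogate.
        """
        if self._cached_suggestion is not None:
            return list(self._cached_suggestion)
        if self._initial_queue:
            suggestion = self._initial_queue[0]
        else:
            model = self._current_model()
            rng = np.random.default_rng([self.seed, 23, len(self.observations)])
            suggestion = argmax_acquisition(
                model, self.space, self.acq, rng, self.constraints
            )
        self._cached_suggestion = list(suggestion)
        return list(suggestion)

    def tell(self, x: Sequence, y: float, origin: str | None = None) -> OptResult:
        """Record an experiment's score and return the updated result.

        ``origin`` defaults to "initial" while the initial design is being
        consumed, "model" when a model-phase suggestion is pending, and
        "manual" otherwise; pass it explicitly to override (e.g. when
        importing historical data).
        """
        x = self.space.validate(x)
        y = float(y)
        if not np.isfinite(y):
            raise ValidationError(f"score must be finite, got {y}")
        if origin is None:
            if len(self.observations) < self.n_initial_points:
                origin = "initial"
            elif self._cached_suggestion is not None:
                origin = "model"
            else:
                origin = "manual"
        self.observations.append(ObservationRecord(list(x), y, origin))
        self._cached_suggestion = None
        if origin == "initial" and self._initial_queue:
            self._initial_queue.pop(0)
        if len(self.observations) >= self.n_initial_points:
            self.models.append(self._fit_model(self.observations))
        return self.get_result()

    def _fit_model(self, observations: list[ObservationRecord]) -> GaussianProcess:
        X = self.space.to_unit_many([o.x for o in observations])
        y = np.array([o.y for o in observations])
        rng = np.random.default_rng([self.seed, 31, len(observations)])
        return GaussianProcess.fit(X, y, rng=rng)

    def _current_model(self) -> GaussianProcess:
        if not self.models or len(self.observations) == 0:
            raise ValidationError("no surrogate available yet")
        return self.models[-1]

    def get_result(self) -> OptResult:
        return OptResult(
            space=self.space,
            observations=list(self.observations),
            models=list(self.models),
            constraints=list(self.constraints),
            seed=self.seed,
        )

    # -- batch ---------------------------------------------------------------

    def ask_batch(self, n: int, strategy: str = "cl_min") -> list[list]:
        """Suggest ``n`` recipes at once via the constant-liar heuristic.

        Remaining initial-design points are served first.  Model-phase slots
        are filled iteratively: suggest, impute a lie (min/mean/max of real
        scores per strategy), refit, repeat.  The optimizer's real state is
        untouched — lies never persist and the batch stays reproducible until
        the next ``tell`` (ask_batch(1) coincides with ask()).
        """
        if n < 1:
            raise ValidationError("batch size must be >= 1")
        if strategy not in _BATCH_STRATEGIES:
            raise ValidationError(
                f"unknown batch strategy {strategy!r}; choose from {_BATCH_STRATEGIES}"
            )
        batch: list[list] = [list(p) for p in self._initial_queue[:n]]
        if len(batch) >= n:
            return batch

        ys = np.array([o.y for o in self.observations])
        if ys.size == 0:
            raise ValidationError(
                "batch asks beyond the initial design need at least one observation"
            )
        lie = {"cl_min": ys.min(), "cl_mean": ys.mean(), "cl_max": ys.max()}[strategy]
        pseudo = list(self.observations)
        while len(batch) < n:
            # rng keys depend on the pseudo-data size, so the first model-phase
            # slot reproduces exactly what a plain ask() would suggest
            model = self._fit_model(pseudo)
            rng = np.random.default_rng([self.seed, 23, len(pseudo)])
            point = argmax_acquisition(model, self.space, self.acq, rng, self.constraints)
            batch.append(point)
            pseudo = pseudo + [ObservationRecord(point, float(lie), "model")]
        return batch


# -- result analyses ----------------------------------------------------------


def expected_min(
    result: OptResult,
    n_restarts: int = 5,
    include_noise: bool = False,
    n_candidates: int = 1000,
) -> tuple[list, float, float]:
    """Recipe minimizing the surrogate's predictive mean, with its predicted
    value and standard deviation there.

    The predictive mean is minimized over seeded uniform feasible candidates
    plus every observed recipe as starting points; the best ``n_restarts``
    are polished by bounded derivative-free search.  The reported std is the
    model (epistemic) std by default; ``include_noise`` adds the learned
    observation noise.
    """
    model = result.model
    if model is None:
        raise ValidationError("result has no fitted model yet")
    space = result.space
    from scipy.optimize import minimize  # local import keeps module load cheap

    rng = np.random.default_rng([result.seed, 59, len(result.observations)])
    candidates = space.sample(n_candidates, rng, constraints=result.constraints)
    candidates = candidates + [o.x for o in result.observations]
    U = space.to_unit_many(candidates)
    mu = model.predict(U, return_std=False)

    order = np.argsort(mu)
    best_point = candidates[int(order[0])]
    best_mu = float(mu[order[0]])

    def obj(u: np.ndarray) -> float:
        return float(model.predict(u.reshape(1, -1), return_std=False)[0])

    bounds = [(0.0, 1.0)] * space.encoded_width
    for i in order[:n_restarts]:
        res = minimize(
            obj, U[int(i)], method="Powell", bounds=bounds,
            options={"maxiter": 200, "xtol": 1e-5, "ftol": 1e-8},
        )
        point = space.from_unit(np.clip(res.x, 0.0, 1.0))
        if result.constraints and not all(
            c.holds(space, point) for c in result.constraints
        ):
            continue
        m = obj(space.to_unit(point))
        if m < best_mu:
            best_point, best_mu = point, m

    u_best = space.to_unit(best_point)
    mean, std = model.predict(u_best.reshape(1, -1), include_noise=include_noise)
    return list(best_point), float(mean[0]), float(std[0])


def convergence_trace(result: OptResult) -> np.ndarray:
    """Best-so-far score after each observation (non-increasing)."""
    if not result.observations:
        raise ValidationError("no observations yet")
    ys = np.array([o.y for o in result.observations])
    return np.minimum.accumulate(ys)


@dataclass
class PartialDependence:
    """Plot-ready averaged model response along one or two dimensions."""

    dim_names: tuple
    grid: tuple          # one array per dim, original units / labels
    mean: np.ndarray     # shape (g,) or (g1, g2)
    std: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        if len(self.dim_names) == 1:
            return pd.DataFrame(
                {self.dim_names[0]: self.grid[0], "mean": self.mean, "std": self.std}
            )
        g1, g2 = np.meshgrid(self.grid[0], self.grid[1], indexing="ij")
        return pd.DataFrame(
            {
                self.dim_names[0]: np.asarray(g1).ravel(),
                self.dim_names[1]: np.asarray(g2).ravel(),
                "mean": self.mean.ravel(),
                "std": self.std.ravel(),
            }
        )


def _dim_grid(dim, grid_size: int):
    """Grid of representative values for one dimension, original units."""
    if dim.kind == "categorical":
        return list(dim.categories)
    if dim.kind == "integer":
        vals = np.unique(np.round(np.linspace(dim.low, dim.high, grid_size)).astype(int))
        return vals.tolist()
    return np.linspace(dim.low, dim.high, grid_size).tolist()


def partial_dependence(
    result: OptResult,
    dims: str | Sequence[str],
    grid_size: int = 25,
    n_background: int = 50,
    seed: int | None = None,
) -> PartialDependence:
    """Average the model's predictive mean over the other factors.

    For each grid value of the chosen dimension(s), the remaining factors
    are set to ``n_background`` seeded uniform samples and the predictive
    mean averaged — the data behind a model-landscape ("objective") plot.
    """
    model = result.model
    if model is None:
        raise ValidationError("result has no fitted model yet")
    space = result.space
    if isinstance(dims, str):
        dims = [dims]
    dims = list(dims)
    if len(dims) not in (1, 2):
        raise ValidationError("partial dependence supports one or two dimensions")
    idx = [space.index(name) for name in dims]

    rng = np.random.default_rng(seed if seed is not None else [result.seed, 71])
    background = space.sample(n_background, rng)
    grids = [_dim_grid(space.dims[i], grid_size) for i in idx]

    def profile_at(values: dict[int, object]) -> tuple[float, float]:
        pts = []
        for b in background:
            p = list(b)
            for i, v in values.items():
                p[i] = v
            pts.append(p)
        mu = model.predict(space.to_unit_many(pts), return_std=False)
        return float(np.mean(mu)), float(np.std(mu))

    if len(idx) == 1:
        stats = [profile_at({idx[0]: v}) for v in grids[0]]
        mean = np.array([s[0] for s in stats])
        std = np.array([s[1] for s in stats])
    else:
        mean = np.empty((len(grids[0]), len(grids[1])))
        std = np.empty_like(mean)
        for a, va in enumerate(grids[0]):
            for b, vb in enumerate(grids[1]):
                mean[a, b], std[a, b] = profile_at({idx[0]: va, idx[1]: vb})
    return PartialDependence(
        dim_names=tuple(dims),
        grid=tuple(np.asarray(g) if not isinstance(g, list) or not isinstance(g[0], str) else g for g in grids),
        mean=mean,
        std=std,
    )
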
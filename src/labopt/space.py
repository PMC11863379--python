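"""Mixed-type design spaces for process optimization.

A :class:`SearchSpace` is an ordered list of dimensions — real, integer or
categorical — describing the factors of an experiment (e.g. the percentage of
acid in a buffer, the volume of an indicator solution, or a choice of
solvent).  Points live in two coordinate systems:

* *recipe* coordinates: original units and category labels, one entry per
  dimension, in dimension order (the vector a chemist would pipette from);
* *unit* coordinates: every numeric dimension rescaled linearly to [0, 1] and
  every categorical dimension one-hot encoded, the representation the
  surrogate model and the evolutionary operators work on.

The module also provides constraint predicates (mixture sums, forbidden and
allowed values), grid snapping for plate-based experiments, rejection
sampling, and Latin-hypercube initial designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

__all__ = [
    "Real",
    "Integer",
    "Categorical",
    "SearchSpace",
    "SumEquals",
    "ValueExclusion",
    "ValueRestriction",
    "ValidationError",
    "build_space",
    "satisfies",
]

Recipe = list  # one entry per dimension, original units / labels


class ValidationError(ValueError):
    """A space, constraint, point or configuration failed validation."""


def _round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (documented policy)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class Real:
    """Continuous factor on the closed interval [low, high], original units."""

    low: float
    high: float
    name: str | None = None
    grid_step: float | None = None

    kind = "real"
    encoded_width = 1

    def __post_init__(self) -> None:
        _check_numeric_dim(self)

    def to_unit(self, value: float) -> float:
        return (float(value) - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        return self.low + float(u) * (self.high - self.low)

    def contains(self, value: Any) -> bool:
        return isinstance(value, (int, float, np.integer, np.floating)) and (
            self.low - 1e-12 <= float(value) <= self.high + 1e-12
        )


@dataclass(frozen=True)
class Integer:
    """Discrete numeric factor taking integer values in [low, high]."""

    low: int
    high: int
    name: str | None = None
    grid_step: float | None = None

    kind = "integer"
    encoded_width = 1

    def __post_init__(self) -> None:
        _check_numeric_dim(self)

    def to_unit(self, value: float) -> float:
        return (float(value) - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> int:
        return _round_half_away(self.low + float(u) * (self.high - self.low))

    def contains(self, value: Any) -> bool:
        if not isinstance(value, (int, np.integer)) and not (
            isinstance(value, float) and float(value).is_integer()
        ):
            return False
        return self.low <= int(value) <= self.high


@dataclass(frozen=True)
class Categorical:
    """Unordered factor taking one of a fixed set of labels."""

    categories: tuple
    name: str | None = None

    kind = "categorical"
    grid_step = None

    def __init__(self, categories: Iterable, name: str | None = None):
        object.__setattr__(self, "categories", tuple(categories))
        object.__setattr__(self, "name", name)
        if len(self.categories) == 0:
            raise ValidationError("categorical dimension needs at least one category")
        if len(set(self.categories)) != len(self.categories):
            raise ValidationError(f"duplicate categories in {self.categories!r}")

    @property
    def encoded_width(self) -> int:
        return len(self.categories)

    def contains(self, value: Any) -> bool:
        return value in self.categories


def _check_numeric_dim(dim) -> None:
    if not (dim.low < dim.high):
        raise ValidationError(
            f"dimension {dim.name or ''}: low ({dim.low}) must be < high ({dim.high})"
        )
    if dim.grid_step is not None:
        if dim.grid_step <= 0:
            raise ValidationError("grid_step must be positive")
        span = dim.high - dim.low
        k = span / dim.grid_step
        if abs(k - round(k)) > 1e-9:
            raise ValidationError(
                f"grid_step {dim.grid_step} does not divide the range {span}"
            )


Dimension = Real | Integer | Categorical


class SearchSpace:
    """Ordered collection of dimensions with unit-cube encoding.

    Raises :class:`ValidationError` for an empty space, duplicate names, or a
    space containing only categorical factors (unsupported: the surrogate
    needs at least one numeric axis to model).
    """

    def __init__(self, dims: Sequence[Dimension]):
        dims = list(dims)
        if not dims:
            raise ValidationError("search space needs at least one dimension")
        if all(d.kind == "categorical" for d in dims):
            raise ValidationError(
                "design spaces that only contain categorical factors are not supported"
            )
        named = []
        for i, d in enumerate(dims):
            if d.name is None:
                d = _with_name(d, f"x{i}")
            named.append(d)
        names = [d.name for d in named]
        if len(set(names)) != len(names):
            raise ValidationError(f"dimension names are not unique: {names}")
        self.dims: list[Dimension] = named
        self.encoded_width: int = sum(d.encoded_width for d in self.dims)

    # -- basic introspection -------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dims]

    def __len__(self) -> int:
        return len(self.dims)

    def __repr__(self) -> str:
        return f"SearchSpace({self.dims!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, SearchSpace) and self.dims == other.dims

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown dimension {name!r}; have {self.names}")

    # -- validation ----------------------------------------------------------

    def validate(self, point: Sequence) -> list:
        """Check a recipe point against bounds/categories; return it as a list."""
        point = list(point)
        if len(point) != len(self.dims):
            raise ValidationError(
                f"point has {len(point)} entries, space has {len(self.dims)} dimensions"
            )
        for d, v in zip(self.dims, point):
            if d.kind == "categorical":
                if not d.contains(v):
                    raise ValidationError(
                        f"{v!r} is not a category of dimension {d.name!r} "
                        f"(choices: {list(d.categories)})"
                    )
            else:
                if not isinstance(v, (int, float, np.integer, np.floating)) or not np.isfinite(v):
                    raise ValidationError(f"dimension {d.name!r}: non-numeric value {v!r}")
                if not d.contains(v):
                    raise ValidationError(
                        f"dimension {d.name!r}: value {v} outside [{d.low}, {d.high}]"
                    )
        return point

    # -- encoding ------------------------------------------------------------

    def to_unit(self, point: Sequence) -> np.ndarray:
        """Encode a recipe to the unit cube (numeric rescale + one-hot)."""
        point = self.validate(point)
        coords = np.empty(self.encoded_width)
        j = 0
        for d, v in zip(self.dims, point):
            if d.kind == "categorical":
                block = np.zeros(d.encoded_width)
                block[d.categories.index(v)] = 1.0
                coords[j : j + d.encoded_width] = block
            else:
                coords[j] = np.clip(d.to_unit(v), 0.0, 1.0)
            j += d.encoded_width
        return coords

    def from_unit(self, coords: Sequence[float]) -> list:
        """Decode unit-cube coordinates to a recipe.

        Integer dimensions round half away from zero; categorical blocks decode
        as argmax with ties going to the lowest category index.
        """
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.encoded_width,):
            raise ValidationError(
                f"expected {self.encoded_width} coordinates, got shape {coords.shape}"
            )
        point: list = []
        j = 0
        for d in self.dims:
            block = coords[j : j + d.encoded_width]
            if d.kind == "categorical":
                point.append(d.categories[int(np.argmax(block))])
            else:
                u = float(np.clip(block[0], 0.0, 1.0))
                point.append(d.from_unit(u))
            j += d.encoded_width
        return point

    def to_unit_many(self, points: Sequence[Sequence]) -> np.ndarray:
        return np.array([self.to_unit(p) for p in points])

    # -- grid snapping -------------------------------------------------------

    def round_to_grid(self, point: Sequence) -> list:
        """Snap numeric entries to low + k*grid_step (nearest; ties away from
        zero), clamp into bounds; no-op for dims without a grid_step."""
        point = self.validate(point)
        out: list = []
        for d, v in zip(self.dims, point):
            if d.kind == "categorical" or d.grid_step is None:
                out.append(v)
                continue
            k = _round_half_away((float(v) - d.low) / d.grid_step)
            snapped = d.low + k * d.grid_step
            snapped = min(max(snapped, d.low), d.high)
            if d.kind == "integer":
                snapped = _round_half_away(snapped)
            out.append(snapped)
        return out

    # -- sampling ------------------------------------------------------------

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        constraints: Sequence["Constraint"] | None = None,
        max_proposals: int = 1_000_000,
    ) -> list[list]:
        """Draw n i.i.d. uniform recipes, rejection-sampled to satisfy the
        constraints.  Raises if the feasible region accepts fewer than ~1e-4
        of proposals."""
        if n < 1:
            raise ValidationError("n must be >= 1")
        constraints = list(constraints or [])
        for c in constraints:
            c.check_names(self)
        out: list[list] = []
        proposed = 0
        chunk = max(n, 256)
        while len(out) < n:
            if proposed >= max_proposals:
                raise ValidationError(
                    "infeasible constraint region: acceptance rate below 1e-4 "
                    f"after {proposed} proposals"
                )
            batch = self._uniform(chunk, rng)
            proposed += chunk
            for p in batch:
                if all(c.holds(self, p) for c in constraints):
                    out.append(p)
                    if len(out) == n:
                        break
        return out

    def _uniform(self, n: int, rng: np.random.Generator) -> list[list]:
        cols = []
        for d in self.dims:
            if d.kind == "categorical":
                cols.append([d.categories[i] for i in rng.integers(0, len(d.categories), n)])
            else:
                cols.append([d.from_unit(u) for u in rng.random(n)])
        return [list(row) for row in zip(*cols)]

    def lhs(self, n: int, rng: np.random.Generator) -> list[list]:
        """Latin-hypercube design: per numeric dimension, [0, 1] is split into
        n equal strata and exactly one point is drawn uniformly inside each,
        with an independent random stratum permutation per dimension.
        Categorical dimensions get a shuffled balanced multiset of labels.
        Permutations are consumed from ``rng`` in dimension order, so the
        design is reproducible given (seed, space)."""
        if n < 1:
            raise ValidationError("n must be >= 1")
        cols = []
        for d in self.dims:
            if d.kind == "categorical":
                reps = -(-n // len(d.categories))  # ceil
                multiset = (list(d.categories) * reps)[:n]
                perm = rng.permutation(n)
                cols.append([multiset[i] for i in perm])
            else:
                perm = rng.permutation(n)
                u = (perm + rng.random(n)) / n
                cols.append([d.from_unit(ui) for ui in u])
        return [list(row) for row in zip(*cols)]

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        dims = []
        for d in self.dims:
            entry: dict[str, Any] = {"name": d.name, "kind": d.kind}
            if d.kind == "categorical":
                entry["categories"] = list(d.categories)
            else:
                entry["low"] = d.low
                entry["high"] = d.high
                if d.grid_step is not None:
                    entry["grid_step"] = d.grid_step
            dims.append(entry)
        return {"dimensions": dims}

    @classmethod
    def from_dict(cls, data: dict) -> "SearchSpace":
        if "dimensions" not in data:
            raise ValidationError("missing required key 'dimensions'")
        dims = []
        for entry in data["dimensions"]:
            kind = entry.get("kind", "real")
            name = entry.get("name")
            if kind == "categorical":
                dims.append(Categorical(entry["categories"], name=name))
            elif kind == "integer":
                dims.append(
                    Integer(int(entry["low"]), int(entry["high"]), name=name,
                            grid_step=entry.get("grid_step"))
                )
            elif kind == "real":
                dims.append(
                    Real(float(entry["low"]), float(entry["high"]), name=name,
                         grid_step=entry.get("grid_step"))
                )
            else:
                raise ValidationError(f"unknown dimension kind {kind!r}")
        return cls(dims)


def _with_name(d: Dimension, name: str) -> Dimension:
    if d.kind == "categorical":
        return Categorical(d.categories, name=name)
    cls = Real if d.kind == "real" else Integer
    return cls(d.low, d.high, name=name, grid_step=d.grid_step)


def build_space(dim_specs: Sequence) -> SearchSpace:
    """Build a SearchSpace from terse specs.

    Accepted spec forms, mirroring how practitioners write them:

    * ``(low, high)`` or ``(low, high, "Name")`` — a Real dimension;
    * a list/tuple of strings — a Categorical dimension;
    * an explicit :class:`Real` / :class:`Integer` / :class:`Categorical`;
    * a dict as produced by :meth:`SearchSpace.to_dict`.
    """
    if not dim_specs:
        raise ValidationError("empty design space specification")
    dims: list[Dimension] = []
    for spec in dim_specs:
        if isinstance(spec, (Real, Integer, Categorical)):
            dims.append(spec)
        elif isinstance(spec, dict):
            dims.append(SearchSpace.from_dict({"dimensions": [spec]}).dims[0])
        elif isinstance(spec, (tuple, list)):
            if all(isinstance(s, str) for s in spec):
                dims.append(Categorical(spec))
            elif len(spec) in (2, 3) and all(
                isinstance(s, (int, float)) for s in spec[:2]
            ):
                name = spec[2] if len(spec) == 3 else None
                dims.append(Real(float(spec[0]), float(spec[1]), name=name))
            else:
                raise ValidationError(f"unrecognised dimension spec {spec!r}")
        else:
            raise ValidationError(f"unrecognised dimension spec {spec!r}")
    return SearchSpace(dims)


# -- constraints --------------------------------------------------------------


@dataclass(frozen=True)
class SumEquals:
    """Mixture constraint: the named numeric factors must sum to ``total``
    within ``tolerance`` (e.g. component fractions summing to 100%)."""

    dim_names: tuple
    total: float
    tolerance: float = 1e-6

    kind = "sum_equals"

    def __init__(self, dim_names: Iterable[str], total: float, tolerance: float = 1e-6):
        object.__setattr__(self, "dim_names", tuple(dim_names))
        object.__setattr__(self, "total", float(total))
        object.__setattr__(self, "tolerance", float(tolerance))
        if self.tolerance < 0:
            raise ValidationError("tolerance must be >= 0")

    def check_names(self, space: SearchSpace) -> None:
        for name in self.dim_names:
            space.index(name)

    def holds(self, space: SearchSpace, point: Sequence) -> bool:
        s = sum(float(point[space.index(n)]) for n in self.dim_names)
        return abs(s - self.total) <= self.tolerance

    def to_dict(self) -> dict:
        return {"kind": self.kind, "dim_names": list(self.dim_names),
                "total": self.total, "tolerance": self.tolerance}


@dataclass(frozen=True)
class ValueExclusion:
    """Specific values a factor must not take."""

    dim_name: str
    forbidden: tuple

    kind = "value_exclusion"

    def __init__(self, dim_name: str, forbidden: Iterable):
        object.__setattr__(self, "dim_name", dim_name)
        object.__setattr__(self, "forbidden", tuple(forbidden))

    def check_names(self, space: SearchSpace) -> None:
        space.index(self.dim_name)

    def holds(self, space: SearchSpace, point: Sequence) -> bool:
        return point[space.index(self.dim_name)] not in self.forbidden

    def to_dict(self) -> dict:
        return {"kind": self.kind, "dim_name": self.dim_name,
                "forbidden": list(self.forbidden)}


@dataclass(frozen=True)
class ValueRestriction:
    """The only values a factor is allowed to take (e.g. plate-well levels)."""

    dim_name: str
    allowed: tuple

    kind = "value_restriction"

    def __init__(self, dim_name: str, allowed: Iterable):
        object.__setattr__(self, "dim_name", dim_name)
        object.__setattr__(self, "allowed", tuple(allowed))

    def check_names(self, space: SearchSpace) -> None:
        space.index(self.dim_name)

    def holds(self, space: SearchSpace, point: Sequence) -> bool:
        v = point[space.index(self.dim_name)]
        if isinstance(v, (int, float, np.integer, np.floating)):
            return any(
                isinstance(a, (int, float)) and abs(float(v) - float(a)) <= 1e-9
                for a in self.allowed
            )
        return v in self.allowed

    def to_dict(self) -> dict:
        return {"kind": self.kind, "dim_name": self.dim_name,
                "allowed": list(self.allowed)}


Constraint = SumEquals | ValueExclusion | ValueRestriction

_CONSTRAINT_KINDS = {
    "sum_equals": lambda d: SumEquals(d["dim_names"], d["total"], d.get("tolerance", 1e-6)),
    "value_exclusion": lambda d: ValueExclusion(d["dim_name"], d["forbidden"]),
    "value_restriction": lambda d: ValueRestriction(d["dim_name"], d["allowed"]),
}


def constraint_from_dict(data: dict) -> Constraint:
    kind = data.get("kind")
    if kind not in _CONSTRAINT_KINDS:
        raise ValidationError(f"unknown constraint kind {kind!r}")
    return _CONSTRAINT_KINDS[kind](data)


def satisfies(space: SearchSpace, constraints: Sequence[Constraint], point: Sequence) -> bool:
    """True iff every constraint holds at the point (names checked first)."""
    for c in constraints:
        c.check_names(space)
    return all(c.holds(space, point) for c in constraints)
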
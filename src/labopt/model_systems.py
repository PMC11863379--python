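"""Benchmark model systems: truth functions, noise models and the synthetic
universal-pH-indicator color plate.

A :class:`ModelSystem` packages a ground-truth score function over a design
space with a pluggable noise model, so an optimizer can be benchmarked by
"running experiments" in silico.  The flagship system emulates a colorimetric
pH-adjustment experiment: a 96-well SBS plate spanning 12 acid percentages
(30–85% in steps of 5) by 8 indicator volumes (5–40 µL in steps of 5), each
well holding a CIELAB color, scored by the ΔE (CIE76) distance to a target
color that sits exactly on one well — so the global optimum score is 0 by
construction.

The plate colors here are *synthetic*: the acid%→pH relationship is a
sigmoid titration-curve stand-in and the pH→hue map interpolates a
red→orange→yellow→green→blue→violet indicator palette, with the indicator
volume scaling chroma and fading lightness toward white.  Real measured
plate data can be swapped in from a CSV with the same (acid, indicator,
L, a, b) layout without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .optimizer import Optimizer, OptResult, convergence_trace, expected_min
from .space import Real, SearchSpace, ValidationError

__all__ = [
    "LabColor",
    "ColorGrid",
    "NoiseSpec",
    "ModelSystem",
    "delta_e",
    "synth_color_grid",
    "color_ph_score",
    "recipe_volume",
    "color_ph_system",
    "get_score",
    "run_benchmark",
    "BenchmarkSummary",
]

# plate layout: 12 x 8 wells
ACID_LEVELS = tuple(range(30, 86, 5))        # % acid in the buffer mixture
INDICATOR_LEVELS = tuple(range(5, 41, 5))    # µL of indicator solution

# liquid-handling scheme: the indicator is diluted with water to 40 µL and
# combined with 200 µL of acid/base mixture
INDICATOR_SOLUTION_UL = 40.0
ACID_BASE_UL = 200.0

DEFAULT_TARGET_WELL = (50, 30)

# synthetic universal-indicator palette: (pH, Lab) anchors, increasing pH
DEFAULT_PALETTE = (
    (3.0, (55.0, 70.0, 50.0)),    # red
    (5.0, (70.0, 40.0, 65.0)),    # orange
    (6.5, (90.0, -10.0, 85.0)),   # yellow
    (8.0, (65.0, -55.0, 45.0)),   # green
    (9.5, (45.0, 0.0, -45.0)),    # blue
    (11.0, (35.0, 45.0, -40.0)),  # violet
)


@dataclass(frozen=True)
class LabColor:
    """A color in CIELAB coordinates (L lightness 0–100, a green–red,
    b blue–yellow)."""

    L: float
    a: float
    b: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.L, self.a, self.b)):
            raise ValidationError("Lab components must be finite")
        if not (0.0 <= self.L <= 100.0):
            raise ValidationError(f"L must be in [0, 100], got {self.L}")


def delta_e(c1: LabColor, c2: LabColor) -> float:
    """CIE76 color difference: Euclidean distance in Lab space."""
    return math.sqrt((c1.L - c2.L) ** 2 + (c1.a - c2.a) ** 2 + (c1.b - c2.b) ** 2)


@dataclass
class ColorGrid:
    """The benchmark plate: Lab color per (acid%, indicator µL) well plus the
    target color and the well where it is attained exactly."""

    acid_levels: tuple
    indicator_levels: tuple
    colors: dict           # (acid, indicator) -> LabColor
    target: LabColor
    optimum_well: tuple

    def __post_init__(self):
        expected = len(self.acid_levels) * len(self.indicator_levels)
        if len(self.colors) != expected:
            raise ValidationError(
                f"grid has {len(self.colors)} wells, expected {expected}"
            )
        if delta_e(self.colors[self.optimum_well], self.target) > 1e-12:
            raise ValidationError("target color must be attained at optimum_well")

    @property
    def n_wells(self) -> int:
        return len(self.colors)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"acid": a, "indicator": v, "L": c.L, "a_star": c.a, "b_star": c.b}
            for (a, v), c in sorted(self.colors.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, target_well: tuple = DEFAULT_TARGET_WELL) -> "ColorGrid":
        """Load a plate from CSV (acid, indicator, L, a_star, b_star); the
        target is the color at ``target_well``, which must be on the grid."""
        df = pd.read_csv(path)
        colors = {
            (int(r.acid), int(r.indicator)): LabColor(r.L, r.a_star, r.b_star)
            for r in df.itertuples()
        }
        acid_levels = tuple(sorted({a for a, _ in colors}))
        indicator_levels = tuple(sorted({v for _, v in colors}))
        if tuple(target_well) not in colors:
            raise ValidationError(f"target well {target_well} not in grid")
        return cls(
            acid_levels=acid_levels,
            indicator_levels=indicator_levels,
            colors=colors,
            target=colors[tuple(target_well)],
            optimum_well=tuple(target_well),
        )


def _interp_palette(palette: Sequence, ph: float) -> tuple[float, float, float]:
    """Piecewise-linear Lab interpolation between pH anchors (clamped)."""
    phs = [p for p, _ in palette]
    labs = np.array([lab for _, lab in palette], dtype=float)
    ph = min(max(ph, phs[0]), phs[-1])
    return tuple(np.array([np.interp(ph, phs, labs[:, k]) for k in range(3)]))


def synth_color_grid(
    palette: Sequence = DEFAULT_PALETTE,
    ph_low: float = 3.0,
    ph_high: float = 11.0,
    acid_mid: float = 0.575,
    steepness: float = 10.0,
    target_well: tuple = DEFAULT_TARGET_WELL,
) -> ColorGrid:
    """Deterministically generate the synthetic 96-well indicator plate.

    The buffer pH follows a sigmoid titration curve of the acid fraction a:
    pH = ph_low + (ph_high - ph_low) / (1 + exp(steepness * (a - acid_mid))),
    so more acid means lower pH.  The well hue is the palette color at that
    pH; the indicator volume v scales chroma (a*, b* multiplied by v/40) and
    fades lightness toward 100 (white) as v -> 0.  The target color is the
    generated color at ``target_well``, so the optimum lies exactly on the
    grid with a score of 0.
    """
    phs = [p for p, _ in palette]
    if len(phs) < 4 or any(p2 <= p1 for p1, p2 in zip(phs, phs[1:])):
        raise ValidationError("palette needs >= 4 anchors with strictly increasing pH")
    colors: dict = {}
    for acid in ACID_LEVELS:
        a_frac = acid / 100.0
        ph = ph_low + (ph_high - ph_low) / (1.0 + math.exp(steepness * (a_frac - acid_mid)))
        L0, a0, b0 = _interp_palette(palette, ph)
        for vol in INDICATOR_LEVELS:
            s = vol / INDICATOR_SOLUTION_UL  # chroma scale in [1/8, 1]
            L = 100.0 - (100.0 - L0) * s     # dilute toward white
            colors[(acid, vol)] = LabColor(L, a0 * s, b0 * s)
    tw = tuple(target_well)
    if tw not in colors:
        raise ValidationError(f"target well {tw} is not a plate well")
    return ColorGrid(
        acid_levels=ACID_LEVELS,
        indicator_levels=INDICATOR_LEVELS,
        colors=colors,
        target=colors[tw],
        optimum_well=tw,
    )


def color_ph_space() -> SearchSpace:
    """The two-factor design space of the color experiment."""
    return SearchSpace(
        [
            Real(30.0, 85.0, name="acid%", grid_step=5.0),
            Real(5.0, 40.0, name="indicator µL", grid_step=5.0),
        ]
    )


def recipe_volume(recipe: Sequence[float]) -> float:
    """Total liquid volume (µL) of a color recipe: indicator diluted with
    water to 40 µL, plus 200 µL of acid/base mixture."""
    _, indicator = float(recipe[0]), float(recipe[1])
    if not (0.0 <= indicator <= INDICATOR_SOLUTION_UL):
        raise ValidationError(
            f"indicator volume {indicator} µL exceeds the {INDICATOR_SOLUTION_UL} µL "
            "dilution volume"
        )
    water = INDICATOR_SOLUTION_UL - indicator
    return indicator + water + ACID_BASE_UL


def color_ph_score(grid: ColorGrid, recipe: Sequence[float]) -> float:
    """ΔE of a recipe against the plate target.

    The recipe is snapped to the nearest plate well (steps of 5, matching how
    suggested recipes are executed on the physical plate) and its color
    compared with the target.  The liquid-handling volume is validated on the
    way (it is always 240 µL for a valid recipe).
    """
    space = color_ph_space()
    recipe = space.validate(recipe)
    recipe_volume(recipe)
    acid, vol = space.round_to_grid(recipe)
    return delta_e(grid.colors[(int(acid), int(vol))], grid.target)


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model for simulated experiments.

    kinds: "zero" (none), "constant" (additive Normal(0, size^2)),
    "proportional" (Normal with std = size * |truth|).
    """

    kind: str = "zero"
    size: float = 0.0

    def __post_init__(self):
        if self.kind not in ("zero", "constant", "proportional"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.size < 0:
            raise ValidationError("noise size must be >= 0")
        if self.kind == "zero" and self.size != 0:
            raise ValidationError("zero noise must have size 0")

    def sample(self, truth: float, rng: np.random.Generator) -> float:
        if self.kind == "zero" or self.size == 0:
            return 0.0
        scale = self.size if self.kind == "constant" else self.size * abs(truth)
        if scale == 0:
            return 0.0
        return float(rng.normal(0.0, scale))


@dataclass
class ModelSystem:
    """A benchmark: ground-truth score over a space plus a noise model."""

    truth: Callable[[Sequence], float]
    space: SearchSpace
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    known_min: tuple | None = None  # (recipe, score) when the optimum is known
    name: str = "model_system"


def get_score(system: ModelSystem, recipe: Sequence, rng: np.random.Generator) -> float:
    """Simulate one experiment: truth plus a seeded noise draw."""
    recipe = system.space.validate(recipe)
    t = float(system.truth(recipe))
    return t + system.noise.sample(t, rng)


def color_ph_system(
    noise: NoiseSpec | None = None, grid: ColorGrid | None = None
) -> ModelSystem:
    """The synthetic universal-indicator plate as a ready-to-run benchmark."""
    grid = grid if grid is not None else synth_color_grid()
    return ModelSystem(
        truth=lambda recipe: color_ph_score(grid, recipe),
        space=color_ph_space(),
        noise=noise if noise is not None else NoiseSpec(),
        known_min=([float(grid.optimum_well[0]), float(grid.optimum_well[1])], 0.0),
        name="color_ph",
    )


REGISTRY: dict[str, Callable[[], ModelSystem]] = {"color_ph": color_ph_system}


@dataclass
class BenchmarkSummary:
    """Per-replicate traces and aggregate statistics of a benchmark run."""

    system_name: str
    traces: np.ndarray                 # (n_reps, budget) best-so-far
    final_best: np.ndarray             # (n_reps,)
    expected_min_recipes: list[list]
    expected_min_values: np.ndarray
    true_at_expected_min: np.ndarray | None  # truth at grid-rounded expected_min
    results: list[OptResult]

    @property
    def median_final_best(self) -> float:
        return float(np.median(self.final_best))

    @property
    def median_true_at_expected_min(self) -> float | None:
        if self.true_at_expected_min is None:
            return None
        return float(np.median(self.true_at_expected_min))

    def aggregate(self) -> dict:
        q25, q75 = np.percentile(self.final_best, [25, 75])
        out = {
            "median_final_best": self.median_final_best,
            "iqr_final_best": float(q75 - q25),
        }
        if self.true_at_expected_min is not None:
            q25t, q75t = np.percentile(self.true_at_expected_min, [25, 75])
            out["median_true_at_expected_min"] = self.median_true_at_expected_min
            out["iqr_true_at_expected_min"] = float(q75t - q25t)
        return out

    def traces_frame(self) -> pd.DataFrame:
        n_reps, budget = self.traces.shape
        rows = []
        for r in range(n_reps):
            for i in range(budget):
                rows.append(
                    {"replicate": r, "iteration": i + 1, "best_so_far": self.traces[r, i]}
                )
        return pd.DataFrame(rows)


def run_benchmark(
    system: ModelSystem,
    budget: int = 24,
    n_reps: int = 5,
    master_seed: int = 1,
    n_initial_points: int = 4,
    acq=None,
) -> BenchmarkSummary:
    """Run the full ask → score → tell loop against a model system.

    Each replicate r uses optimizer seed ``master_seed*1000 + r`` (replicate
    seeds stay below 2^31 for any reasonable master seed) and an independent
    noise stream.  When the system's optimum is known, the truth at the
    grid-rounded expected-minimum recipe is recorded per replicate — the
    headline "did the campaign actually land on the optimum" statistic.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if budget < n_initial_points:
        raise ValidationError(
            f"budget ({budget}) must be >= n_initial_points ({n_initial_points})"
        )
    traces = np.empty((n_reps, budget))
    em_recipes: list[list] = []
    em_values = np.empty(n_reps)
    true_em = np.empty(n_reps) if system.known_min is not None else None
    results: list[OptResult] = []
    for rep in range(n_reps):
        rep_seed = master_seed * 1000 + rep
        opt = Optimizer(
            system.space, n_initial_points=n_initial_points, acq=acq, seed=rep_seed
        )
        noise_rng = np.random.default_rng([master_seed, rep, 7])
        result = None
        for _ in range(budget):
            x = opt.ask()
            # the experiment that actually runs is the grid-snapped recipe
            # (a no-op for grid-free spaces); the observation is attributed
            # to the executed recipe, exactly as a lab notebook would record it
            executed = system.space.round_to_grid(x)
            y = get_score(system, executed, noise_rng)
            result = opt.tell(executed, y)
        results.append(result)
        traces[rep] = convergence_trace(result)
        recipe, mean, _ = expected_min(result)
        em_recipes.append(recipe)
        em_values[rep] = mean
        if true_em is not None:
            rounded = system.space.round_to_grid(recipe)
            true_em[rep] = float(system.truth(rounded))
    return BenchmarkSummary(
        system_name=system.name,
        traces=traces,
        final_best=traces[:, -1].copy(),
        expected_min_recipes=em_recipes,
        expected_min_values=em_values,
        true_at_expected_min=true_em,
        results=results,
    )
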
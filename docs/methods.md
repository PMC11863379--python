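# Methods

This note documents the statistical model, the synthetic benchmark
generator, the default parameters and why they were chosen, the numerical
choices that matter for reproducibility, and the known limitations. It makes
no empirical claims beyond what the test suite (`tests/`) and the acceptance
script (`scripts/acceptance.py`) actually compute.

## Problem setting

A campaign minimizes an expensive black-box score `y = f(x) + ε` over a
mixed design space (real, integer, categorical factors). The optimizer never
calls `f` itself: it *asks* for a recipe, the user measures it and *tells*
the score back. All interfaces minimize; maximize by negating the score.

## Design space and encoding

- Real and integer factors are affinely mapped to `[0, 1]` ("unit
  coordinates"); integers round on the way back. Categorical factors are
  handled natively (index genes in the genetic operators, per-category
  handling in sampling) rather than one-hot relaxed.
- Factors may carry a `grid_step` describing equipment resolution (e.g.
  plate wells every 5 %). `round_to_grid` snaps half-away-from-zero, so a
  suggested 79 % acid is executed as 80 %. Suggestions themselves remain
  continuous; rounding is the *execution* step, mirroring how a suggested
  recipe is actually pipetted.
- Constraints (`SumEquals`, `ValueExclusion`, `ValueRestriction`) are
  enforced by rejection sampling in the initial design and by filtering
  acquisition candidates. An infeasible constraint region fails loudly after
  a bounded number of proposals.

## Initial design

The first `n_initial_points` (default 4) suggestions come from a Latin
hypercube: per numeric factor, one point uniformly inside each of `n` equal
strata, strata randomly permuted; categorical factors receive a balanced
shuffled multiset of categories. Exactly these points are served before any
surrogate is fitted — there is nothing to fit a model to yet, and a
space-filling start protects against a confidently wrong early surrogate.
The default of 4 is deliberately small because real experiments are
expensive; with `d` factors, `2d`–`3d` initial points are a reasonable
choice when the budget allows.

## Surrogate model

A zero-mean Gaussian process on unit coordinates with an anisotropic
Matérn-5/2 kernel

```
k(u, v) = σf² (1 + √5 r + 5/3 r²) exp(−√5 r),   r² = Σ_k (u_k − v_k)² / ℓ_k²
```

plus learned white noise σn². Matérn-5/2 is the standard compromise for
physical response surfaces: twice differentiable (smooth enough for
gradient-based acquisition polish) without the unrealistic infinite
smoothness of a squared-exponential kernel.

- Targets are standardized internally (mean 0, sd 1), inputs live on the
  unit cube, so hyperparameter bounds are scale-free: ℓ ∈ [1e−3, 1e3],
  σf² ∈ [1e−3, 1e3], σn² ∈ [1e−10, var(z) + 1].
- Hyperparameters maximize the log marginal likelihood with L-BFGS-B from 5
  log-uniform random restarts **plus a fixed fallback start**
  (ℓ = 0.3, σf² = 1, σn² = 0.01), so the fitted model is never worse in
  marginal likelihood than that sensible default.
- Gradients of the marginal likelihood are **analytic**
  (∂LML/∂θ = ½ tr((ααᵀ − K⁻¹) ∂K/∂θ) in log-hyperparameters). Finite
  differences were tried first and caused seed-sensitive basin switching on
  flat likelihood ridges; analytic gradients make refits reproducible to
  ~1e−11.
- Predictions can include the learned noise (`include_noise=True`) — that is
  what a *repeated physical experiment* would scatter like — or report the
  epistemic model uncertainty alone.
- The model is refitted at every `tell` once the initial design is complete.
  Fits are cubic in n, but campaign sizes here are tens of points, so a
  full refit (seconds) is negligible next to a physical experiment.

## Acquisition

Default is expected improvement with an exploration offset ξ = 0.01 on the
standardized scale (the classic mild-exploration default); probability of
improvement and LCB (κ = 1.96, a 95 % bound) are available. The incumbent is
the best *observed* score. The argmax is found by scoring 1000 seeded
uniform feasible candidates and polishing the top 5 with Powell in unit
coordinates — derivative-free, bound-respecting, and deterministic given the
seed. σ = 0 limits are handled exactly (EI → max(improvement, 0), PI →
indicator).

## Batch suggestions (constant liar)

`ask_batch(n, strategy)` first serves any unconsumed initial-design points,
then repeatedly: suggest, impute a pseudo-score at the suggestion (`cl_min`,
`cl_mean`, or `cl_max` of observed scores), refit on the augmented data, and
suggest again. The pseudo-observations are discarded afterwards —
`ask_batch` has no side effects, and `ask_batch(1)` is bit-identical to
`ask()` because random streams are keyed by the (pseudo-)observation count.

## Analyses

- **Expected minimum**: the recipe minimizing the GP predictive mean, found
  by the same candidates + Powell-polish scheme with all observed points
  added as polish starts; reported with the predictive std (with or without
  noise). This is the recommended end-of-campaign answer: it interpolates
  between measured recipes instead of merely picking the luckiest
  observation.
- **Convergence trace**: running minimum of told scores.
- **Partial dependence**: model mean over a grid for the chosen factor(s),
  averaged over a seeded background sample of the remaining factors.

## Multi-objective (NSGA-II)

Canonical elitist NSGA-II: Deb's fast non-dominated sort, crowding distance
(boundary points infinite; interior points sum normalized neighbour gaps per
objective), binary tournament on (rank, crowding), simulated binary
crossover (η_c = 15, p = 0.9) and polynomial mutation (η_m = 20, p = 1/d) on
unit-interval genes; categorical genes use uniform swap crossover and
category resampling. Defaults: population 40, 50 generations. Constraints
are rejected with an explicit error rather than silently ignored. Note that
per-generation hypervolume is *not* monotone (crowding truncation can shed
tiny slices of the front — inherent to the algorithm); the tested guarantee
is improvement from the initial population to the final front.

## Synthetic color plate (benchmark generator)

The flagship model system emulates a colorimetric pH-adjustment experiment
on a 96-well plate: 12 acid levels (30–85 % in steps of 5) × 8 indicator
volumes (5–40 µL in steps of 5). Each well's color is generated as:

1. **Titration curve**: pH = 3 + 8 / (1 + exp(10 (a − 0.575))) with `a` the
   acid fraction — a sigmoid stand-in for a buffer titration, more acid →
   lower pH.
2. **Indicator palette**: piecewise-linear CIELAB interpolation through six
   anchors, pH 3 red → 5 orange → 6.5 yellow → 8 green → 9.5 blue →
   11 violet — the familiar universal-indicator sweep.
3. **Indicator volume**: scales chroma (a*, b* multiplied by v/40) and fades
   lightness toward white as v → 0, emulating dye dilution.

The target color is the *generated* color at the (50 %, 30 µL) well, so the
global optimum is exactly on the grid with score 0 by construction — which is
what makes "did the campaign land on the optimum" a crisp yes/no statistic.
Scores are CIE76 ΔE (Euclidean distance in Lab). Liquid handling is fixed:
indicator diluted with water to 40 µL plus 200 µL acid/base = 240 µL per
well, validated on every scoring call.

What the generator emulates: a smooth, non-trivial 2-factor response surface
with a unique on-grid optimum and realistic factor semantics. What it does
**not** emulate: real indicator photochemistry, plate-position effects,
pipetting bias, or CIE76's perceptual non-uniformity at large distances.
Real measured plates can replace it via `ColorGrid.from_csv` (columns
`acid, indicator, L, a_star, b_star`) without code changes.

Noise models: `zero`, `constant` (additive N(0, size²)), `proportional`
(std = size·|truth|, hence exactly zero at the optimum).

## Benchmarking protocol

`run_benchmark(system, budget=24, n_reps=5, master_seed=1,
n_initial_points=4)` runs the full ask → score → tell loop per replicate;
replicate r uses optimizer seed `master_seed·1000 + r` and an independent
noise stream. Each suggestion is snapped to the equipment grid before
scoring, and the *executed* recipe is what gets told back — the observation
is attributed to the experiment that actually ran, exactly as a lab notebook
would record it. The headline statistic is the truth at the grid-rounded
expected-minimum recipe (median across replicates) — with the synthetic
plate this is ΔE, and 0 means the campaign identified the exact target well.

## Determinism and numerics

- Every random draw flows through `numpy.random.default_rng` seeded with
  structured keys `[seed, purpose-constant, observation-count]`, so
  suggestions depend only on (config, seed, told data) — never on call
  counts or wall clock. Derived seeds stay below 2³¹.
- Replay: the session log stores recipes as shortest-roundtrip decimal
  text and reads them back with Python's correctly-rounded parser, so
  replaying a log reproduces the live optimizer bit-for-bit.
- Cholesky factorizations carry a 1e−12 jitter; predictive variances are
  clamped at 0; a constant-response campaign (sd < 1e−12) falls back to
  unit scaling instead of dividing by ~0.

## Problem sizes used in validation

The test suite validates against: dense linear-algebra and fixed-kernel
scikit-learn GP oracles (n = 5–9), a 10⁶-draw Monte Carlo EI oracle,
brute-force dominance sorting on 50 random 20-point 3-objective instances,
LHS stratification counting across 200 seeds, a 1-D quadratic recovery /
regression guard (20 seeds × 20 experiments), and the end-to-end color-plate
benchmark (5 replicates × 24 experiments).

## Limitations

- GP fits are O(n³); fine for experimental campaigns (tens to a few hundred
  points), wrong tool for thousands.
- Categorical factors use independent per-category handling, not learned
  embeddings; many-category factors will be sample-hungry.
- Single-objective constraints are rejection-based — a tiny feasible region
  makes sampling slow before it fails loudly; MOO does not support
  constraints at all.
- The acquisition argmax is stochastic-start + local polish, not a global
  guarantee; 1000 candidates are ample for ≤ ~10 factors.
- CIE76 is the simplest ΔE; perceptual accuracy at large color differences
  is limited (CIEDE2000 would be a drop-in refinement of the scoring
  function, not of the optimizer).
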
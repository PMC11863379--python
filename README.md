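# labopt

Bayesian optimization for real-world experimental processes — wet-lab
campaigns, process tuning, anything where each evaluation is a physical
experiment that costs hours and money rather than microseconds of CPU.

`labopt` is built around an **ask/tell** loop: the optimizer *asks* you to run
a specific recipe, you run it (by hand, or on a robot) and *tell* it the
measured score, and it updates a Gaussian-process surrogate to decide what to
try next. Everything is **minimized**, deterministic given a seed, and
serializable, so a campaign can stretch over weeks, survive crashes, and be
replayed bit-for-bit.

What's in the box:

- **Mixed design spaces** — real, integer, and categorical factors, optional
  snapping to an equipment grid, and constraints (sum-equals, value
  exclusions/restrictions) honored by sampling and suggestion.
- **GP surrogate** — anisotropic Matérn-5/2 kernel, hyperparameters fitted by
  multi-restart marginal-likelihood maximization with analytic gradients.
- **Acquisition functions** — expected improvement (default), probability of
  improvement, lower confidence bound.
- **Batch suggestions** — constant-liar strategies (`cl_min`, `cl_mean`,
  `cl_max`) for running several experiments in parallel.
- **Analysis** — expected minimum with uncertainty, convergence traces,
  partial-dependence profiles.
- **Multi-objective** — NSGA-II (`pareto_suggest`) when several scores
  compete and the answer is a Pareto front.
- **Benchmark model systems** — a synthetic 96-well universal-pH-indicator
  color plate with pluggable noise, for testing campaign strategies in
  silico before touching a pipette.
- **A thin CLI** (`labopt init/ask/tell/report/benchmark`) that drives a
  durable on-disk session for shell-driven campaigns.

## Worked example: matching a color

The packaged benchmark emulates a colorimetric pH experiment: mix 200 µL of
an acid/base buffer (30–85 % acid) with a universal pH indicator (5–40 µL,
diluted with water to 40 µL — every well is 240 µL total), then score the
resulting color by its CIELAB distance ΔE to a target color. The target sits
exactly on one well of the 96-well plate, so the best achievable score is 0.

```python
import numpy as np
from labopt import Optimizer, build_space, expected_min
from labopt.model_systems import color_ph_system, get_score

system = color_ph_system()
space = build_space([(30, 85, "acid%"), (5, 40, "indicator µL")])
opt = Optimizer(space, n_initial_points=4, seed=7)
noise_rng = np.random.default_rng(7)

for i in range(12):
    recipe = opt.ask()
    executed = system.space.round_to_grid(recipe)   # plate wells are steps of 5
    result = opt.tell(executed, get_score(system, executed, noise_rng))

recipe, mean, std = expected_min(result)
```

Running this (it is `examples/color_matching.py`) prints:

```
run  1 [LHS]: acid   35%  indicator   30 µL  ->  ΔE =  66.67
run  2 [LHS]: acid   50%  indicator   35 µL  ->  ΔE =   7.45
run  3 [LHS]: acid   80%  indicator   15 µL  ->  ΔE =  54.09
run  4 [LHS]: acid   70%  indicator   15 µL  ->  ΔE =  50.17
...
run 12 [BO]: acid   50%  indicator   40 µL  ->  ΔE =  14.90

best observed ΔE: 7.45
expected minimum: acid 50.1%, indicator 31.1 µL (model predicts ΔE 5.40 ± 3.52)
executed (grid-rounded) recipe [50.0, 30.0] has true ΔE = 0.00
```

Note the distinction the last two lines make: the best *observed* well scored
7.45, but the surrogate's **expected minimum**, once rounded to a real plate
well, is the exact target (ΔE = 0) — the model interpolated to a well the
campaign never measured directly. That model-based readout, not the raw best
observation, is the recommended end-of-campaign answer.

The first 4 suggestions come from a Latin-hypercube design (no model yet);
from run 5 on, suggestions maximize expected improvement under the GP.

More narrative examples in `examples/`:

- `color_matching.py` — the loop above.
- `batch_suggestions.py` — asking for 3 recipes at once with constant liar.
- `multi_objective.py` — a Pareto front for two competing objectives.
- `benchmark_noise.py` — how measurement noise degrades a campaign.

## Command-line sessions

For a campaign driven from the shell, state lives in a session directory
(a YAML config plus an append-only `observations.csv`); every command
reconstructs the optimizer by replaying the log, so nothing is ever lost:

```bash
labopt init config.yaml -s ./my-campaign
labopt ask  -s ./my-campaign                 # -> next experiment: acid% = 34.6, ...
labopt tell -s ./my-campaign "35,30" 66.67
labopt ask  -s ./my-campaign --n 3           # batch of 3 (constant liar)
labopt report -s ./my-campaign               # best, expected min ± std, convergence
labopt benchmark color_ph --budget 24 --reps 5 --seed 1
```

A minimal `config.yaml`:

```yaml
dimensions:
  - {kind: real, low: 30.0, high: 85.0, name: "acid%", grid_step: 5.0}
  - {kind: real, low: 5.0, high: 40.0, name: "indicator µL", grid_step: 5.0}
n_initial_points: 4
seed: 7
```

Exit codes: 0 success, 2 validation error, 3 missing/corrupt session.

## Design notes

See `docs/methods.md` for the statistical model, the synthetic plate
generator, parameter defaults and their rationale, numerical choices, and
known limitations.
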
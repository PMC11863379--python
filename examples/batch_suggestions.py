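"""Ask for several experiments at once (batch mode).

When a plate or a parallel reactor can run several conditions per cycle,
ask_batch proposes a whole batch.  Beyond the initial design it uses the
constant-liar heuristic: each pending suggestion is temporarily imputed a
pseudo-score (the minimum observed so far for "cl_min") so later
suggestions in the batch spread out instead of piling onto one optimum.
"""

import numpy as np

from labopt import Optimizer, build_space
from labopt.model_systems import color_ph_system, get_score

system = color_ph_system()
space = build_space([(30, 85, "acid%"), (5, 40, "indicator µL")])
opt = Optimizer(space, n_initial_points=4, seed=3)
rng = np.random.default_rng(3)

# first batch: the four LHS initial experiments in one go
batch = opt.ask_batch(4)
print("initial batch:")
for recipe in batch:
    score = get_score(system, space.round_to_grid(recipe), rng)
    opt.tell(space.round_to_grid(recipe), score)
    print(f"  acid {recipe[0]:5.1f}%  indicator {recipe[1]:5.1f} µL  ->  ΔE {score:6.2f}")

# second batch: three model-driven suggestions via the constant liar
batch = opt.ask_batch(3, strategy="cl_min")
print("\nmodel-phase batch (cl_min):")
U = np.array([space.to_unit(r) for r in batch])
for recipe in batch:
    print(f"  acid {recipe[0]:5.1f}%  indicator {recipe[1]:5.1f} µL")
d_min = min(np.linalg.norm(U[i] - U[j]) for i in range(3) for j in range(i + 1, 3))
print(f"smallest pairwise distance in unit coordinates: {d_min:.3f}")
# a strictly positive distance shows the liar kept the batch diverse
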
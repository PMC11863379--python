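"""Optimize a liquid's color toward a target with an ask/tell loop.

The experiment: mix 200 µL of an acid/base buffer (30-85% acid) with a
universal pH indicator (5-40 µL, diluted to 40 µL with water) and compare
the resulting color to a target, scored by the CIELAB color difference ΔE
(0 = perfect match).  Here the "experiment" is the packaged synthetic
96-well plate, so the loop runs instantly; in the lab, get_score would be a
pipetting robot or a chemist.
"""

import numpy as np

from labopt import Optimizer, build_space, convergence_trace, expected_min
from labopt.model_systems import color_ph_system, get_score

system = color_ph_system()
space = build_space([(30, 85, "acid%"), (5, 40, "indicator µL")])
opt = Optimizer(space, n_initial_points=4, seed=7)
noise_rng = np.random.default_rng(7)

result = None
for i in range(12):
    recipe = opt.ask()
    # the plate only has wells at multiples of 5, so execute the rounded recipe
    executed = system.space.round_to_grid(recipe)
    score = get_score(system, executed, noise_rng)
    result = opt.tell(executed, score)
    phase = "LHS" if i < 4 else "BO"
    print(f"run {i + 1:2d} [{phase}]: acid {executed[0]:4.0f}%  "
          f"indicator {executed[1]:4.0f} µL  ->  ΔE = {score:6.2f}")

recipe, mean, std = expected_min(result)
rounded = system.space.round_to_grid(recipe)
true_de = system.truth(rounded)
print(f"\nbest observed ΔE: {result.best_y:.2f}")
print(f"expected minimum: acid {recipe[0]:.1f}%, indicator {recipe[1]:.1f} µL "
      f"(model predicts ΔE {mean:.2f} ± {std:.2f})")
print(f"executed (grid-rounded) recipe {rounded} has true ΔE = {true_de:.2f}")
print("convergence:", np.round(convergence_trace(result), 2))
# ΔE = 0 at the rounded expected minimum means the campaign found the exact
# target well of the plate.
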
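"""Trade off two competing objectives with NSGA-II.

A toy bi-objective problem with a known answer: minimize both x² and
(x - 1)² over x in [-1, 2].  The true Pareto set is exactly x in [0, 1]
(any x outside it is worse on both counts), so we can see directly whether
the evolved front landed where it should.
"""

import numpy as np

from labopt import build_space, pareto_suggest
from labopt.moo import front_to_frame

space = build_space([(-1.0, 2.0, "x")])


def objectives(recipe):
    x = recipe[0]
    return [x**2, (x - 1.0) ** 2]


front = pareto_suggest(
    objectives, space, pop_size=40, generations=50, rng=np.random.default_rng(0)
)

xs = np.sort([ind.x[0] for ind in front])
inside = np.mean((xs >= -0.02) & (xs <= 1.02))
print(f"front size: {len(front)}")
print(f"x range of the front: [{xs.min():.3f}, {xs.max():.3f}]")
print(f"fraction inside the true Pareto set [0, 1] (±0.02): {inside:.0%}")
print("\nfirst few trade-offs (both objectives minimized):")
print(front_to_frame(front, space).sort_values("x").head(8).to_string(index=False))
# each row is a non-dominated compromise: smaller objective_0 (near x=0)
# necessarily means larger objective_1 (distance from x=1), and vice versa.
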
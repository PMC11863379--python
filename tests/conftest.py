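import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from labopt import Optimizer, build_space
from labopt.model_systems import color_ph_space, color_ph_system, synth_color_grid

settings.register_profile(
    "suite",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def color_space():
    """The two-factor color experiment space (acid 30-85%, indicator 5-40 µL)."""
    return color_ph_space()


@pytest.fixture(scope="session")
def color_grid():
    return synth_color_grid()


@pytest.fixture(scope="session")
def color_system(color_grid):
    return color_ph_system(grid=color_grid)


@pytest.fixture(scope="session")
def quadratic_result():
    """Optimizer result on the noiseless 1-D quadratic (x - 0.3)^2 after 12
    LHS observations — a cheap, well-conditioned fitted model for analyses."""
    space = build_space([(0.0, 1.0, "x")])
    opt = Optimizer(space, n_initial_points=12, seed=2)
    result = None
    for _ in range(12):
        x = opt.ask()
        result = opt.tell(x, (x[0] - 0.3) ** 2)
    return result


def stratum_counts(space, points, n):
    """Per-numeric-dimension occupancy of the n equal LHS strata."""
    counts = []
    for j, d in enumerate(space.dims):
        if d.kind == "categorical":
            continue
        u = np.array([(p[j] - d.low) / (d.high - d.low) for p in points])
        bins = np.clip((u * n).astype(int), 0, n - 1)
        counts.append(np.bincount(bins, minlength=n))
    return counts
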
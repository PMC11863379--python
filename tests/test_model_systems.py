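import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from labopt import ValidationError
from labopt.model_systems import (
    ACID_LEVELS,
    DEFAULT_TARGET_WELL,
    INDICATOR_LEVELS,
    ColorGrid,
    LabColor,
    ModelSystem,
    NoiseSpec,
    color_ph_score,
    color_ph_space,
    color_ph_system,
    delta_e,
    get_score,
    recipe_volume,
    run_benchmark,
    synth_color_grid,
)

lab = st.builds(
    LabColor,
    st.floats(0, 100),
    st.floats(-100, 100),
    st.floats(-100, 100),
)


class TestDeltaE:
    def test_identity(self):
        c = LabColor(50, 10, -20)
        assert delta_e(c, c) == 0.0

    def test_known_345_triangle(self):
        assert delta_e(LabColor(0, 0, 0), LabColor(3, 4, 0)) == pytest.approx(5.0)

    @given(lab, lab)
    def test_symmetry(self, c1, c2):
        assert delta_e(c1, c2) == delta_e(c2, c1)

    @given(lab, lab, lab)
    def test_triangle_inequality(self, a, b, c):
        assert delta_e(a, c) <= delta_e(a, b) + delta_e(b, c) + 1e-9

    @pytest.mark.parametrize("bad", [(np.nan, 0, 0), (np.inf, 0, 0), (-1, 0, 0), (101, 0, 0)])
    def test_invalid_lab_rejected(self, bad):
        with pytest.raises(ValidationError):
            LabColor(*bad)


class TestSynthGrid:
    def test_full_plate(self, color_grid):
        assert color_grid.n_wells == 96
        assert len(color_grid.acid_levels) == 12
        assert len(color_grid.indicator_levels) == 8

    def test_unique_zero_at_target_well(self, color_grid):
        scores = {
            well: delta_e(c, color_grid.target) for well, c in color_grid.colors.items()
        }
        assert scores[DEFAULT_TARGET_WELL] == 0.0
        others = [v for w, v in scores.items() if w != DEFAULT_TARGET_WELL]
        assert min(others) > 1.0  # the optimum is isolated, not a plateau

    def test_score_surface_is_smooth(self, color_grid):
        """Adjacent wells should differ far less than opposite plate corners;
        a smooth landscape is what makes GP optimization meaningful here."""
        def color(i, j):
            return color_grid.colors[(ACID_LEVELS[i], INDICATOR_LEVELS[j])]

        adjacent = []
        for i in range(12):
            for j in range(8):
                if i + 1 < 12:
                    adjacent.append(delta_e(color(i, j), color(i + 1, j)))
                if j + 1 < 8:
                    adjacent.append(delta_e(color(i, j), color(i, j + 1)))
        corner = delta_e(color(0, 7), color(11, 7))
        assert max(adjacent) < corner

    def test_bitwise_deterministic(self):
        g1, g2 = synth_color_grid(), synth_color_grid()
        for well in g1.colors:
            assert g1.colors[well] == g2.colors[well]

    def test_more_acid_means_lower_ph_redder_hue(self, color_grid):
        # at full indicator volume, a* (green-red axis) should be higher at
        # 85% acid (pH ~ 3, red) than at 30% acid (pH ~ 11, violet side of
        # the palette has lower chroma after scaling)
        low_acid = color_grid.colors[(30, 40)]
        high_acid = color_grid.colors[(85, 40)]
        assert high_acid.a > 0  # red end
        assert high_acid.b > low_acid.b  # red/yellow end is more positive-b

    def test_non_monotone_palette_rejected(self):
        with pytest.raises(ValidationError):
            synth_color_grid(
                palette=(
                    (3.0, (55, 70, 50)),
                    (5.0, (70, 40, 65)),
                    (4.0, (90, -10, 85)),
                    (11.0, (35, 45, -40)),
                )
            )

    def test_off_grid_target_well_rejected(self):
        with pytest.raises(ValidationError):
            synth_color_grid(target_well=(52, 30))

    def test_csv_roundtrip(self, color_grid, tmp_path):
        path = tmp_path / "plate.csv"
        color_grid.to_csv(path)
        loaded = ColorGrid.from_csv(path)
        assert loaded.n_wells == 96
        assert loaded.optimum_well == DEFAULT_TARGET_WELL
        for well, c in color_grid.colors.items():
            assert delta_e(c, loaded.colors[well]) < 1e-9

    def test_grid_with_wrong_well_count_rejected(self, color_grid):
        colors = dict(color_grid.colors)
        colors.pop((30, 5))
        with pytest.raises(ValidationError):
            ColorGrid(
                acid_levels=color_grid.acid_levels,
                indicator_levels=color_grid.indicator_levels,
                colors=colors,
                target=color_grid.target,
                optimum_well=color_grid.optimum_well,
            )


class TestRecipeVolume:
    def test_always_240(self):
        for indicator in INDICATOR_LEVELS:
            assert recipe_volume([50.0, float(indicator)]) == 240.0

    def test_overfull_indicator_rejected(self):
        with pytest.raises(ValidationError):
            recipe_volume([50.0, 45.0])


class TestColorPhScore:
    def test_target_recipe_scores_zero(self, color_grid):
        assert color_ph_score(color_grid, [50, 30]) == 0.0

    def test_rounding_to_plate_wells(self, color_grid):
        # 79% acid is executed as the 80% well; 36 µL as the 35 µL well
        assert color_ph_score(color_grid, [79, 36]) == color_ph_score(
            color_grid, [80, 35]
        )
        assert color_ph_score(color_grid, [79, 36]) > 0

    def test_out_of_bounds_recipe_rejected(self, color_grid):
        with pytest.raises(ValidationError):
            color_ph_score(color_grid, [95, 30])

    def test_full_grid_scan_has_single_zero(self, color_grid):
        zeros = [
            (a, v)
            for a in ACID_LEVELS
            for v in INDICATOR_LEVELS
            if color_ph_score(color_grid, [a, v]) == 0.0
        ]
        assert zeros == [DEFAULT_TARGET_WELL]


class TestNoise:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            NoiseSpec(kind="uniform")
        with pytest.raises(ValidationError):
            NoiseSpec(kind="constant", size=-1.0)
        with pytest.raises(ValidationError):
            NoiseSpec(kind="zero", size=0.5)

    def test_zero_noise_is_exact(self, color_system):
        rng = np.random.default_rng(0)
        assert get_score(color_system, [50, 30], rng) == 0.0
        assert get_score(color_system, [50, 30], rng) == 0.0

    def test_constant_noise_moments(self, color_grid):
        system = color_ph_system(noise=NoiseSpec("constant", 2.0), grid=color_grid)
        rng = np.random.default_rng(42)
        draws = np.array([get_score(system, [50, 30], rng) for _ in range(10_000)])
        assert abs(draws.mean()) < 0.05  # truth is 0, so pure noise
        assert 0.93 * 2.0 <= draws.std() <= 1.07 * 2.0

    def test_proportional_noise_vanishes_at_the_optimum(self, color_grid):
        system = color_ph_system(noise=NoiseSpec("proportional", 0.1), grid=color_grid)
        rng = np.random.default_rng(3)
        assert get_score(system, [50, 30], rng) == 0.0

    def test_proportional_noise_scales_with_truth(self, color_grid):
        system = color_ph_system(noise=NoiseSpec("proportional", 0.1), grid=color_grid)
        truth = color_ph_score(color_grid, [85, 5])
        rng = np.random.default_rng(7)
        draws = np.array([get_score(system, [85, 5], rng) for _ in range(5_000)])
        assert (draws - truth).std() == pytest.approx(0.1 * truth, rel=0.1)


@pytest.fixture(scope="module")
def summary(color_system):
    return run_benchmark(color_system, budget=8, n_reps=2, master_seed=3)


class TestRunBenchmark:

    def test_trace_shape_and_monotonicity(self, summary):
        assert summary.traces.shape == (2, 8)
        assert np.all(np.diff(summary.traces, axis=1) <= 0)

    def test_final_best_matches_trace(self, summary):
        np.testing.assert_array_equal(summary.final_best, summary.traces[:, -1])

    def test_true_at_expected_min_recorded(self, summary):
        assert summary.true_at_expected_min.shape == (2,)
        assert np.all(summary.true_at_expected_min >= 0)
        assert summary.median_true_at_expected_min is not None
        agg = summary.aggregate()
        assert set(agg) == {
            "median_final_best",
            "iqr_final_best",
            "median_true_at_expected_min",
            "iqr_true_at_expected_min",
        }

    def test_traces_frame_layout(self, summary):
        df = summary.traces_frame()
        assert list(df.columns) == ["replicate", "iteration", "best_so_far"]
        assert len(df) == 16

    def test_deterministic(self, color_system, summary):
        again = run_benchmark(color_system, budget=8, n_reps=2, master_seed=3)
        np.testing.assert_array_equal(again.traces, summary.traces)

    def test_invalid_budget_rejected(self, color_system):
        with pytest.raises(ValidationError):
            run_benchmark(color_system, budget=3, n_reps=1, n_initial_points=4)
        with pytest.raises(ValidationError):
            run_benchmark(color_system, budget=8, n_reps=0)

    def test_unknown_min_skips_truth_column(self):
        space = color_ph_space()
        system = ModelSystem(
            truth=lambda r: (r[0] - 50) ** 2 + (r[1] - 30) ** 2,
            space=space,
            name="quadratic",
        )
        summary = run_benchmark(system, budget=6, n_reps=1, master_seed=2)
        assert summary.true_at_expected_min is None
        assert summary.median_true_at_expected_min is None
        assert "median_true_at_expected_min" not in summary.aggregate()
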
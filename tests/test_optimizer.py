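import numpy as np
import pytest
from hypothesis import given, strategies as st

from labopt import (
    Optimizer,
    ValidationError,
    build_space,
    convergence_trace,
    expected_min,
    partial_dependence,
)
from labopt.acquisition import acquisition_values
from labopt.optimizer import OptResult, ObservationRecord
from tests.conftest import stratum_counts


def _color_opt(seed=0, n_initial_points=4):
    space = build_space([(30, 85, "acid%"), (5, 40, "indicator µL")])
    return Optimizer(space, n_initial_points=n_initial_points, seed=seed)


class TestCreation:
    def test_initial_queue_is_lhs_no_model(self):
        opt = _color_opt(seed=1)
        assert len(opt._initial_queue) == 4
        assert opt.models == []
        for counts in stratum_counts(opt.space, opt._initial_queue, 4):
            assert np.all(counts == 1)

    def test_zero_initial_points_rejected(self):
        with pytest.raises(ValidationError):
            _color_opt(n_initial_points=0)

    def test_same_seed_same_queue(self):
        assert _color_opt(seed=5)._initial_queue == _color_opt(seed=5)._initial_queue


class TestAskTell:
    def test_initial_asks_served_without_surrogate(self):
        opt = _color_opt(seed=2)
        for i in range(4):
            x = opt.ask()
            assert opt.models == [], f"model fitted before initial design done (ask {i})"
            opt.tell(x, float(i))
        assert len(opt.models) == 1  # first fit after the 4th observation

    def test_ask_idempotent_until_tell(self):
        opt = _color_opt(seed=3)
        assert opt.ask() == opt.ask()
        opt.tell(opt.ask(), 1.0)
        first_model_phase = None
        for i in range(3):
            opt.tell(opt.ask(), float(i))
        assert opt.ask() == opt.ask()  # model-phase idempotence

    def test_model_phase_suggestion_is_acquisition_optimal(self):
        opt = _color_opt(seed=4)
        for i, y in enumerate([50.8, 30.0, 40.0, 25.0]):
            opt.tell(opt.ask(), y)
        suggestion = opt.ask()
        model = opt.models[-1]
        a_sugg = acquisition_values(
            opt.acq, model, np.array([opt.space.to_unit(suggestion)])
        )[0]
        dense = opt.space.to_unit_many(opt.space.sample(1000, np.random.default_rng(99)))
        assert a_sugg >= acquisition_values(opt.acq, model, dense).max() - 1e-6

    def test_first_tell_sets_best(self):
        opt = _color_opt()
        result = opt.tell([80, 35], 50.8)
        assert len(result.observations) == 1
        assert result.best_y == 50.8
        assert result.best_x == [80.0, 35.0]

    def test_running_minimum(self):
        opt = _color_opt()
        opt.tell([80, 35], 50.8)
        r = opt.tell([45, 20], 30.0)
        assert r.best_y == 30.0
        r = opt.tell([60, 10], 40.0)
        assert r.best_y == 30.0  # worse tell leaves the incumbent

    def test_invalid_tells_rejected(self):
        opt = _color_opt()
        with pytest.raises(ValidationError):
            opt.tell([200, 35], 1.0)
        with pytest.raises(ValidationError):
            opt.tell([50, 20], np.inf)

    def test_replay_reproduces_suggestions(self):
        def run(seed):
            opt = _color_opt(seed=seed)
            seq = []
            for y in [50.8, 30.0, 40.0, 25.0, 20.0, 18.0]:
                x = opt.ask()
                seq.append(x)
                opt.tell(x, y)
            return seq

        assert run(7) == run(7)


class TestAskBatch:
    def test_batch_of_one_equals_ask(self):
        o1, o2 = _color_opt(seed=9), _color_opt(seed=9)
        for k in range(6):
            x1, (x2,) = o1.ask(), o2.ask_batch(1)
            assert x1 == x2
            o1.tell(x1, float(k))
            o2.tell(x2, float(k))

    def test_batch_points_distinct_over_seeds(self):
        for seed in range(20):
            opt = _color_opt(seed=seed)
            for i in range(4):
                x = opt.ask()
                opt.tell(x, float((x[0] - 50) ** 2 + (x[1] - 30) ** 2))
            batch = opt.ask_batch(3)
            U = opt.space.to_unit_many(batch)
            for i in range(3):
                for j in range(i + 1, 3):
                    assert np.linalg.norm(U[i] - U[j]) > 0

    def test_no_side_effects(self):
        opt = _color_opt(seed=11)
        for i in range(4):
            opt.tell(opt.ask(), float(i))
        before = [o.x for o in opt.observations]
        n_models = len(opt.models)
        opt.ask_batch(3)
        assert [o.x for o in opt.observations] == before
        assert len(opt.models) == n_models

    def test_invalid_batch_requests(self):
        opt = _color_opt()
        with pytest.raises(ValidationError):
            opt.ask_batch(0)
        with pytest.raises(ValidationError):
            opt.ask_batch(2, strategy="cl_median")


class TestExpectedMin:
    def test_quadratic_toy_recovery(self, quadratic_result):
        recipe, mean, std = expected_min(quadratic_result)
        assert abs(recipe[0] - 0.3) < 0.05
        assert abs(mean) < 0.01
        assert std >= 0

    def test_minimality_over_observed_points(self, quadratic_result):
        _, mean, _ = expected_min(quadratic_result)
        model = quadratic_result.model
        U = quadratic_result.space.to_unit_many(
            [o.x for o in quadratic_result.observations]
        )
        assert mean <= model.predict(U, return_std=False).min() + 1e-9

    def test_include_noise_widens_std(self, quadratic_result):
        _, _, s0 = expected_min(quadratic_result, include_noise=False)
        _, _, s1 = expected_min(quadratic_result, include_noise=True)
        assert s1 >= s0

    def test_requires_model(self):
        opt = _color_opt()
        result = opt.tell([50, 20], 1.0)
        with pytest.raises(ValidationError):
            expected_min(result)


class TestConvergenceTrace:
    def test_worked_sequence(self):
        opt = _color_opt()
        for y in [50.8, 30.0, 40.0]:
            result = opt.tell(opt.ask(), y)
        np.testing.assert_array_equal(convergence_trace(result), [50.8, 30.0, 30.0])

    def test_single_observation(self):
        opt = _color_opt()
        result = opt.tell([50, 20], 3.0)
        assert convergence_trace(result).tolist() == [3.0]

    def test_empty_rejected(self):
        result = OptResult(space=_color_opt().space, observations=[])
        with pytest.raises(ValidationError):
            convergence_trace(result)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_nonincreasing_for_any_sequence(self, ys):
        space = build_space([(0.0, 1.0, "x")])
        result = OptResult(
            space=space,
            observations=[ObservationRecord([0.5], y, "manual") for y in ys],
        )
        trace = convergence_trace(result)
        assert len(trace) == len(ys)
        assert np.all(np.diff(trace) <= 0)


class TestPartialDependence:
    def _fit(self, f, seed=3, n=30):
        space = build_space([(0.0, 1.0, "x1"), (0.0, 1.0, "x2")])
        opt = Optimizer(space, n_initial_points=n, seed=seed)
        result = None
        for _ in range(n):
            x = opt.ask()
            result = opt.tell(x, f(x))
        return result

    def test_constant_response_gives_flat_profile(self):
        result = self._fit(lambda x: 4.2)
        pdp = partial_dependence(result, "x1", grid_size=15)
        assert np.ptp(pdp.mean) < 1e-6

    def test_additive_truth_recovered(self):
        f = lambda x: (x[0] - 0.3) ** 2 + 0.5 * np.sin(6 * x[1])
        result = self._fit(f)
        pdp = partial_dependence(result, "x1", grid_size=20, n_background=40)
        truth = (np.asarray(pdp.grid[0], dtype=float) - 0.3) ** 2
        assert np.corrcoef(pdp.mean, truth)[0, 1] > 0.95

    def test_output_shapes(self):
        result = self._fit(lambda x: x[0] + x[1], n=12)
        pdp1 = partial_dependence(result, "x1", grid_size=7)
        assert pdp1.mean.shape == (7,)
        pdp2 = partial_dependence(result, ["x1", "x2"], grid_size=5)
        assert pdp2.mean.shape == (5, 5)
        assert len(pdp2.to_frame()) == 25

    def test_unknown_dimension_rejected(self):
        result = self._fit(lambda x: x[0], n=12)
        with pytest.raises(ValidationError):
            partial_dependence(result, "nope")


class TestRegressionGuard:
    def test_quadratic_toy_budget_20(self):
        """On the noiseless 1-D quadratic, a 20-experiment run should hit
        y <= 0.01 in at least 18 of 20 seeds."""
        space = build_space([(0.0, 1.0, "x")])
        wins = 0
        for seed in range(20):
            opt = Optimizer(space, n_initial_points=4, seed=seed)
            best = np.inf
            for _ in range(20):
                x = opt.ask()
                y = (x[0] - 0.3) ** 2
                opt.tell(x, y)
                best = min(best, y)
            wins += best <= 0.01
        assert wins >= 18


def test_result_json_roundtrip(tmp_path, quadratic_result):
    path = tmp_path / "result.json"
    quadratic_result.to_json(path)
    loaded = OptResult.from_json(path)
    assert loaded.best_y == quadratic_result.best_y
    assert loaded.best_x == quadratic_result.best_x
    assert [o.x for o in loaded.observations] == [
        o.x for o in quadratic_result.observations
    ]
    U = np.array([[0.25], [0.75]])
    np.testing.assert_allclose(
        loaded.model.predict(U, return_std=False),
        quadratic_result.model.predict(U, return_std=False),
        atol=1e-10,
    )


def test_observations_frame_layout(quadratic_result):
    df = quadratic_result.observations_frame()
    assert list(df.columns) == ["iteration", "x", "score", "origin"]
    assert len(df) == 12
    assert set(df["origin"]) == {"initial"}
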
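"""CMA-ES maximizer: initialization, sampling, updates, stopping, convergence."""

import numpy as np
import pytest

from stepcal.cmaes import (
    ParameterSpec,
    SearchSpec,
    default_population_size,
    init_state,
    maximize,
    sample_generation,
    should_stop,
    update,
)
from stepcal.errors import ConfigurationError


def spec_1d(seed=0, **kw):
    return SearchSpec([ParameterSpec("x", 0.0, 10.0, initial_guess=5.0)], seed=seed, **kw)


class TestPopulationRule:
    @pytest.mark.parametrize("d,expected", [(1, 4), (2, 6), (14, 11)])
    def test_values(self, d, expected):
        assert default_population_size(d) == expected

    def test_rejects_nonpositive_dimension(self):
        with pytest.raises(ConfigurationError):
            default_population_size(0)


class TestInitState:
    def test_initial_std_is_half_interval_width(self):
        state = init_state(spec_1d())
        # normalized coordinates: half of the unit interval
        assert np.sqrt(state.C[0, 0]) == pytest.approx(0.5)
        assert state.mean[0] == pytest.approx(0.5)  # guess 5 in [0, 10]
        assert state.sigma == 1.0
        assert state.generation == 0
        assert np.all(state.p_sigma == 0) and np.all(state.p_c == 0)

    def test_explicit_std_override_in_raw_units(self):
        # start (-2, 1) with per-axis std 0.5 over a 4 x 2 box
        params = [
            ParameterSpec("x1", -2.0, 2.0, initial_guess=-2.0, init_std=0.5),
            ParameterSpec("x2", -1.0, 1.0, initial_guess=1.0, init_std=0.5),
        ]
        state = init_state(SearchSpec(params))
        assert np.sqrt(state.C[0, 0]) == pytest.approx(0.5 / 4.0)
        assert np.sqrt(state.C[1, 1]) == pytest.approx(0.5 / 2.0)
        spec = SearchSpec(params)
        assert spec.to_raw(state.mean) == pytest.approx([-2.0, 1.0])

    def test_frozen_parameters_are_excluded_from_dimension(self):
        spec = SearchSpec(
            [
                ParameterSpec("a", 0.0, 1.0),
                ParameterSpec("b", 2.0, 2.0),  # degenerate -> frozen
            ]
        )
        assert spec.dimension == 1

    def test_all_frozen_is_an_error(self):
        spec = SearchSpec([ParameterSpec("a", 1.0, 1.0)])
        with pytest.raises(ConfigurationError):
            init_state(spec)


class TestSampling:
    def test_samples_respect_bounds_and_seed(self):
        spec = spec_1d(population_size=20)
        state = init_state(spec)
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        s1 = sample_generation(state, spec, rng1)
        s2 = sample_generation(state, spec, rng2)
        assert s1.shape == (20, 1)
        assert np.array_equal(s1, s2)
        assert np.all((s1 >= 0.0) & (s1 <= 1.0))

    def test_zero_sigma_limit_collapses_to_mean(self):
        spec = spec_1d(population_size=5)
        state = init_state(spec)
        state.sigma = 1e-300
        samples = sample_generation(state, spec, np.random.default_rng(0))
        assert np.allclose(samples, state.mean, atol=1e-12)

    def test_covariance_repair_floors_eigenvalues(self):
        spec = spec_1d(population_size=4)
        state = init_state(spec)
        state.C = np.array([[-1.0]])  # broken covariance
        samples = sample_generation(state, spec, np.random.default_rng(0))
        assert np.all(np.isfinite(samples))


class TestUpdate:
    def test_equal_objectives_tie_break_is_deterministic(self):
        spec = spec_1d(population_size=6)
        state = init_state(spec)
        cands = sample_generation(state, spec, np.random.default_rng(1))
        new1 = update(state, spec, cands, [0.5] * 6)
        new2 = update(state, spec, cands, [0.5] * 6)
        assert np.array_equal(new1.mean, new2.mean)
        assert new1.generation == 1
        assert np.all(np.isfinite(new1.C))

    def test_non_finite_objective_is_demoted_to_worst(self):
        spec = spec_1d(population_size=4)
        state = init_state(spec)
        cands = sample_generation(state, spec, np.random.default_rng(1))
        values = [0.2, np.nan, 0.9, np.inf]
        new = update(state, spec, cands, values)
        # best_so_far must come from the finite 0.9 candidate
        assert new.best_so_far[1] == pytest.approx(0.9)

    def test_best_so_far_monotone_nondecreasing(self):
        spec = spec_1d(population_size=8)
        state = init_state(spec)
        rng = np.random.default_rng(3)
        best_values = []
        for _ in range(20):
            cands = sample_generation(state, spec, rng)
            vals = [-((spec.to_raw(z)[0] - 7.0) ** 2) for z in cands]
            state = update(state, spec, cands, vals)
            best_values.append(state.best_so_far[1])
        assert np.all(np.diff(best_values) >= 0)


class TestShouldStop:
    def test_threshold(self):
        spec = spec_1d(stop_threshold=0.99)
        state = init_state(spec)
        state.best_so_far = (np.array([5.0]), 0.995)
        assert should_stop(state, [0.5, 0.995], spec) == "threshold"

    def test_stagnation_on_flat_history(self):
        spec = spec_1d(stagnation_window=5, stagnation_tol=1e-6, stop_threshold=1.0)
        state = init_state(spec)
        state.generation = 10
        state.best_so_far = (np.array([5.0]), 0.4)
        assert should_stop(state, [0.4] * 10, spec) == "stagnation"

    def test_generation_zero_continues(self):
        spec = spec_1d()
        state = init_state(spec)
        assert should_stop(state, [], spec) is None

    def test_budget(self):
        spec = spec_1d(max_generations=3, stop_threshold=1.0, stagnation_window=100)
        state = init_state(spec)
        state.generation = 3
        state.best_so_far = (np.array([5.0]), 0.2)
        assert should_stop(state, [0.1, 0.15, 0.2], spec) == "budget"


class TestMaximize:
    def test_recovers_1d_quadratic_maximum(self):
        target = 7.3

        def f(x):
            return 1.0 - (x[0] - target) ** 2 / 100.0

        spec = spec_1d(max_generations=200, stop_threshold=1.0, stagnation_tol=1e-12)
        result = maximize(f, spec)
        assert result.best_params[0] == pytest.approx(target, abs=1e-3)

    def test_recovers_2d_rescaled_quadratic_argmax(self):
        # anisotropic parabola with known maximum at (3, -40)
        params = [
            ParameterSpec("a", 0.0, 10.0, initial_guess=8.0),
            ParameterSpec("b", -100.0, 100.0, initial_guess=50.0),
        ]

        def f(x):
            return 1.0 - ((x[0] - 3.0) ** 2 / 100.0 + (x[1] + 40.0) ** 2 / 40000.0)

        spec = SearchSpec(params, max_generations=400, stop_threshold=1.0,
                          stagnation_tol=1e-14, stagnation_window=60, seed=5)
        result = maximize(f, spec)
        assert result.best_params[0] == pytest.approx(3.0, abs=1e-2)
        assert result.best_params[1] == pytest.approx(-40.0, abs=0.5)

    @pytest.mark.parametrize("d", [2, 5])
    def test_sphere_function_reaches_origin(self, d):
        params = [
            ParameterSpec(f"x{i}", -5.0, 5.0, initial_guess=4.0) for i in range(d)
        ]

        def f(x):
            return 1.0 - float(np.sum(np.asarray(x) ** 2)) / (25.0 * d)

        spec = SearchSpec(params, max_generations=500, stop_threshold=1.0,
                          stagnation_tol=1e-14, stagnation_window=80, seed=11)
        result = maximize(f, spec)
        assert np.linalg.norm(result.best_params) < 1e-3 * np.sqrt(25.0 * d)

    def test_constant_objective_stops_by_stagnation(self):
        spec = spec_1d(stagnation_window=5, max_generations=100)
        result = maximize(lambda x: 0.5, spec)
        assert result.stop_reason == "stagnation"

    def test_raising_objective_scores_zero_and_continues(self):
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("integration failed")
            return 1.0 - (x[0] - 5.0) ** 2 / 100.0

        spec = spec_1d(max_generations=30, stagnation_window=10)
        result = maximize(f, spec)
        assert result.best_value > 0.9

    def test_bit_reproducible_under_fixed_seed(self):
        def f(x):
            return 1.0 - (x[0] - 2.0) ** 2 / 100.0

        spec_a = spec_1d(seed=42, max_generations=50)
        spec_b = spec_1d(seed=42, max_generations=50)
        ra, rb = maximize(f, spec_a), maximize(f, spec_b)
        assert np.array_equal(ra.best_params, rb.best_params)
        assert ra.history.equals(rb.history)
        assert ra.best_value == rb.best_value

    def test_history_columns(self):
        result = maximize(lambda x: 0.5, spec_1d(stagnation_window=3))
        assert list(result.history.columns) == [
            "generation",
            "best",
            "worst",
            "mean",
            "best_so_far",
        ]
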
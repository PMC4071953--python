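"""Objective construction, global/local fitting and reproducibility."""

import numpy as np
import pytest

from mdximmune import SimulationSettings, mdx_parameters
from mdximmune.calibration import (FREE_PARAMETERS, FitResult, ObservationSet,
                                   default_bounds, fit_global, fit_local,
                                   minimize_global, minimize_local, objective,
                                   read_observations, write_observations)
from mdximmune.synthetic import generate_observations

FIT_CFG = SimulationSettings(t_end=12.0, output_step=0.5,
                             rel_tol=1e-6, abs_tol=1e-8)


@pytest.fixture(scope="module")
def clean_obs(mdx):
    return generate_observations(mdx, count_cv=0.0, percent_sd=0.0, seed=0)


@pytest.fixture(scope="module")
def noisy_obs(mdx):
    return generate_observations(mdx, count_cv=0.2, percent_sd=3.0, seed=11)


class TestObjective:
    def test_zero_at_generating_parameters(self, mdx, clean_obs):
        assert objective(mdx, clean_obs, cfg=FIT_CFG) < 1e-8

    def test_constant_offset_arithmetic(self, mdx):
        """Observed = simulated + 1 at n points, unnormalized -> SSE = n."""
        p = mdx.with_values(h=0.0, C0=0.0)  # N constant at 100
        times = np.arange(2.0, 13.0)
        obs = [ObservationSet("const", "N", times, np.full(times.size, 101.0))]
        assert objective(p, obs, cfg=FIT_CFG, normalize=False) == pytest.approx(
            times.size, rel=1e-6)

    def test_noise_lifts_objective_above_clean_floor(self, mdx, clean_obs, noisy_obs):
        clean = objective(mdx, clean_obs, cfg=FIT_CFG)
        noisy = objective(mdx, noisy_obs, cfg=FIT_CFG)
        assert noisy > clean + 0.1

    def test_single_parameter_perturbations_raise_objective(self, mdx, clean_obs):
        """Local identifiability smoke test for the sensitive rates."""
        base = objective(mdx, clean_obs, cfg=FIT_CFG)
        for name in ("k1", "k2", "k4", "k5"):
            bumped = mdx.with_values(**{name: 1.1 * getattr(mdx, name)})
            assert objective(bumped, clean_obs, cfg=FIT_CFG) > base

    def test_weight_scales_dataset_contribution(self, mdx, noisy_obs):
        doubled = [ObservationSet(o.dataset_id, o.variable, o.times, o.values,
                                  weight=2.0) for o in noisy_obs]
        assert objective(mdx, doubled, cfg=FIT_CFG) == pytest.approx(
            2 * objective(mdx, noisy_obs, cfg=FIT_CFG), rel=1e-9)


class TestOptimizers:
    def test_global_recovers_quadratic_minimum(self):
        center = np.array([0.3, 0.6, 0.2])
        func = lambda x: float(np.sum((x - center) ** 2))
        x, fval, n_evals, _ = minimize_global(func, [(0, 1)] * 3, seed=3, budget=4000)
        assert np.all(np.abs(x - center) / center < 0.05)
        assert n_evals <= 4000

    def test_global_budget_zero_returns_sample_best(self):
        func = lambda x: float(np.sum(x ** 2))
        x, fval, n_evals, converged = minimize_global(func, [(-1, 1)] * 2,
                                                      seed=0, budget=0)
        assert not converged
        assert fval >= 0

    def test_local_never_worse_than_start(self):
        func = lambda x: float((x[0] - 0.5) ** 2)
        x, fval, _ = minimize_local(func, np.array([0.9]), [(0, 1)])
        assert fval <= func(np.array([0.9]))
        assert x[0] == pytest.approx(0.5, abs=1e-4)


class TestFitting:
    def test_fit_global_is_seed_deterministic(self, mdx, noisy_obs):
        a = fit_global(noisy_obs, seed=5, budget=60, cfg=FIT_CFG)
        b = fit_global(noisy_obs, seed=5, budget=60, cfg=FIT_CFG)
        assert a.parameters == b.parameters
        assert a.objective_value == b.objective_value
        c = fit_global(noisy_obs, seed=6, budget=60, cfg=FIT_CFG)
        assert c.parameters != a.parameters

    def test_fit_results_respect_bounds(self, mdx, noisy_obs):
        bounds = default_bounds(mdx)
        res = fit_global(noisy_obs, bounds=bounds, seed=2, budget=120, cfg=FIT_CFG)
        est = res.parameters.to_dict()
        for name in FREE_PARAMETERS:
            lo, hi = bounds[name]
            assert lo - 1e-12 <= est[name] <= hi + 1e-12

    def test_local_stage_descends_from_perturbed_start(self, mdx, clean_obs):
        start = mdx.with_values(k4=1.1 * mdx.k4, k2=0.9 * mdx.k2)
        f0 = objective(start, clean_obs, cfg=FIT_CFG)
        res = fit_local(start, clean_obs, cfg=FIT_CFG, max_evals=600)
        assert res.objective_value < f0

    def test_local_stage_fixed_at_exact_optimum(self, mdx, clean_obs):
        res = fit_local(mdx, clean_obs, cfg=FIT_CFG, max_evals=300)
        assert res.objective_value <= objective(mdx, clean_obs, cfg=FIT_CFG) + 1e-12
        assert res.parameters.to_dict()["k4"] == pytest.approx(mdx.k4, rel=0.01)

    def test_fit_result_json_round_trip(self, mdx, tmp_path):
        res = FitResult(parameters=mdx, objective_value=1.5, n_evaluations=10,
                        seed=3, converged=False, residuals={"a": 0.5})
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = FitResult.from_json(path)
        assert back == res


class TestObservationIO:
    def test_csv_round_trip_converts_days_to_weeks(self, mdx, noisy_obs, tmp_path):
        path = tmp_path / "obs.csv"
        write_observations(noisy_obs, path)
        back = read_observations(path)
        assert len(back) == len(noisy_obs)
        for a, b in zip(noisy_obs, back):
            assert a.dataset_id == b.dataset_id and a.variable == b.variable
            np.testing.assert_allclose(a.times, b.times, rtol=1e-12)
            np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ObservationSet("x", "N", np.array([1.0, 2.0]), np.array([1.0]))
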
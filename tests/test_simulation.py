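"""Integration, trajectory summaries and regime classification."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from mdximmune import (SimulationSettings, Trajectory, classify_mode,
                       integrate, peak_value, tail_statistics)
from mdximmune.io import read_trajectory

# 12-week reference trajectory values computed with an independent ODE
# implementation (R deSolve, lsoda, rtol 1e-10, atol 1e-12) from the same
# equations and calibrated parameters.
ORACLE_POINTS = {
    2.0: (207.3772182, 24.36253565, 5405.889151, 88.56814859, 3.0258205858, 8.406030827),
    4.0: (4239.1698269, 404.08158489, 104005.753995, 18.55580566, 0.9270351649, 80.517159178),
    6.0: (1681.2194511, 81.43945973, 44106.872572, 15.95608426, 0.3485202503, 83.695395488),
    8.0: (650.6822802, 32.51445783, 17790.128748, 26.75593281, 0.5095764054, 72.734490788),
    12.0: (425.6358228, 34.94183145, 11171.576032, 40.89027953, 1.1859561608, 57.923764312),
}


def constant_trajectory(value_N, t_end=50.0, mdx=None):
    """Hand-built constant trajectory for summary-function tests."""
    from mdximmune import mdx_parameters

    times = np.linspace(0, t_end, 201)
    state = np.array([0.0, 4.0, 400.0, value_N, 0.0, 100.0 - value_N])
    states = np.tile(state, (times.size, 1))
    return Trajectory(times=times, states=states,
                      parameters=mdx or mdx_parameters(),
                      settings=SimulationSettings(t_end=t_end))


class TestIntegrate:
    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SimulationSettings(t_start=5.0, t_end=5.0)
        with pytest.raises(ValueError):
            SimulationSettings(output_step=0.0)

    def test_fixed_point_preserved(self, mdx):
        """No damage input and no resident CD8+ cells: the healthy baseline
        never moves."""
        p = mdx.with_values(h=0.0, C0=0.0)
        tr = integrate(p, cfg=SimulationSettings(t_end=12.0))
        np.testing.assert_allclose(
            tr.states, np.tile(p.baseline_state().as_array(), (tr.times.size, 1)),
            rtol=1e-7, atol=1e-7)

    def test_fiber_conservation_reference_run(self, reference_12wk):
        cfg = reference_12wk.settings
        assert reference_12wk.conservation_error() <= 10 * cfg.rel_tol * 100

    def test_matches_independent_oracle(self, reference_12wk):
        """Cross-implementation check against frozen R deSolve values."""
        for t, expected in ORACLE_POINTS.items():
            got = reference_12wk.state_at(t).as_array()
            np.testing.assert_allclose(got, expected, rtol=5e-4)

    def test_tolerance_refinement_changes_little(self, mdx):
        """Tightening tolerances moves reported states by <0.1% relative."""
        base = integrate(mdx, cfg=SimulationSettings(t_end=12.0, output_step=0.5))
        tight = integrate(mdx, cfg=SimulationSettings(
            t_end=12.0, output_step=0.5, rel_tol=1e-10, abs_tol=1e-12))
        scale = np.abs(tight.states).max(axis=0)
        assert np.max(np.abs(base.states - tight.states) / scale) < 1e-3

    @given(
        k4=st.floats(0.06, 0.25), k5=st.floats(2e-3, 8.2e-3),
        k1=st.floats(0.016, 0.065),
    )
    @hsettings(max_examples=10, deadline=None)
    def test_conservation_for_random_admissible_parameters(self, mdx, fast_cfg, k4, k5, k1):
        tr = integrate(mdx.with_values(k4=k4, k5=k5, k1=k1), cfg=fast_cfg)
        assert tr.conservation_error() < 1e-3

    def test_csv_round_trip(self, reference_12wk, tmp_path):
        path = tmp_path / "traj.csv"
        reference_12wk.to_csv(path)
        df = read_trajectory(path)
        np.testing.assert_allclose(df["t"].to_numpy(), reference_12wk.times, atol=1e-12)
        np.testing.assert_allclose(df[["H", "C", "M", "N", "D", "R"]].to_numpy(),
                                   reference_12wk.states, rtol=1e-12)
        assert (tmp_path / "traj.csv.meta.json").exists()


class TestSummaries:
    def test_constant_trajectory_has_zero_amplitude(self):
        ts = tail_statistics(constant_trajectory(40.0), (40, 50))
        assert np.all(ts.stats["amplitude"].to_numpy() == 0.0)

    def test_mean_within_min_max(self, reference_12wk):
        ts = tail_statistics(reference_12wk, (2.0, 12.0))
        assert np.all(ts.stats["min"] <= ts.stats["mean"])
        assert np.all(ts.stats["mean"] <= ts.stats["max"])
        assert np.all(ts.stats["amplitude"] >= 0)

    def test_empty_window_raises(self, reference_12wk):
        with pytest.raises(ValueError):
            tail_statistics(reference_12wk, (40.0, 50.0))

    def test_classify_constant_modes(self):
        assert classify_mode(constant_trajectory(100.0)) == "disease_free"
        assert classify_mode(constant_trajectory(40.0)) == "quiescent_low"

    def test_classify_oscillatory(self, mdx):
        tr = constant_trajectory(50.0)
        states = tr.states.copy()
        states[:, 3] += 5.0 * np.sin(tr.times)  # 10-point swing in N
        osc = Trajectory(times=tr.times, states=states,
                         parameters=tr.parameters, settings=tr.settings)
        assert classify_mode(osc) == "oscillatory"

    def test_peak_of_constant_breaks_tie_to_earliest(self):
        t_peak, value = peak_value(constant_trajectory(40.0), "N", (10, 20))
        assert t_peak == 10.0
        assert value == 40.0

    def test_peak_of_monotone_variable_at_window_end(self):
        tr = constant_trajectory(40.0)
        states = tr.states.copy()
        states[:, 0] = tr.times  # strictly increasing H
        mono = Trajectory(times=tr.times, states=states,
                          parameters=tr.parameters, settings=tr.settings)
        t_peak, value = peak_value(mono, "H", (0, 50))
        assert t_peak == 50.0 and value == 50.0

    def test_peak_rejects_unknown_variable(self, reference_12wk):
        with pytest.raises(ValueError):
            peak_value(reference_12wk, "X")
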
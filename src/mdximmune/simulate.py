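"""Numerical integration of the model and trajectory summaries.

The system is mildly stiff — immune counts reach ~1e5 cells/mm^3 while fiber
percentages stay in [0, 100] — so integration defaults to a stiff-capable
adaptive method (LSODA) with tight tolerances (rel 1e-8, abs 1e-10) to keep
the fiber conservation identity N + D + R = 100 intact over 50-week horizons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import VARIABLES, ModelParameters, StateVector, make_rhs

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "TailSummary",
    "IntegrationError",
    "NegativeOvershootWarning",
    "integrate",
    "tail_statistics",
    "classify_mode",
    "peak_value",
]


class IntegrationError(RuntimeError):
    """Integrator failure (e.g. step-size collapse), naming the failing time."""


class NegativeOvershootWarning(UserWarning):
    """A state component undershot zero beyond integrator tolerance."""


@dataclass(frozen=True)
class SimulationSettings:
    """Time span, output grid and integrator tolerances (all times in weeks)."""

    t_start: float = 0.0
    t_end: float = 12.0
    output_step: float = 0.1
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = np.inf
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if not (self.t_end > self.t_start >= 0):
            raise ValueError("require t_end > t_start >= 0")
        if self.output_step <= 0 or self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("output_step and tolerances must be > 0")

    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.output_step))
        grid = self.t_start + self.output_step * np.arange(n + 1)
        if grid[-1] < self.t_end - 1e-12:
            grid = np.append(grid, self.t_end)
        grid[-1] = min(grid[-1], self.t_end)
        return grid


@dataclass(frozen=True)
class Trajectory:
    """Dense model output: times (weeks) and a (len(times), 6) state array
    in the canonical H, C, M, N, D, R order."""

    times: np.ndarray
    states: np.ndarray
    parameters: ModelParameters
    settings: SimulationSettings

    def variable(self, name: str) -> np.ndarray:
        return self.states[:, VARIABLES.index(name)]

    def state_at(self, t: float) -> StateVector:
        """State at the output point closest to t."""
        i = int(np.argmin(np.abs(self.times - t)))
        return StateVector.from_array(self.states[i])

    @property
    def final_state(self) -> StateVector:
        return StateVector.from_array(self.states[-1])

    def conservation_error(self) -> float:
        """Max |N + D + R - 100| over all output points."""
        return float(np.abs(self.states[:, 3:6].sum(axis=1) - 100.0).max())

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        if hi < lo:
            raise ValueError("window must be (lo, hi) with hi >= lo")
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError(f"window {window} contains no output points")
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, columns=list(VARIABLES)).assign(t=self.times)[
            ["t", *VARIABLES]
        ]

    def to_csv(self, path: Union[str, Path], sidecar: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "units": {"t": "weeks", "H": "cells/mm^3", "C": "cells/mm^3",
                          "M": "cells/mm^3", "N": "% fibers", "D": "% fibers",
                          "R": "% fibers"},
                "parameters": self.parameters.to_dict(),
                "settings": {"t_start": self.settings.t_start,
                             "t_end": self.settings.t_end,
                             "output_step": self.settings.output_step,
                             "rel_tol": self.settings.rel_tol,
                             "abs_tol": self.settings.abs_tol,
                             "method": self.settings.method},
            }
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2) + "\n")


@dataclass(frozen=True)
class TailSummary:
    """Per-variable mean/min/max/amplitude over a stated tail window."""

    window: tuple[float, float]
    stats: pd.DataFrame  # index: variable; columns: mean, min, max, amplitude

    def mean(self, var: str) -> float:
        return float(self.stats.loc[var, "mean"])

    def amplitude(self, var: str) -> float:
        return float(self.stats.loc[var, "amplitude"])


def _solve_segment(rhs, t0, t1, y0, cfg: SimulationSettings, t_eval):
    sol = solve_ivp(
        rhs, (t0, t1), y0, method=cfg.method, rtol=cfg.rel_tol, atol=cfg.abs_tol,
        max_step=cfg.max_step, t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else t0
        raise IntegrationError(
            f"integration failed near t = {t_fail:.4g} weeks: {sol.message}")
    return sol


def integrate(
    p: ModelParameters,
    init: Optional[StateVector] = None,
    cfg: Optional[SimulationSettings] = None,
    depletion=None,
) -> Trajectory:
    """Integrate the model and return a :class:`Trajectory`.

    ``init`` defaults to the healthy baseline (N=100, D=R=0, immune at the
    homeostatic baselines).  ``depletion``, if given, is a
    :class:`~mdximmune.interventions.DepletionSchedule`; the run is split at
    the window edges and the modified dynamics applied inside the window.
    """
    cfg = cfg or SimulationSettings()
    init = init or p.baseline_state()
    grid = cfg.time_grid()

    if depletion is None:
        segments = [(cfg.t_start, cfg.t_end, make_rhs(p), None)]
    else:
        from .interventions import depletion_segments
        segments = depletion_segments(p, depletion, cfg.t_start, cfg.t_end)

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = init.as_array().copy()
    for t0, t1, rhs, enter in segments:
        if t1 <= t0:
            continue
        if enter is not None:
            y = enter(y)
        # evaluate at grid points inside the segment plus both endpoints, so
        # the state hands off exactly and window edges appear in the output
        inner = grid[(grid > t0 + 1e-12) & (grid < t1 - 1e-12)]
        t_eval = np.concatenate(([t0], inner, [t1]))
        sol = _solve_segment(rhs, t0, t1, y, cfg, t_eval)
        times_out.append(sol.t)
        states_out.append(sol.y.T)
        y = sol.y[:, -1].copy()

    times = np.concatenate(times_out)
    states = np.concatenate(states_out)
    # drop duplicated boundary points from segment stitching, keeping the
    # later one (the post-jump state when a clamp window begins)
    keep = np.ones(times.size, dtype=bool)
    keep[:-1] = np.diff(times) > 1e-12
    times, states = times[keep], states[keep]

    floor = -max(100 * cfg.abs_tol, 1e-6)
    if states.min() < floor:
        i, j = np.unravel_index(np.argmin(states), states.shape)
        warnings.warn(
            f"{VARIABLES[j]} undershot zero ({states[i, j]:.3e} at "
            f"t = {times[i]:.3g} weeks)", NegativeOvershootWarning)
    return Trajectory(times=times, states=states, parameters=p, settings=cfg)


def tail_statistics(tr: Trajectory, window: tuple[float, float]) -> TailSummary:
    """Mean/min/max/peak-to-peak amplitude of every variable over ``window``."""
    mask = tr.window_mask(window)
    sub = tr.states[mask]
    stats = pd.DataFrame(
        {
            "mean": sub.mean(axis=0),
            "min": sub.min(axis=0),
            "max": sub.max(axis=0),
        },
        index=list(VARIABLES),
    )
    stats["amplitude"] = stats["max"] - stats["min"]
    return TailSummary(window=window, stats=stats)


def classify_mode(
    tr: Trajectory,
    window: tuple[float, float] = (40.0, 50.0),
    amp_threshold: float = 1.0,
    normal_threshold: float = 90.0,
) -> str:
    """Label the long-run regime from the tail of the normal-fiber trace.

    "oscillatory": tail peak-to-peak amplitude of N >= amp_threshold
    (persistent degeneration/regeneration cycling); "disease_free": amplitude
    below threshold and tail-mean N >= normal_threshold (tissue settles almost
    all-normal); "quiescent_low": settled but with depressed normal fraction.
    """
    ts = tail_statistics(tr, window)
    if ts.amplitude("N") >= amp_threshold:
        return "oscillatory"
    if ts.mean("N") >= normal_threshold:
        return "disease_free"
    return "quiescent_low"


def peak_value(
    tr: Trajectory, variable: str, window: Optional[tuple[float, float]] = None
) -> tuple[float, float]:
    """(t_peak, value) of the maximum of ``variable`` over output points in
    ``window`` (defaults to the whole run).  Ties break to the earliest time."""
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    if window is None:
        window = (float(tr.times[0]), float(tr.times[-1]))
    mask = tr.window_mask(window)
    t = tr.times[mask]
    v = tr.variable(variable)[mask]
    i = int(np.argmax(v))  # argmax returns the first maximum: earliest time
    return float(t[i]), float(v[i])
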
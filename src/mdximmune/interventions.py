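"""In-silico immune-cell depletion experiments.

Antibody-mediated depletion of macrophages or T-cell subsets is emulated by
modifying the dynamics inside a time window, by one of two mechanisms:

``clamp_zero``
    The target population is set to zero on entering the window and both the
    component and its derivative are held at zero for the window's duration
    (total, instantaneous depletion).  Outside the window the original
    dynamics resume from the current state.

``block_influx``
    The target's constant source (bX) and its damage-driven activation term
    (k1*D*M, k2*D*H or k3*M*D) are switched off inside the window; the
    existing population still dies off at its normal death rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .model import ModelParameters, make_rhs
from .simulate import SimulationSettings, Trajectory, integrate

__all__ = [
    "DepletionSchedule",
    "DepletionResult",
    "apply_depletion",
    "depletion_segments",
    "run_depletion_experiment",
    "TARGETS",
]

#: depletion target -> index of the clamped component in the state vector
TARGETS = {"CD4": 0, "CD8": 1, "macrophages": 2}

MECHANISMS = ("clamp_zero", "block_influx")


@dataclass(frozen=True)
class DepletionSchedule:
    """Which immune population is suppressed, over which window (weeks),
    and by which mechanism."""

    target: str
    t_start: float
    t_end: float
    mechanism: str = "clamp_zero"

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(
                f"unknown target {self.target!r}; expected one of {sorted(TARGETS)}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}")
        if not (0 <= self.t_start <= self.t_end):
            raise ValueError("require 0 <= t_start <= t_end")


def experimental_window_schedule(
    target: str = "macrophages", mechanism: str = "clamp_zero"
) -> DepletionSchedule:
    """Schedule mirroring the cited antibody experiments: depletion begins at
    6 days of age and continues to 4 weeks."""
    return DepletionSchedule(target=target, t_start=6 / 7, t_end=4.0, mechanism=mechanism)


def _clamped_rhs(p: ModelParameters, idx: int):
    base = make_rhs(p)

    def rhs(t, y):
        y = y.copy()
        y[idx] = 0.0
        dy = base(t, y)
        dy[idx] = 0.0
        return dy

    return rhs


def _blocked_params(p: ModelParameters, target: str) -> ModelParameters:
    # zero the constant source via the baseline, and the activation rate
    if target == "CD4":
        return p.with_values(H0=0.0, k1=0.0)
    if target == "CD8":
        return p.with_values(C0=0.0, k2=0.0)
    return p.with_values(M0=0.0, k3=0.0)


def apply_depletion(p: ModelParameters, sched: DepletionSchedule):
    """Return the in-window right-hand side ``f(t, y)`` implementing the
    schedule's mechanism (the out-of-window dynamics are the unmodified
    model)."""
    if sched.mechanism == "clamp_zero":
        return _clamped_rhs(p, TARGETS[sched.target])
    return make_rhs(_blocked_params(p, sched.target))


def depletion_segments(p: ModelParameters, sched: DepletionSchedule,
                       t_start: float, t_end: float):
    """Split [t_start, t_end] at the depletion window edges.

    Returns a list of (t0, t1, rhs, enter) tuples consumed by
    :func:`mdximmune.simulate.integrate`; ``enter`` is an optional state
    transformation applied when the segment begins (zeroing the clamped
    component on window entry).
    """
    base = make_rhs(p)
    in_rhs = apply_depletion(p, sched)
    w0 = max(t_start, sched.t_start)
    w1 = min(t_end, sched.t_end)
    if w1 <= w0:  # window outside the run (or zero length): original dynamics
        return [(t_start, t_end, base, None)]

    enter = None
    if sched.mechanism == "clamp_zero":
        idx = TARGETS[sched.target]

        def enter(y, _i=idx):
            y = y.copy()
            y[_i] = 0.0
            return y

    return [
        (t_start, w0, base, None),
        (w0, w1, in_rhs, enter),
        (w1, t_end, base, None),
    ]


@dataclass(frozen=True)
class DepletionResult:
    """Matched depleted / undepleted runs plus end-of-run fiber composition."""

    depleted: Trajectory
    control: Trajectory
    schedule: DepletionSchedule

    @property
    def final_fibers(self) -> dict:
        s = self.depleted.final_state
        return {"N": s.N, "D": s.D, "R": s.R}

    @property
    def control_final_fibers(self) -> dict:
        s = self.control.final_state
        return {"N": s.N, "D": s.D, "R": s.R}


def run_depletion_experiment(
    p: ModelParameters,
    sched: DepletionSchedule,
    cfg: Optional[SimulationSettings] = None,
) -> DepletionResult:
    """Run the depleted and matched undepleted simulations."""
    cfg = cfg or SimulationSettings()
    depleted = integrate(p, cfg=cfg, depletion=sched)
    control = integrate(p, cfg=cfg)
    return DepletionResult(depleted=depleted, control=control, schedule=sched)
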
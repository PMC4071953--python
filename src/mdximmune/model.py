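"""Core state, parameters and right-hand side of the mdx immune–muscle model.

The model couples three immune-cell populations measured in cells per mm^3 of
muscle tissue — CD4+ helper T-cells (H), CD8+ cytotoxic T-cells (C) and
macrophages (M) — to three muscle-fiber states measured as percentages of the
whole tissue: normal (N), damaged (D) and regenerating (R) fibers, with
N + D + R = 100 conserved.

Mechanical damage enters as a lognormal time-to-failure hazard ``alpha(t)``:
accumulated damage in a dystrophic muscle is a multiplicative degradation
process, so the time at which fibers fail is lognormally distributed and the
per-week failure hazard applied to normal fibers is a scaled lognormal density
in the age of the mouse (in weeks).

The coupled dynamics are

    dH/dt = bH + k1*D*M - dH*H
    dC/dt = bC + k2*D*H - dC*C
    dM/dt = bM + k3*M*D - dM*M
    dN/dt = k4*R - k5*C*N - alpha(t)*N
    dD/dt = k5*C*N + alpha(t)*N - k6*D*M - dD*D
    dR/dt = k6*D*M + dD*D - k4*R

where the immune source terms are tied to the homeostatic baselines:
bH = dH*H0, bC = dC*C0, bM = dM*M0, so that with no damage present the
immune populations rest at (H0, C0, M0).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "VARIABLES",
    "StateVector",
    "StateDerivative",
    "DamageParameters",
    "ModelParameters",
    "damage_rate",
    "derived_sources",
    "derivatives",
    "mdx_parameters",
    "wild_type_parameters",
]

#: Canonical ordering of the six state variables.
VARIABLES = ("H", "C", "M", "N", "D", "R")

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class InvalidParameterError(ValueError):
    """Raised when a parameter container violates its constraints."""


@dataclass(frozen=True)
class StateVector:
    """Model state at one time point.

    H, C, M are immune-cell counts (cells/mm^3); N, D, R are fiber-state
    percentages of the whole muscle (summing to 100).
    """

    H: float
    C: float
    M: float
    N: float
    D: float
    R: float

    def as_array(self) -> np.ndarray:
        return np.array([self.H, self.C, self.M, self.N, self.D, self.R], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*(float(v) for v in np.asarray(y, dtype=float)))

    @property
    def fiber_total(self) -> float:
        return self.N + self.D + self.R


@dataclass(frozen=True)
class StateDerivative:
    """Time derivative of the state; the three fiber flows sum to zero exactly."""

    dH: float
    dC: float
    dM: float
    dN: float
    dD: float
    dR: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dH, self.dC, self.dM, self.dN, self.dD, self.dR], dtype=float)


@dataclass(frozen=True)
class DamageParameters:
    """Lognormal damage hazard parameters.

    h is the total hazard mass (the integral of alpha over all time), m and
    sigma are the location and scale of log failure time (log-weeks).
    """

    h: float
    m: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.h < 0:
            raise InvalidParameterError(f"h must be >= 0, got {self.h}")


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants plus damage parameters and immune baselines.

    Units: k1, k2, k3 in (% damage)^-1 week^-1; k4, dH, dC, dM, dD in
    week^-1; k5, k6 in cell^-1 week^-1; H0, C0, M0 in cells/mm^3.
    The constant immune source terms bH, bC, bM are derived (bX = dX * X0),
    never stored.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    dH: float
    dC: float
    dM: float
    dD: float
    H0: float
    C0: float
    M0: float
    damage: DamageParameters

    _RATE_FIELDS = ("k1", "k2", "k3", "k4", "k5", "k6", "dH", "dC", "dM", "dD")

    def __post_init__(self) -> None:
        for name in self._RATE_FIELDS + ("H0", "C0", "M0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")

    # -- derived source terms -------------------------------------------------
    @property
    def bH(self) -> float:
        return self.dH * self.H0

    @property
    def bC(self) -> float:
        return self.dC * self.C0

    @property
    def bM(self) -> float:
        return self.dM * self.M0

    def baseline_state(self) -> StateVector:
        """Healthy-tissue initial condition: all fibers normal, immune at rest."""
        return StateVector(H=self.H0, C=self.C0, M=self.M0, N=100.0, D=0.0, R=0.0)

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self._RATE_FIELDS}
        d.update(h=self.damage.h, m=self.damage.m, sigma=self.damage.sigma,
                 H0=self.H0, C0=self.C0, M0=self.M0)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        damage = DamageParameters(h=d.pop("h"), m=d.pop("m"), sigma=d.pop("sigma"))
        return cls(damage=damage, **d)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_values(self, **updates) -> "ModelParameters":
        """Copy with named entries replaced; accepts the flat keys h, m, sigma too."""
        damage_updates = {k: updates.pop(k) for k in ("h", "m", "sigma") if k in updates}
        out = replace(self, **updates)
        if damage_updates:
            out = replace(out, damage=replace(out.damage, **damage_updates))
        return out


def mdx_parameters() -> ModelParameters:
    """Calibrated parameter set for the dystrophic (mdx) mouse."""
    return ModelParameters(
        k1=0.0324139,
        k2=0.115375,
        k3=0.766576,
        k4=0.123848,
        k5=4.09948e-3,
        k6=3.23097e-4,
        dH=0.83355,
        dC=1.61511,
        dM=0.781155,
        dD=1.34671,
        H0=0.0,
        C0=4.0,
        M0=400.0,
        damage=DamageParameters(h=0.511657, m=4.22686, sigma=2.92815),
    )


def wild_type_parameters() -> ModelParameters:
    """Wild-type configuration: identical to mdx except the damage amplitude
    h is one tenth of the mdx value (physiological damage is not amplified)."""
    p = mdx_parameters()
    return p.with_values(h=p.damage.h / 10.0)


def damage_rate(t, p: DamageParameters):
    """Lognormal per-week damage hazard alpha(t).

    alpha(t) = h / (t * sigma * sqrt(2*pi)) * exp(-(ln t - m)^2 / (2 sigma^2))

    for t > 0, and 0 at t = 0 (the continuous right-limit of the lognormal
    density).  Accepts scalars or arrays of times in weeks.
    """
    if p.sigma <= 0:
        raise InvalidParameterError("sigma must be > 0")
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise ValueError("damage_rate requires t >= 0")
    out = np.zeros_like(t_arr)
    pos = t_arr > 0
    if p.h > 0 and pos.any():
        # evaluate in log space: near t = 0 the 1/t factor overflows long
        # before the Gaussian tail underflows, but their product tends to 0
        log_t = np.log(t_arr[pos])
        log_pdf = (math.log(p.h) - log_t - math.log(p.sigma * _SQRT_2PI)
                   - (log_t - p.m) ** 2 / (2.0 * p.sigma ** 2))
        out[pos] = np.exp(log_pdf)
    return float(out[0]) if scalar else out


def derived_sources(p: ModelParameters) -> tuple[float, float, float]:
    """Constant immune source terms (bH, bC, bM) = (dH*H0, dC*C0, dM*M0)."""
    return p.bH, p.bC, p.bM


def derivatives(t: float, s: StateVector, p: ModelParameters) -> StateDerivative:
    """Right-hand side of the model at time t (weeks).

    The regenerating-fiber flow is computed as dR = -(dN + dD), which is
    algebraically identical to k6*D*M + dD*D - k4*R and makes the fiber
    conservation identity dN + dD + dR = 0 hold exactly in floating point.
    """
    a = damage_rate(t, p.damage)
    H, C, M, N, D = s.H, s.C, s.M, s.N, s.D
    dH = p.bH + p.k1 * D * M - p.dH * H
    dC = p.bC + p.k2 * D * H - p.dC * C
    dM = p.bM + p.k3 * M * D - p.dM * M
    dN = p.k4 * s.R - p.k5 * C * N - a * N
    dD = p.k5 * C * N + a * N - p.k6 * D * M - p.dD * D
    dR = -(dN + dD)
    return StateDerivative(dH=dH, dC=dC, dM=dM, dN=dN, dD=dD, dR=dR)


def make_rhs(p: ModelParameters):
    """Return a fast ``f(t, y) -> ndarray`` closure over raw state arrays,
    suitable for scipy integrators.  Same flows as :func:`derivatives`."""
    k1, k2, k3, k4, k5, k6 = p.k1, p.k2, p.k3, p.k4, p.k5, p.k6
    dH_, dC_, dM_, dD_ = p.dH, p.dC, p.dM, p.dD
    bH, bC, bM = p.bH, p.bC, p.bM
    h, m, sigma = p.damage.h, p.damage.m, p.damage.sigma
    two_sig2 = 2.0 * sigma * sigma
    log_coef = math.log(h / (sigma * _SQRT_2PI)) if h > 0 else -math.inf

    def rhs(t, y):
        H, C, M, N, D, R = y
        if t <= 0.0 or h == 0.0:
            a = 0.0
        else:
            log_t = math.log(t)
            log_a = log_coef - log_t - (log_t - m) ** 2 / two_sig2
            a = math.exp(log_a) if log_a > -745.0 else 0.0
        dN = k4 * R - k5 * C * N - a * N
        dD = k5 * C * N + a * N - k6 * D * M - dD_ * D
        return np.array([
            bH + k1 * D * M - dH_ * H,
            bC + k2 * D * H - dC_ * C,
            bM + k3 * M * D - dM_ * M,
            dN,
            dD,
            -(dN + dD),
        ])

    return rhs
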
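"""Literature-style synthetic observation sets from known parameters.

The calibration data this emulates are sparse weekly time courses over the
age range 14–84 days, pooled from several murine studies: immune-cell
densities (cells/mm^3) and fiber-state percentages.  Counts get independent
multiplicative lognormal noise (unit mean, chosen coefficient of variation);
fiber percentages get additive Gaussian noise truncated to [0, 100].  Noise
is independent per observation — no autocorrelation and no replicate
structure — so the generator captures sampling sparseness and measurement
scatter, not between-animal covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import ObservationSet
from .model import VARIABLES, ModelParameters
from .simulate import SimulationSettings, integrate

__all__ = [
    "NoiseModel",
    "DesignSet",
    "SamplingDesign",
    "default_mdx_design",
    "generate_observations",
]

COUNT_VARIABLES = ("H", "C", "M")
PERCENT_VARIABLES = ("N", "D", "R")


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: multiplicative lognormal (scale = CV) for cell
    counts, additive truncated Gaussian (scale = sd, percentage points) for
    fiber percentages."""

    kind: str
    scale: float

    KINDS = ("multiplicative_lognormal", "additive_truncated_gaussian")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.scale == 0:
            return values.copy()
        if self.kind == "multiplicative_lognormal":
            # unit-mean lognormal factor with the requested CV
            sig2 = np.log1p(self.scale ** 2)
            factors = rng.lognormal(mean=-sig2 / 2, sigma=np.sqrt(sig2), size=values.shape)
            return values * factors
        noisy = values + rng.normal(0.0, self.scale, size=values.shape)
        return np.clip(noisy, 0.0, 100.0)


def default_noise_for(variable: str, count_cv: float = 0.2,
                      percent_sd: float = 3.0) -> NoiseModel:
    if variable in COUNT_VARIABLES:
        return NoiseModel("multiplicative_lognormal", count_cv)
    return NoiseModel("additive_truncated_gaussian", percent_sd)


@dataclass(frozen=True)
class DesignSet:
    """One dataset of the design: a variable sampled at stated times (weeks)."""

    dataset_id: str
    variable: str
    times: tuple

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")


@dataclass(frozen=True)
class SamplingDesign:
    sets: tuple

    @property
    def max_time(self) -> float:
        return max(max(s.times) for s in self.sets)


def default_mdx_design() -> SamplingDesign:
    """Default design emulating the pooled literature time courses: every
    variable sampled weekly from day 14 to day 84 (weeks 2–12).

    Immune counts mimic the cited soleus macrophage and quadriceps T-cell
    series; fiber-state percentages mimic the histopathology series.
    """
    times = tuple(np.arange(14, 85, 7) / 7.0)  # 11 weekly samples, in weeks
    ids = {
        "M": "macrophages_soleus",
        "H": "cd4_quadriceps",
        "C": "cd8_quadriceps",
        "N": "fibers_normal",
        "D": "fibers_damaged",
        "R": "fibers_regenerating",
    }
    return SamplingDesign(sets=tuple(
        DesignSet(dataset_id=ids[v], variable=v, times=times) for v in VARIABLES
    ))


def generate_observations(
    p: ModelParameters,
    design: Optional[SamplingDesign] = None,
    count_cv: float = 0.2,
    percent_sd: float = 3.0,
    seed: int = 0,
    cfg: Optional[SimulationSettings] = None,
) -> list[ObservationSet]:
    """Simulate ``p`` and sample noisy observations per the design.

    With both noise scales zero the returned values equal the trajectory
    values at the sampling times exactly.  Fully reproducible from ``seed``.
    """
    design = design or default_mdx_design()
    if cfg is None:
        cfg = SimulationSettings(t_end=float(np.ceil(design.max_time)))
    elif design.max_time > cfg.t_end + 1e-9:
        raise ValueError("design times exceed the simulation horizon")
    tr = integrate(p, cfg=cfg)
    rng = np.random.default_rng(seed)
    out = []
    for ds in design.sets:
        times = np.asarray(ds.times, dtype=float)
        clean = np.interp(times, tr.times, tr.variable(ds.variable))
        noise = default_noise_for(ds.variable, count_cv, percent_sd)
        values = noise.apply(clean, rng)
        out.append(ObservationSet(
            dataset_id=ds.dataset_id, variable=ds.variable,
            times=times, values=values, weight=1.0))
    return out
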
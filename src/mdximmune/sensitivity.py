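"""Ensemble and sweep analyses: initial-condition ensembles, the two-level
factorial over the sensitivity ranges, one-dimensional parameter sweeps,
k1 x k2 heat maps at week 50, and the optimal-k4 grid search.

"Asymptotic" behavior is operationalized as the tail of a 50-week run:
sweeps summarize the mean over weeks 40-50 (damping oscillation-phase
artifacts), heat maps sample the week-50 state value.  All operations are
pure functions of (parameters, grids, seed) and reproduce bit-identically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelParameters, StateVector, mdx_parameters
from .simulate import (IntegrationError, SimulationSettings, Trajectory,
                       classify_mode, integrate, peak_value, tail_statistics)

__all__ = [
    "SENSITIVITY_RANGES",
    "DEFAULT_BASELINE_RANGES",
    "EnsembleResult",
    "SweepResult",
    "initial_condition_ensemble",
    "factorial_ensemble",
    "sweep_1d",
    "heatmap_2d",
    "find_optimal_k4",
]

#: Half-to-double style (Min, Max) ranges for the ten swept rate parameters,
#: as printed in the calibration report (stored verbatim; a few rows differ
#: slightly from exact halving/doubling).
SENSITIVITY_RANGES = {
    "k1": (0.0160773, 0.0643092),
    "dH": (0.416775, 1.6671),
    "k2": (0.0577452, 0.230981),
    "dC": (0.807555, 3.23022),
    "k3": (0.381371, 1.52549),
    "dM": (0.390577, 1.56231),
    "k4": (0.061924, 0.247696),
    "k5": (2.04974e-3, 8.19896e-3),
    "k6": (1.61548e-4, 6.46194e-4),
    "dD": (0.673355, 2.69342),
}

#: Immune-baseline draw ranges (cells/mm^3) spanning reported wild-type
#: levels (T-cells ~100, macrophages ~1000); configurable per call.
DEFAULT_BASELINE_RANGES = {"H0": (0.0, 10.0), "C0": (1.0, 100.0), "M0": (100.0, 1000.0)}


def _fast_cfg(t_end: float, rel_tol: float = 1e-6) -> SimulationSettings:
    return SimulationSettings(t_end=t_end, output_step=0.1,
                              rel_tol=rel_tol, abs_tol=rel_tol * 1e-2)


# ---------------------------------------------------------------------------
# initial-condition ensemble
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleResult:
    """Parameter-identical runs differing only in immune baselines."""

    reference: Trajectory
    trajectories: list
    draws: pd.DataFrame
    labels: list
    reference_label: str
    peak_times: pd.DataFrame  # per-run peak times of M and D
    verdict: bool


def initial_condition_ensemble(
    n: int = 125,
    ranges: Optional[dict] = None,
    seed: int = 0,
    p: Optional[ModelParameters] = None,
    cfg: Optional[SimulationSettings] = None,
) -> EnsembleResult:
    """Run ``n`` simulations with immune baselines (H0, C0, M0) drawn
    uniformly from ``ranges`` (seeded), everything else at the reference
    parameters.

    The qualitative-equivalence verdict is True when every run carries the
    reference run's regime label (classified over the final stretch of the
    horizon) and its macrophage and damaged-fiber peak times agree with the
    reference within one week.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or DEFAULT_BASELINE_RANGES
    p = p or mdx_parameters()
    cfg = cfg or SimulationSettings(t_end=12.0)
    window = (max(cfg.t_start, cfg.t_end - 2.0), cfg.t_end)

    reference = integrate(p, cfg=cfg)
    ref_label = classify_mode(reference, window=window)
    ref_peaks = {v: peak_value(reference, v)[0] for v in ("M", "D")}

    rng = np.random.default_rng(seed)
    draws = pd.DataFrame({
        name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in ranges.items()
    })
    trajectories, labels, peak_rows = [], [], []
    for i in range(n):
        pi = p.with_values(**{k: float(draws.loc[i, k]) for k in ranges})
        tr = integrate(pi, cfg=cfg)
        trajectories.append(tr)
        labels.append(classify_mode(tr, window=window))
        peak_rows.append({v: peak_value(tr, v)[0] for v in ("M", "D")})
    peaks = pd.DataFrame(peak_rows)
    verdict = (
        all(lab == ref_label for lab in labels)
        and all((peaks[v] - ref_peaks[v]).abs().max() <= 1.0 for v in ("M", "D"))
    )
    return EnsembleResult(reference=reference, trajectories=trajectories,
                          draws=draws, labels=labels, reference_label=ref_label,
                          peak_times=peaks, verdict=verdict)


# ---------------------------------------------------------------------------
# two-level factorial ensemble
# ---------------------------------------------------------------------------

def _count_peaks(values: np.ndarray, prominence_frac: float = 0.05) -> int:
    """Number of interior local maxima taller than a fraction of the range."""
    rng_ = values.max() - values.min()
    if rng_ <= 0:
        return 0
    thr = prominence_frac * rng_
    peaks = 0
    for i in range(1, len(values) - 1):
        if values[i] >= values[i - 1] and values[i] > values[i + 1]:
            # prominence: drop to the lower of the two flanking minima
            left = values[:i].min()
            right = values[i + 1:].min()
            if values[i] - max(left, right) >= thr:
                peaks += 1
    return peaks


def early_shape_check(tr: Trajectory, t_max: float = 7.0) -> bool:
    """First-weeks qualitative check shared by the factorial ensemble: a
    single macrophage rise and a single initial damage peak before ``t_max``."""
    mask = tr.times <= t_max
    m_peaks = _count_peaks(tr.variable("M")[mask])
    d_peaks = _count_peaks(tr.variable("D")[mask])
    return m_peaks <= 1 and d_peaks <= 1


def factorial_ensemble(
    ranges: Optional[dict] = None,
    horizon: float = 50.0,
    window: tuple = (40.0, 50.0),
    rel_tol: float = 1e-6,
    p: Optional[ModelParameters] = None,
) -> pd.DataFrame:
    """Enumerate all two-level combinations of the sensitivity ranges
    (2^10 = 1024 by default), simulate each, and return a census DataFrame
    with one row per combination: the chosen level per parameter, the regime
    label, tail statistics of N, and the early-shape check.

    Integrator failures are recorded per combination (label "error"), never
    fatal.
    """
    ranges = ranges or SENSITIVITY_RANGES
    p = p or mdx_parameters()
    names = list(ranges)
    cfg = _fast_cfg(horizon, rel_tol)
    rows = []
    for bits in itertools.product((0, 1), repeat=len(names)):
        values = {name: ranges[name][b] for name, b in zip(names, bits)}
        row = dict(values)
        try:
            tr = integrate(p.with_values(**values), cfg=cfg)
            ts = tail_statistics(tr, window)
            row.update(
                label=classify_mode(tr, window=window),
                tail_mean_N=ts.mean("N"), tail_amp_N=ts.amplitude("N"),
                early_uniform=early_shape_check(tr),
                error="",
            )
        except IntegrationError as err:
            row.update(label="error", tail_mean_N=np.nan, tail_amp_N=np.nan,
                       early_uniform=False, error=str(err))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweeps and heat maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    """Tail summaries per grid point of a one-parameter sweep."""

    parameter: str
    grid: np.ndarray
    table: pd.DataFrame  # one row per grid point: tail stats + mode label
    horizon: float
    window: tuple


def sweep_1d(
    param: str,
    grid: Sequence[float],
    horizon: float = 50.0,
    window: tuple = (40.0, 50.0),
    p: Optional[ModelParameters] = None,
    rel_tol: float = 1e-8,
) -> SweepResult:
    """Vary one parameter over ``grid`` with all others fixed; summarize the
    tail window of each run."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sweep grid is empty")
    p = p or mdx_parameters()
    cfg = SimulationSettings(t_end=horizon, output_step=0.1,
                             rel_tol=rel_tol, abs_tol=rel_tol * 1e-2)
    rows = []
    for value in grid:
        tr = integrate(p.with_values(**{param: float(value)}), cfg=cfg)
        ts = tail_statistics(tr, window)
        row = {param: float(value), "label": classify_mode(tr, window=window)}
        for var in ("N", "D", "R", "M", "C", "H"):
            row[f"mean_{var}"] = ts.mean(var)
            row[f"amp_{var}"] = ts.amplitude(var)
        rows.append(row)
    return SweepResult(parameter=param, grid=grid, table=pd.DataFrame(rows),
                       horizon=horizon, window=window)


def heatmap_2d(
    k1_grid: Sequence[float],
    k2_grid: Sequence[float],
    variable: str = "N",
    week: float = 50.0,
    p: Optional[ModelParameters] = None,
    params: tuple = ("k1", "k2"),
    rel_tol: float = 1e-8,
) -> pd.DataFrame:
    """Matrix of the week-``week`` value of ``variable`` over a two-parameter
    grid (rows: first parameter, columns: second), all else fixed."""
    p = p or mdx_parameters()
    a_grid = np.asarray(list(k1_grid), dtype=float)
    b_grid = np.asarray(list(k2_grid), dtype=float)
    cfg = SimulationSettings(t_end=week, output_step=0.1,
                             rel_tol=rel_tol, abs_tol=rel_tol * 1e-2)
    out = np.empty((a_grid.size, b_grid.size))
    for i, a in enumerate(a_grid):
        for j, b in enumerate(b_grid):
            tr = integrate(p.with_values(**{params[0]: float(a),
                                            params[1]: float(b)}), cfg=cfg)
            out[i, j] = getattr(tr.final_state, variable)
    return pd.DataFrame(out, index=pd.Index(a_grid, name=params[0]),
                        columns=pd.Index(b_grid, name=params[1]))


def find_optimal_k4(
    k4_range: tuple = (0.05, 0.25),
    resolution: float = 0.005,
    horizon: float = 50.0,
    window: tuple = (40.0, 50.0),
    p: Optional[ModelParameters] = None,
) -> tuple[float, float, SweepResult]:
    """Grid argmax of the tail-mean normal-fiber percentage over k4.

    Returns (k4_star, tail-mean N at k4_star, full sweep).  Deterministic;
    ties break toward the smallest k4.
    """
    lo, hi = k4_range
    n = int(round((hi - lo) / resolution))
    grid = lo + resolution * np.arange(n + 1)
    sweep = sweep_1d("k4", grid, horizon=horizon, window=window, p=p)
    means = sweep.table["mean_N"].to_numpy()
    i = int(np.argmax(means))
    return float(grid[i]), float(means[i]), sweep
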
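"""File round-tripping and run logging.

Parameters travel as a flat key-value JSON document (keys k1..k6, dH, dC,
dM, dD, h, m, sigma, H0, C0, M0); trajectories as CSV with header
t,H,C,M,N,D,R plus a sidecar metadata JSON; observations as CSV with
columns dataset_id,variable,time_days,value,weight.  All floats are written
at full double precision so round trips are identities.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Union

import pandas as pd

from .model import VARIABLES, ModelParameters
from .simulate import SimulationSettings, Trajectory

__all__ = [
    "read_params",
    "write_params",
    "read_trajectory",
    "write_trajectory",
    "write_run_log",
    "setup_logging",
]


def read_params(path: Union[str, Path]) -> ModelParameters:
    return ModelParameters.from_json(path)


def write_params(p: ModelParameters, path: Union[str, Path]) -> None:
    p.to_json(path)


def write_trajectory(tr: Trajectory, path: Union[str, Path]) -> None:
    tr.to_csv(path)


def read_trajectory(path: Union[str, Path]) -> pd.DataFrame:
    """Trajectory CSV back as a DataFrame (t plus the six state columns)."""
    df = pd.read_csv(path)
    expected = ["t", *VARIABLES]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    return df


def write_run_log(path: Union[str, Path], experiment: str, seed=None,
                  config: dict | None = None, **extra) -> None:
    """Record exactly what produced an artifact: experiment name, seed,
    configuration and library versions."""
    import numpy
    import scipy

    payload = {
        "experiment": experiment,
        "seed": seed,
        "config": config or {},
        "versions": {
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def setup_logging(logfile: Union[str, Path, None] = None,
                  level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
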
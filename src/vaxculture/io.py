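"""CSV/JSON serialization of trajectories and sweep grids."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PhenotypeDistribution, Trajectory
from .sweeps import SweepResult

__all__ = ["write_trajectory", "read_trajectory", "write_sweep", "sweep_summary"]

_TRAJ_COLUMNS = [
    "iteration",
    "freq_VpAp",
    "freq_VpAm",
    "freq_VmAp",
    "freq_VmAm",
    "coverage",
    "confidence",
    "sigma",
]


def write_trajectory(trajectory: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as CSV, one row per recorded state (initial included).

    Frequencies are written in full float precision so a read back reproduces
    the trajectory to within 1e-12.
    """
    path = Path(path)
    df = trajectory.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    df = pd.read_csv(Path(path))
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    states = [
        PhenotypeDistribution.from_array(row, renormalize=True)
        for row in df[["freq_VpAp", "freq_VpAm", "freq_VmAp", "freq_VmAm"]].to_numpy()
    ]
    sigma = df["sigma"].to_numpy()[1:].astype(float).tolist()
    traj = Trajectory(states=states, sigma_series=sigma)
    # equilibrium flags are derivable, not stored; leave at defaults
    return traj


def write_sweep(result: SweepResult, csv_path: str | Path, json_path: str | Path | None = None) -> Path:
    """Write a sweep grid as long-format CSV, optionally with a JSON summary."""
    csv_path = Path(csv_path)
    result.to_dataframe().to_csv(csv_path, index=False, float_format="%.17g")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(sweep_summary(result), indent=2))
    return csv_path


def sweep_summary(result: SweepResult) -> dict:
    """Compact JSON-ready summary of a sweep grid."""
    cov = np.asarray(result.equilibrium_coverage)
    conf = np.asarray(result.equilibrium_confidence)
    return {
        "axis1": {"parameter": result.axis1.parameter, "n": len(result.axis1)},
        "axis2": {"parameter": result.axis2.parameter, "values": list(result.axis2.values)},
        "coverage": {"min": float(cov.min()), "max": float(cov.max()), "mean": float(cov.mean())},
        "confidence": {
            "min": float(conf.min()),
            "max": float(conf.max()),
            "mean": float(conf.mean()),
        },
    }
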
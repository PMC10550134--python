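"""Parameter-sweep engines producing equilibrium landscapes.

Two sweep designs, each a grid with sigma_max on one axis:

* mixed-couple confidence transmission: ``C1 = C2`` varies, ``C0``/``C3`` stay
  at baseline — probes how the attitude transmission of mixed-attitude
  couples interacts with perceived vaccine value;
* confidence range shift: all four ``C_n`` move together inside a sliding
  interval [lo, hi] with ``C0 = lo``, ``C1 = C2 = (lo+hi)/2``, ``C3 = hi`` —
  probes uniformly more hesitant or more confident transmission cultures.

Every cell restarts the recursion from the same initial phenotype
frequencies, so cells are independent equilibria, not a continuation path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    IterationSettings,
    PhenotypeDistribution,
    Trajectory,
    TransmissionParameters,
    iterate,
)
from .responses import ObliqueFunctions, SelectionFunction
from .scenarios import ScenarioConfig, apply_scenario

__all__ = [
    "SweepAxis",
    "SweepResult",
    "default_confidence_range_intervals",
    "sweep_mixed_confidence",
    "sweep_confidence_range",
]

#: Initial phenotype frequencies for all sweeps (US-like starting point).
DEFAULT_INITIAL_STATE = PhenotypeDistribution(0.81, 0.10, 0.07, 0.02)


@dataclass(frozen=True)
class SweepAxis:
    """One sweep dimension: the parameter it varies and its grid."""

    parameter: str  # mixed_confidence | confidence_range_shift | sigma_max
    values: tuple

    def __post_init__(self) -> None:
        if self.parameter not in ("mixed_confidence", "confidence_range_shift", "sigma_max"):
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        object.__setattr__(self, "values", tuple(self.values))
        if len(self.values) == 0:
            raise ValueError("sweep axis needs at least one grid value")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SweepResult:
    """Equilibrium surfaces over a 2-D parameter grid.

    Matrices are indexed ``[i, j]`` with ``i`` along ``axis1`` (the
    confidence-transmission axis) and ``j`` along ``axis2`` (sigma_max).
    """

    axis1: SweepAxis
    axis2: SweepAxis
    equilibrium_coverage: np.ndarray
    equilibrium_confidence: np.ndarray
    iterations_used: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.axis1), len(self.axis2))
        for name in ("equilibrium_coverage", "equilibrium_confidence", "iterations_used"):
            mat = np.asarray(getattr(self, name))
            if mat.shape != shape:
                raise ValueError(f"{name} has shape {mat.shape}, expected {shape}")

    def to_dataframe(self):
        """Long format: one row per grid cell."""
        import pandas as pd

        rows = []
        for i, v1 in enumerate(self.axis1.values):
            for j, v2 in enumerate(self.axis2.values):
                rows.append(
                    {
                        "axis1_name": self.axis1.parameter,
                        "axis1_value": v1 if np.isscalar(v1) else str(v1),
                        "axis2_value": v2,
                        "equilibrium_coverage": self.equilibrium_coverage[i, j],
                        "equilibrium_confidence": self.equilibrium_confidence[i, j],
                        "iterations_used": int(self.iterations_used[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def default_confidence_range_intervals(n: int = 21) -> list[tuple[float, float]]:
    """Default sliding intervals for the range-shift sweep.

    Interval i has lower bound 0.01 and width 0.98 * t_i with t_i uniform on
    [0, 1], so the topmost interval is [0.01, 0.99] — exactly the baseline
    ``C`` vector — and lower intervals represent uniformly more hesitant
    transmission cultures.
    """
    ts = np.linspace(0.0, 1.0, n)
    return [(0.01, 0.01 + 0.98 * t) for t in ts]


def _run_cell(
    dist0: PhenotypeDistribution,
    params: TransmissionParameters,
    selection: SelectionFunction,
    oblique: ObliqueFunctions,
    settings: IterationSettings,
) -> Trajectory:
    return iterate(dist0, params, selection, oblique, settings)


def _sweep(
    axis1: SweepAxis,
    axis2: SweepAxis,
    cell_params,
    dist0: PhenotypeDistribution,
    selection_template: SelectionFunction,
    oblique: ObliqueFunctions,
    settings: IterationSettings,
) -> SweepResult:
    n1, n2 = len(axis1), len(axis2)
    cov = np.empty((n1, n2))
    conf = np.empty((n1, n2))
    iters = np.empty((n1, n2), dtype=int)
    for i, v1 in enumerate(axis1.values):
        params = cell_params(v1)
        for j, smax in enumerate(axis2.values):
            traj = _run_cell(dist0, params, selection_template.with_sigma_max(smax), oblique, settings)
            cov[i, j] = traj.final.coverage
            conf[i, j] = traj.final.confidence
            iters[i, j] = traj.n_iterations
    return SweepResult(axis1, axis2, cov, conf, iters)


def sweep_mixed_confidence(
    base_params: TransmissionParameters,
    scenario: ScenarioConfig | str,
    C_grid: Sequence[float],
    sigma_max_grid: Sequence[float],
    selection_family: str | SelectionFunction = "threshold_mid",
    settings: IterationSettings | None = None,
    oblique: ObliqueFunctions | None = None,
    initial_state: PhenotypeDistribution | None = None,
) -> SweepResult:
    """Equilibrium grid over (C1 = C2) x sigma_max for one scenario.

    Each cell sets the mixed-attitude couples' confidence transmission
    ``C1 = C2`` to the grid value (``C0`` and ``C3`` stay at their base
    values), applies the scenario's ``c`` override, and iterates from the
    standard initial state.
    """
    settings = settings or IterationSettings()
    oblique = oblique or ObliqueFunctions()
    dist0 = initial_state or DEFAULT_INITIAL_STATE
    selection = (
        SelectionFunction(family=selection_family)
        if isinstance(selection_family, str)
        else selection_family
    )
    scen_params = apply_scenario(base_params, scenario)

    axis1 = SweepAxis("mixed_confidence", tuple(float(x) for x in C_grid))
    axis2 = SweepAxis("sigma_max", tuple(float(x) for x in sigma_max_grid))
    _validate_increasing(axis1)
    _validate_increasing(axis2)

    def cell_params(c12: float) -> TransmissionParameters:
        C = (scen_params.C[0], c12, c12, scen_params.C[3])
        return scen_params.replace(C=C)

    return _sweep(axis1, axis2, cell_params, dist0, selection, oblique, settings)


def sweep_confidence_range(
    base_params: TransmissionParameters,
    scenario: ScenarioConfig | str,
    range_grid: Sequence[tuple[float, float]],
    sigma_max_grid: Sequence[float],
    selection_family: str | SelectionFunction = "threshold_mid",
    settings: IterationSettings | None = None,
    oblique: ObliqueFunctions | None = None,
    initial_state: PhenotypeDistribution | None = None,
) -> SweepResult:
    """Equilibrium grid over confidence-range intervals x sigma_max.

    Each interval [lo, hi] sets ``C0 = lo``, ``C1 = C2 = (lo + hi)/2``,
    ``C3 = hi`` — preserving the baseline ordering where homogeneous hesitant
    couples transmit the least confidence and homogeneous confident couples
    the most.
    """
    settings = settings or IterationSettings()
    oblique = oblique or ObliqueFunctions()
    dist0 = initial_state or DEFAULT_INITIAL_STATE
    selection = (
        SelectionFunction(family=selection_family)
        if isinstance(selection_family, str)
        else selection_family
    )
    scen_params = apply_scenario(base_params, scenario)

    intervals = []
    for lo, hi in range_grid:
        lo, hi = float(lo), float(hi)
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"malformed interval [{lo}, {hi}]: need 0 <= lo <= hi <= 1")
        intervals.append((lo, hi))

    axis1 = SweepAxis("confidence_range_shift", tuple(intervals))
    axis2 = SweepAxis("sigma_max", tuple(float(x) for x in sigma_max_grid))
    _validate_increasing(axis2)

    def cell_params(interval: tuple[float, float]) -> TransmissionParameters:
        lo, hi = interval
        mid = (lo + hi) / 2.0
        return scen_params.replace(C=(lo, mid, mid, hi))

    return _sweep(axis1, axis2, cell_params, dist0, selection, oblique, settings)


def _validate_increasing(axis: SweepAxis) -> None:
    vals = np.asarray(axis.values, dtype=float)
    if len(vals) > 1 and np.any(np.diff(vals) <= 0):
        raise ValueError(f"{axis.parameter} grid must be strictly increasing")
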
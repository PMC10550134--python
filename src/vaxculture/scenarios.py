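"""Named policy scenarios and baseline comparisons.

Mandates and inaccessibility both act on the attitude-influence vector ``c``:
a mandate raises ``c`` for hesitant-containing couples (hesitancy no longer
prevents vaccination), inaccessibility lowers ``c`` for confident-containing
couples (confidence no longer guarantees vaccination).  Both therefore
decouple attitudes from vaccination behavior, in opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PhenotypeDistribution, Trajectory, TransmissionParameters

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "apply_scenario",
    "EquilibriumComparison",
    "compare_to_baseline",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """A named override of the attitude-influence vector ``c``."""

    name: str
    c_override: tuple[float, float, float, float] | None
    description: str = ""

    def __post_init__(self) -> None:
        if self.c_override is not None:
            vec = np.asarray(self.c_override, dtype=float)
            if vec.shape != (4,):
                raise ValueError("c_override must have 4 entries")
            if np.any(vec < 0) or np.any(vec > 1):
                raise ValueError(f"c_override entries must be in [0, 1], got {vec}")
            object.__setattr__(self, "c_override", tuple(vec.tolist()))


#: Built-in scenario presets.  The mandate presets raise the attitude
#: influence of hesitant-containing couples; the inaccessibility presets
#: lower it for confident-containing couples.
SCENARIOS: dict[str, ScenarioConfig] = {
    s.name: s
    for s in (
        ScenarioConfig("baseline", None, "accessible vaccine, no mandate"),
        ScenarioConfig(
            "strict_mandate",
            (0.5, 0.9, 0.9, 0.99),
            "strict mandate: exemptions hard to obtain even for hesitant couples",
        ),
        ScenarioConfig(
            "less_strict_mandate",
            (0.3, 0.7, 0.7, 0.99),
            "less strict mandate: hesitant couples can still obtain exemptions",
        ),
        ScenarioConfig(
            "somewhat_inaccessible",
            (0.01, 0.3, 0.3, 0.7),
            "somewhat inaccessible vaccine: confidence only partially translates into vaccination",
        ),
        ScenarioConfig(
            "inaccessible",
            (0.01, 0.1, 0.1, 0.5),
            "inaccessible vaccine: vaccination rare regardless of attitudes",
        ),
    )
}


def apply_scenario(
    base: TransmissionParameters, scenario: ScenarioConfig | str
) -> TransmissionParameters:
    """Transmission parameters with the scenario's ``c`` override applied.

    ``C`` and ``b`` are untouched; the baseline scenario returns the input
    unchanged.  Unknown scenario names raise with the list of valid names.
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise KeyError(
                f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}"
            ) from None
    if scenario.c_override is None:
        return base
    return base.replace(c=scenario.c_override)


@dataclass(frozen=True)
class EquilibriumComparison:
    """Per-phenotype percent change of a scenario equilibrium vs baseline.

    ``percent_change[k] = 100 * (scenario[k] - baseline[k]) / baseline[k]``;
    a phenotype absent at baseline yields NaN (undefined, not infinite).
    """

    scenario_final: PhenotypeDistribution
    baseline_final: PhenotypeDistribution
    percent_change: tuple[float, float, float, float]

    @property
    def signs(self) -> tuple[str, ...]:
        """'increase' / 'decrease' / 'unchanged' / 'undefined' per phenotype."""
        out = []
        for pc in self.percent_change:
            if np.isnan(pc):
                out.append("undefined")
            elif pc > 0:
                out.append("increase")
            elif pc < 0:
                out.append("decrease")
            else:
                out.append("unchanged")
        return tuple(out)


def compare_to_baseline(
    scenario_trajectory: Trajectory, baseline_trajectory: Trajectory
) -> EquilibriumComparison:
    """Percent change of the scenario's final state from the baseline's."""
    s = scenario_trajectory.final.as_array()
    b = baseline_trajectory.final.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = np.where(b > 0, 100.0 * (s - b) / np.where(b > 0, b, 1.0), np.nan)
    return EquilibriumComparison(
        scenario_final=scenario_trajectory.final,
        baseline_final=baseline_trajectory.final,
        percent_change=tuple(pc.tolist()),
    )
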
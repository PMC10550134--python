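"""Run configuration: YAML/JSON loading with field-level validation.

A config file is a flat mapping; every key is optional and defaults to the
baseline parameterization (US-like initial phenotype frequencies, Mendelian-
like transmission probabilities, sigma_max = 0.1 with the mid-threshold
selection curve).  Unknown keys are rejected by name so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import IterationSettings, PhenotypeDistribution, TransmissionParameters
from .responses import ObliqueFunctions, SelectionFunction
from .scenarios import SCENARIOS

__all__ = ["RunConfig", "load_config", "DEFAULT_INITIAL_STATE"]

DEFAULT_INITIAL_STATE = (0.81, 0.10, 0.07, 0.02)

_TOP_LEVEL_KEYS = {
    "initial_distribution",
    "C",
    "b",
    "c",
    "scenario",
    "sigma",
    "oblique",
    "iterations",
    "seed",
    "output",
}
_SIGMA_KEYS = {"family", "sigma_max", "threshold_coverage", "steepness"}
_OBLIQUE_KEYS = {"max_transition", "midpoint_coverage", "steepness"}
_ITER_KEYS = {"max_iterations", "equilibrium_tolerance"}


class ConfigError(ValueError):
    """Invalid configuration, with the offending field in the message."""


@dataclass
class RunConfig:
    """Fully validated inputs for one model run."""

    initial_distribution: PhenotypeDistribution = field(
        default_factory=lambda: PhenotypeDistribution(*DEFAULT_INITIAL_STATE)
    )
    transmission: TransmissionParameters = field(default_factory=TransmissionParameters.baseline)
    selection: SelectionFunction = field(default_factory=SelectionFunction)
    oblique: ObliqueFunctions = field(default_factory=ObliqueFunctions)
    scenario: str = "baseline"
    settings: IterationSettings = field(default_factory=IterationSettings)
    seed: int = 0
    output: str | None = None


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown {context} key(s): {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _vector(raw, name: str) -> tuple[float, float, float, float]:
    try:
        vec = tuple(float(x) for x in raw)
    except (TypeError, ValueError):
        raise ConfigError(f"{name} must be a sequence of 4 numbers, got {raw!r}") from None
    if len(vec) != 4:
        raise ConfigError(f"{name} must have exactly 4 entries, got {len(vec)}")
    for i, x in enumerate(vec):
        if not (0.0 <= x <= 1.0):
            raise ConfigError(f"{name}[{i}] = {x} is out of range [0, 1]")
    return vec


def from_mapping(data: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain mapping."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    _check_keys(data, _TOP_LEVEL_KEYS, "config")

    base = TransmissionParameters.baseline()
    kwargs: dict = {}

    if "initial_distribution" in data:
        vec = _vector(data["initial_distribution"], "initial_distribution")
        try:
            kwargs["initial_distribution"] = PhenotypeDistribution(*vec)
        except ValueError as exc:
            raise ConfigError(f"initial_distribution: {exc}") from None

    trans = {"C": base.C, "b": base.b, "c": base.c}
    for name in ("C", "b", "c"):
        if name in data:
            trans[name] = _vector(data[name], name)
    kwargs["transmission"] = TransmissionParameters(**trans)

    if "scenario" in data:
        name = str(data["scenario"])
        if name not in SCENARIOS:
            raise ConfigError(f"scenario: unknown name {name!r}; available: {sorted(SCENARIOS)}")
        kwargs["scenario"] = name

    if "sigma" in data:
        sig = dict(data["sigma"])
        _check_keys(sig, _SIGMA_KEYS, "sigma")
        try:
            kwargs["selection"] = SelectionFunction(**sig)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"sigma: {exc}") from None

    if "oblique" in data:
        obl = dict(data["oblique"])
        _check_keys(obl, _OBLIQUE_KEYS, "oblique")
        try:
            kwargs["oblique"] = ObliqueFunctions(**obl)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"oblique: {exc}") from None

    if "iterations" in data:
        it = dict(data["iterations"])
        _check_keys(it, _ITER_KEYS, "iterations")
        try:
            kwargs["settings"] = IterationSettings(**it)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"iterations: {exc}") from None

    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "output" in data:
        kwargs["output"] = str(data["output"])

    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config file.

    An empty file yields the full baseline configuration.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text)
    return from_mapping(data)
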
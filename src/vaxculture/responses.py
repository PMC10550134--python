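"""Coverage-dependent response curves.

Two families of curves close the feedback loop between population-level
vaccination coverage and individual behavior:

* the cultural selection coefficient sigma(v), the perceived net benefit of
  vaccinating at coverage v — high when disease is visible (low coverage),
  declining once coverage masks the disease ("herd immunity" in the perception
  sense, not the epidemiological one);
* the oblique attitude-transition probabilities, by which non-parental
  community influence flips attitudes: hesitant adults adopt confidence when
  coverage is low and disease is salient, confident adults adopt hesitancy
  when coverage is high and vaccine risks dominate perception.

The exact curves are configuration, not constants: every family is controlled
by (sigma_max, threshold, steepness) so alternative calibrations drop in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.special import expit

__all__ = ["SelectionFunction", "ObliqueFunctions", "SELECTION_FAMILIES"]

#: Recognized sigma-curve families, each weakly decreasing in coverage except
#: ``constant``.  The three threshold families differ only in where the
#: decline is centred (0.9 / 0.7 / 0.5 coverage).
SELECTION_FAMILIES = (
    "constant",
    "threshold_high",
    "threshold_mid",
    "threshold_low",
    "linear",
    "cubic",
)

_THRESHOLDS = {"threshold_high": 0.9, "threshold_mid": 0.7, "threshold_low": 0.5}


def _check_unit(v: float, name: str = "coverage") -> float:
    v = float(v)
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {v}")
    return v


@dataclass(frozen=True)
class SelectionFunction:
    """Cultural selection coefficient sigma as a function of coverage.

    ``sigma_max`` bounds the coefficient in magnitude (default 0.1, the
    conventional scale of selection coefficients); every family satisfies
    ``|sigma(v)| <= sigma_max`` and ``sigma(0) ~ sigma_max``.

    Families:

    ``constant``
        sigma(v) = sigma_max, coverage-independent.
    ``threshold_high`` / ``threshold_mid`` / ``threshold_low``
        sigma_max * (1 - 2 * L((v - v0) / s)) with L the standard logistic;
        a plateau at sigma_max below the threshold v0 (0.9 / 0.7 / 0.5),
        crossing zero at v0 and approaching -sigma_max above.
    ``linear``
        sigma_max * (1 - 2 v): zero at v = 0.5, -sigma_max at v = 1.
    ``cubic``
        sigma_max * (1 - 2 v^3): a slow initial decline, steep near full
        coverage.
    """

    family: str = "threshold_mid"
    sigma_max: float = 0.1
    threshold_coverage: float | None = None
    steepness: float = 0.05

    def __post_init__(self) -> None:
        if self.family not in SELECTION_FAMILIES:
            raise ValueError(
                f"unknown selection family {self.family!r}; choose from {SELECTION_FAMILIES}"
            )
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.threshold_coverage is None and self.family in _THRESHOLDS:
            object.__setattr__(self, "threshold_coverage", _THRESHOLDS[self.family])
        if self.threshold_coverage is not None:
            _check_unit(self.threshold_coverage, "threshold_coverage")

    def __call__(self, v: float) -> float:
        v = _check_unit(v)
        if self.family == "constant":
            return self.sigma_max
        if self.family in _THRESHOLDS:
            z = (v - self.threshold_coverage) / self.steepness
            return self.sigma_max * (1.0 - 2.0 * float(expit(z)))
        if self.family == "linear":
            return self.sigma_max * (1.0 - 2.0 * v)
        # cubic
        return self.sigma_max * (1.0 - 2.0 * v**3)

    def with_sigma_max(self, sigma_max: float) -> "SelectionFunction":
        """Same curve shape with a different amplitude (used by sweeps)."""
        return _dc_replace(self, sigma_max=sigma_max)

    def grid(self, n: int = 101) -> tuple[np.ndarray, np.ndarray]:
        """Curve sampled on a uniform coverage grid (for plotting/inspection)."""
        v = np.linspace(0.0, 1.0, n)
        return v, np.array([self(x) for x in v])


@dataclass(frozen=True)
class ObliqueFunctions:
    """Coverage-dependent attitude-transition probabilities.

    Mirrored logistic curves around ``midpoint_coverage``:

    * ``hesitant_to_confident(v) = max_transition * (1 - L((v - mid) / s))``,
      decreasing in coverage — hesitant individuals adopt confidence when the
      disease is visible;
    * ``confident_to_hesitant(v) = max_transition * L((v - mid) / s)``,
      increasing in coverage — confident individuals adopt hesitancy when the
      disease is masked.

    ``max_transition`` caps the per-generation switching probability (default
    0.1, small relative to vertical transmission so parental transmission
    dominates the dynamics).  The two defaults sum to ``max_transition`` at
    every coverage.
    """

    max_transition: float = 0.1
    midpoint_coverage: float = 0.5
    steepness: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_transition <= 1.0):
            raise ValueError("max_transition must be in [0, 1]")
        _check_unit(self.midpoint_coverage, "midpoint_coverage")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def hesitant_to_confident(self, v: float) -> float:
        v = _check_unit(v)
        z = (v - self.midpoint_coverage) / self.steepness
        return self.max_transition * (1.0 - float(expit(z)))

    def confident_to_hesitant(self, v: float) -> float:
        v = _check_unit(v)
        z = (v - self.midpoint_coverage) / self.steepness
        return self.max_transition * float(expit(z))

    @classmethod
    def none(cls) -> "ObliqueFunctions":
        """No oblique transmission (both transition probabilities zero)."""
        return cls(max_transition=0.0)
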
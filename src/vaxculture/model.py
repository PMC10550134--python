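"""Deterministic recursion for coupled vaccination-behavior / vaccine-attitude dynamics.

The population is described by the frequencies of four phenotypes combining a
binary vaccination state (V+ vaccinated / V- unvaccinated) with a binary
attitude state (A+ confident / A- hesitant).  One generation consists of

1. random mating (all 16 ordered parental pairs, product frequencies),
2. vertical transmission: a pair with vaccination subscript ``m`` and attitude
   subscript ``n`` vaccinates its offspring with probability
   ``B[m, n] = c[n] * (1 + b[m]) / 2`` and transmits confidence with
   probability ``C[n]``, the two draws independent given the pair,
3. frequency-dependent cultural selection multiplying both vaccinated
   phenotypes by ``1 + sigma`` followed by renormalization,
4. oblique transmission: attitude switching within each vaccination class at
   coverage-dependent probabilities, leaving coverage unchanged.

The recursion is iterated until phenotype frequencies stop changing (or a hard
iteration cap is hit).  Everything here is deterministic; a finite-population
stochastic counterpart lives in :mod:`vaxculture.abm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PHENOTYPE_LABELS",
    "PhenotypeDistribution",
    "TransmissionParameters",
    "IterationSettings",
    "Trajectory",
    "pair_subscript",
    "vaccination_probability",
    "vertical_step",
    "selection_step",
    "oblique_step",
    "step",
    "iterate",
]

#: Phenotype order used throughout: index 0..3.
PHENOTYPE_LABELS = ("VpAp", "VpAm", "VmAp", "VmAm")

# Presence indicator of each trait per phenotype index (V, A), same order.
_V_BIT = np.array([1, 1, 0, 0])
_A_BIT = np.array([1, 0, 1, 0])

_SUM_TOL = 1e-9


def pair_subscript(trait_parent1: str, trait_parent2: str) -> int:
    """Index of an ordered parental trait pair.

    The convention is ``-x- -> 0``, ``-x+ -> 1``, ``+x- -> 2``, ``+x+ -> 3``,
    applied identically to vaccination pairs (subscript ``m``) and attitude
    pairs (subscript ``n``).
    """
    lookup = {"+": 1, "-": 0, "−": 0}  # accept ASCII or Unicode minus
    try:
        p1, p2 = lookup[trait_parent1], lookup[trait_parent2]
    except KeyError as exc:
        raise ValueError(f"trait states must be '+' or '-', got {exc.args[0]!r}") from None
    return 2 * p1 + p2


def vaccination_probability(b_m: float, c_n: float) -> float:
    """Probability ``B = c_n * (1 + b_m) / 2`` that a couple vaccinates its offspring.

    ``b_m`` is the influence of the parents' own vaccination states, ``c_n``
    the influence of their attitudes.  Both must lie in [0, 1]; the result is
    then guaranteed to lie in [0, 1].
    """
    if not (0.0 <= b_m <= 1.0):
        raise ValueError(f"b_m must be in [0, 1], got {b_m}")
    if not (0.0 <= c_n <= 1.0):
        raise ValueError(f"c_n must be in [0, 1], got {c_n}")
    return c_n * (1.0 + b_m) / 2.0


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Frequencies of the four phenotypes V+A+, V+A-, V-A+, V-A-."""

    freq_VpAp: float
    freq_VpAm: float
    freq_VmAp: float
    freq_VmAm: float

    def __post_init__(self) -> None:
        f = self.as_array()
        if np.any(f < 0):
            raise ValueError(f"phenotype frequencies must be non-negative, got {f}")
        if abs(f.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"phenotype frequencies must sum to 1, got sum={f.sum()!r}")

    @classmethod
    def from_array(cls, freqs: Sequence[float], *, renormalize: bool = False) -> "PhenotypeDistribution":
        f = np.asarray(freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError(f"expected 4 phenotype frequencies, got shape {f.shape}")
        if renormalize:
            total = f.sum()
            if total <= 0:
                raise ValueError("cannot renormalize a distribution with non-positive mass")
            f = f / total
        return cls(*f.tolist())

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.freq_VpAp, self.freq_VpAm, self.freq_VmAp, self.freq_VmAm], dtype=float
        )

    @property
    def coverage(self) -> float:
        """Frequency of the vaccinated (V+) trait."""
        return self.freq_VpAp + self.freq_VpAm

    @property
    def confidence(self) -> float:
        """Frequency of the vaccine-confident (A+) trait."""
        return self.freq_VpAp + self.freq_VmAp

    def max_abs_difference(self, other: "PhenotypeDistribution") -> float:
        return float(np.max(np.abs(self.as_array() - other.as_array())))


@dataclass(frozen=True)
class TransmissionParameters:
    """Pair-indexed transmission probabilities C_n, b_m, c_n.

    Each is a 4-vector over ordered parental pairs with the subscript
    convention of :func:`pair_subscript`.  ``C`` is the probability of
    transmitting confidence, ``b`` the vaccination-state influence and ``c``
    the attitude influence on the vaccination decision; the joint vaccination
    probability ``B[m, n]`` is always computed, never stored.
    """

    C: tuple[float, float, float, float]
    b: tuple[float, float, float, float]
    c: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name in ("C", "b", "c"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (4,):
                raise ValueError(f"{name} must have 4 entries, got shape {vec.shape}")
            if np.any(vec < 0) or np.any(vec > 1):
                raise ValueError(f"{name} entries must be in [0, 1], got {vec}")
            object.__setattr__(self, name, tuple(vec.tolist()))

    @classmethod
    def baseline(cls) -> "TransmissionParameters":
        """Mendelian-like baseline: homogeneous pairs near-certain, mixed pairs 0.5."""
        v = (0.01, 0.5, 0.5, 0.99)
        return cls(C=v, b=v, c=v)

    def vaccination_matrix(self) -> np.ndarray:
        """4x4 matrix ``B[m, n] = c[n] * (1 + b[m]) / 2``."""
        b = np.asarray(self.b)
        c = np.asarray(self.c)
        return c[None, :] * (1.0 + b[:, None]) / 2.0

    def replace(self, **kwargs) -> "TransmissionParameters":
        data = {"C": self.C, "b": self.b, "c": self.c}
        data.update(kwargs)
        return TransmissionParameters(**data)


@dataclass(frozen=True)
class IterationSettings:
    """Run-control settings for :func:`iterate`.

    ``sigma_coverage_timing`` fixes the coverage at which the selection
    coefficient is evaluated (the generation entering the iteration);
    ``oblique_coverage_timing`` fixes the coverage driving attitude switching
    (the offspring generation after selection).  Both are recorded explicitly
    so alternative orderings remain visible in serialized runs.
    """

    max_iterations: int = 100
    equilibrium_tolerance: float = 1e-8
    sigma_coverage_timing: str = "previous_generation"
    oblique_coverage_timing: str = "post_selection"

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.equilibrium_tolerance <= 0:
            raise ValueError("equilibrium_tolerance must be > 0")
        if self.sigma_coverage_timing != "previous_generation":
            raise ValueError("sigma_coverage_timing: only 'previous_generation' is supported")
        if self.oblique_coverage_timing != "post_selection":
            raise ValueError("oblique_coverage_timing: only 'post_selection' is supported")


@dataclass
class Trajectory:
    """Record of an iterated run: every state, the sigma applied per step."""

    states: list[PhenotypeDistribution] = field(default_factory=list)
    sigma_series: list[float] = field(default_factory=list)
    reached_equilibrium: bool = False
    equilibrium_iteration: int | None = None

    @property
    def initial(self) -> PhenotypeDistribution:
        return self.states[0]

    @property
    def final(self) -> PhenotypeDistribution:
        return self.states[-1]

    @property
    def n_iterations(self) -> int:
        return len(self.states) - 1

    def to_dataframe(self):
        """Long table: one row per recorded state (the initial row has sigma = NaN)."""
        import pandas as pd

        arr = np.array([s.as_array() for s in self.states])
        sigma = np.concatenate([[np.nan], np.asarray(self.sigma_series, dtype=float)])
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.states)),
                "freq_VpAp": arr[:, 0],
                "freq_VpAm": arr[:, 1],
                "freq_VmAp": arr[:, 2],
                "freq_VmAm": arr[:, 3],
                "coverage": arr[:, 0] + arr[:, 1],
                "confidence": arr[:, 0] + arr[:, 2],
                "sigma": sigma,
            }
        )


def _vertical_step_array(freqs: np.ndarray, params: TransmissionParameters) -> np.ndarray:
    # Ordered-pair enumeration, vectorized over the 4x4 pair grid.
    m = 2 * _V_BIT[:, None] + _V_BIT[None, :]  # vaccination pair subscript
    n = 2 * _A_BIT[:, None] + _A_BIT[None, :]  # attitude pair subscript
    B = params.vaccination_matrix()[m, n]  # P(offspring V+) per ordered pair
    Cn = np.asarray(params.C)[n]  # P(offspring A+) per ordered pair
    pair_freq = np.outer(freqs, freqs)
    out = np.array(
        [
            np.sum(pair_freq * B * Cn),
            np.sum(pair_freq * B * (1.0 - Cn)),
            np.sum(pair_freq * (1.0 - B) * Cn),
            np.sum(pair_freq * (1.0 - B) * (1.0 - Cn)),
        ]
    )
    return out / out.sum()  # absorb floating-point drift


def vertical_step(
    dist: PhenotypeDistribution, params: TransmissionParameters
) -> PhenotypeDistribution:
    """Offspring distribution under random mating and vertical transmission.

    All 16 ordered parental pairs are enumerated with pair frequency equal to
    the product of the parental phenotype frequencies; offspring traits are
    drawn independently given the pair (V+ with probability ``B[m, n]``, A+
    with probability ``C[n]``).
    """
    return PhenotypeDistribution.from_array(_vertical_step_array(dist.as_array(), params))


def selection_step(dist: PhenotypeDistribution, sigma: float) -> PhenotypeDistribution:
    """Multiply both V+ phenotypes by ``1 + sigma`` and renormalize.

    Within-class ratios (V+A+ : V+A- and V-A+ : V-A-) are preserved.  A sigma
    of -1 or below would annihilate the vaccinated class and is rejected
    whenever that class carries mass.
    """
    f = dist.as_array()
    if sigma <= -1.0 and (f[0] + f[1]) > 0:
        raise ValueError(f"sigma must exceed -1 when V+ mass is present, got {sigma}")
    weights = np.array([1.0 + sigma, 1.0 + sigma, 1.0, 1.0])
    return PhenotypeDistribution.from_array(f * weights, renormalize=True)


def oblique_step(
    dist: PhenotypeDistribution, p_hes_to_conf: float, p_conf_to_hes: float
) -> PhenotypeDistribution:
    """Community-driven attitude switching within each vaccination class.

    A- mass moves to A+ with probability ``p_hes_to_conf`` and A+ mass to A-
    with probability ``p_conf_to_hes``; the vaccination marginal (coverage) is
    conserved exactly.
    """
    for name, p in (("p_hes_to_conf", p_hes_to_conf), ("p_conf_to_hes", p_conf_to_hes)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    f = dist.as_array()
    out = np.empty(4)
    out[0], out[1] = _switch_within_class(f[0], f[1], p_hes_to_conf, p_conf_to_hes)
    out[2], out[3] = _switch_within_class(f[2], f[3], p_hes_to_conf, p_conf_to_hes)
    return PhenotypeDistribution.from_array(out)


def _switch_within_class(
    f_conf: float, f_hes: float, p_hes_to_conf: float, p_conf_to_hes: float
) -> tuple[float, float]:
    """Attitude switching within one vaccination class, conserving its total
    bit-exactly.

    The larger post-switch share is computed directly; the smaller is taken
    as the complement against the class total, a subtraction that is exact by
    the Sterbenz lemma (the minuend and subtrahend are within a factor of
    two), so the two shares re-sum to exactly ``f_conf + f_hes``.
    """
    total = f_conf + f_hes
    conf = f_conf * (1.0 - p_conf_to_hes) + f_hes * p_hes_to_conf
    hes = f_hes * (1.0 - p_hes_to_conf) + f_conf * p_conf_to_hes
    if conf >= hes:
        return conf, max(total - conf, 0.0)
    return max(total - hes, 0.0), hes


def step(
    dist: PhenotypeDistribution,
    params: TransmissionParameters,
    selection_fn: Callable[[float], float],
    oblique_fns,
    settings: IterationSettings | None = None,
) -> tuple[PhenotypeDistribution, float]:
    """One full generation; returns the new distribution and the sigma applied.

    Order of events: sigma is evaluated at the coverage of the generation
    entering the step (the parents), then vertical transmission, then cultural
    selection with that sigma, then oblique attitude switching with transition
    probabilities evaluated at the post-selection offspring coverage.

    ``oblique_fns`` must expose ``hesitant_to_confident(v)`` and
    ``confident_to_hesitant(v)`` (see :class:`vaxculture.responses.ObliqueFunctions`).
    """
    if settings is None:
        settings = IterationSettings()
    sigma = float(selection_fn(dist.coverage))
    offspring = vertical_step(dist, params)
    selected = selection_step(offspring, sigma)
    v_post = selected.coverage
    new = oblique_step(
        selected,
        oblique_fns.hesitant_to_confident(v_post),
        oblique_fns.confident_to_hesitant(v_post),
    )
    return new, sigma


def iterate(
    dist0: PhenotypeDistribution,
    params: TransmissionParameters,
    selection_fn: Callable[[float], float],
    oblique_fns,
    settings: IterationSettings | None = None,
) -> Trajectory:
    """Iterate :func:`step` to equilibrium or the iteration cap.

    Equilibrium is declared (and iteration stops) at the first iteration whose
    largest absolute phenotype-frequency change falls below
    ``settings.equilibrium_tolerance``; otherwise the run ends at
    ``max_iterations`` with ``reached_equilibrium`` left False.
    """
    if settings is None:
        settings = IterationSettings()
    traj = Trajectory(states=[dist0])
    current = dist0
    for t in range(1, settings.max_iterations + 1):
        new, sigma = step(current, params, selection_fn, oblique_fns, settings)
        traj.states.append(new)
        traj.sigma_series.append(sigma)
        if not traj.reached_equilibrium:
            if new.max_abs_difference(current) < settings.equilibrium_tolerance:
                traj.reached_equilibrium = True
                traj.equilibrium_iteration = t
        current = new
        if traj.reached_equilibrium:
            break
    return traj
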
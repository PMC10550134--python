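"""Shared fixtures and the independent brute-force oracle.

The oracle re-derives one full generation by explicit looping over the 16
ordered parental pairs and literal transcription of the transmission rules,
deliberately sharing no code with the vectorized implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from vaxculture import (
    IterationSettings,
    ObliqueFunctions,
    PhenotypeDistribution,
    SelectionFunction,
    TransmissionParameters,
)

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")

# phenotype order (V, A) presence flags: VpAp, VpAm, VmAp, VmAm
PHENOTYPE_TRAITS = [(1, 1), (1, 0), (0, 1), (0, 0)]


def brute_force_generation(freqs, C, b, c, sigma, p_hes_to_conf, p_conf_to_hes):
    """One generation computed loop-wise from first principles.

    Vertical transmission over all ordered pairs, selection by (1 + sigma)
    on vaccinated phenotypes with renormalization, then attitude switching
    within each vaccination class.  Pure Python floats throughout.
    """
    off = [0.0, 0.0, 0.0, 0.0]
    for i, (V1, A1) in enumerate(PHENOTYPE_TRAITS):
        for j, (V2, A2) in enumerate(PHENOTYPE_TRAITS):
            pair_freq = freqs[i] * freqs[j]
            m = 2 * V1 + V2
            n = 2 * A1 + A2
            B = c[n] * (1.0 + b[m]) / 2.0
            off[0] += pair_freq * B * C[n]
            off[1] += pair_freq * B * (1.0 - C[n])
            off[2] += pair_freq * (1.0 - B) * C[n]
            off[3] += pair_freq * (1.0 - B) * (1.0 - C[n])
    total = sum(off)
    off = [f / total for f in off]

    w = [1.0 + sigma, 1.0 + sigma, 1.0, 1.0]
    sel = [f * wi for f, wi in zip(off, w)]
    total = sum(sel)
    sel = [f / total for f in sel]

    out = [
        sel[0] * (1.0 - p_conf_to_hes) + sel[1] * p_hes_to_conf,
        sel[1] * (1.0 - p_hes_to_conf) + sel[0] * p_conf_to_hes,
        sel[2] * (1.0 - p_conf_to_hes) + sel[3] * p_hes_to_conf,
        sel[3] * (1.0 - p_hes_to_conf) + sel[2] * p_conf_to_hes,
    ]
    return out


def logistic(x):
    return 1.0 / (1.0 + math.exp(-x))


@pytest.fixture
def baseline_params() -> TransmissionParameters:
    return TransmissionParameters.baseline()


@pytest.fixture
def initial_state() -> PhenotypeDistribution:
    """US-like starting frequencies used throughout the scenario analyses."""
    return PhenotypeDistribution(0.81, 0.10, 0.07, 0.02)


@pytest.fixture
def default_selection() -> SelectionFunction:
    return SelectionFunction()


@pytest.fixture
def default_oblique() -> ObliqueFunctions:
    return ObliqueFunctions()


@pytest.fixture
def settings_100() -> IterationSettings:
    return IterationSettings(max_iterations=100)


def random_distribution(rng: np.random.Generator) -> PhenotypeDistribution:
    f = rng.dirichlet(np.ones(4))
    return PhenotypeDistribution.from_array(f, renormalize=True)


def random_params(rng: np.random.Generator) -> TransmissionParameters:
    return TransmissionParameters(
        C=tuple(rng.random(4)), b=tuple(rng.random(4)), c=tuple(rng.random(4))
    )
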
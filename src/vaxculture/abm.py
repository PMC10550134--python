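"""Finite-population agent-based counterpart of the deterministic recursion.

Each replicate tracks N individual agents through the same generation
structure as :func:`vaxculture.model.step`: random pairing, per-pair
Bernoulli transmission of vaccination and attitude, selection as weighted
resampling of offspring (weight 1 + sigma for vaccinated offspring, matching
the deterministic multiply-and-renormalize in expectation), and per-agent
Bernoulli attitude switching.  As N grows, phenotype frequencies converge to
the deterministic trajectory at the usual sqrt(p(1-p)/N) scale, which makes
this an independent stochastic cross-check of the recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import IterationSettings, PhenotypeDistribution, TransmissionParameters
from .responses import ObliqueFunctions, SelectionFunction

__all__ = ["AgentPopulation", "ABMResult", "simulate_abm"]

# Phenotype codes 0..3 follow the deterministic module's order
# (VpAp, VpAm, VmAp, VmAm); V = code < 2, A = code even.
_V_OF_CODE = np.array([1, 1, 0, 0])
_A_OF_CODE = np.array([1, 0, 1, 0])


@dataclass
class AgentPopulation:
    """A finite population of phenotype-coded agents."""

    population_size: int
    agent_states: np.ndarray  # int codes 0..3, length N
    rng_seed: int

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        self.agent_states = np.asarray(self.agent_states, dtype=np.int64)
        if self.agent_states.shape != (self.population_size,):
            raise ValueError("agent_states length must equal population_size")

    def frequencies(self) -> np.ndarray:
        return np.bincount(self.agent_states, minlength=4) / self.population_size


@dataclass
class ABMResult:
    """Per-iteration phenotype frequencies across replicates.

    ``frequencies`` has shape (replicates, n_iterations + 1, 4), including
    the initial state.  ``mean`` and ``se`` aggregate across replicates;
    with one replicate the SE is the binomial sampling scale
    sqrt(p(1-p)/N) instead of a between-replicate estimate.
    """

    frequencies: np.ndarray
    population_size: int
    seed: int

    @property
    def mean(self) -> np.ndarray:
        return self.frequencies.mean(axis=0)

    @property
    def se(self) -> np.ndarray:
        r = self.frequencies.shape[0]
        if r > 1:
            return self.frequencies.std(axis=0, ddof=1) / np.sqrt(r)
        p = self.frequencies[0]
        return np.sqrt(p * (1.0 - p) / self.population_size)

    def to_dataframe(self):
        import pandas as pd

        m, s = self.mean, self.se
        n_states = m.shape[0]
        cols = {"iteration": np.arange(n_states)}
        for k, lab in enumerate(("VpAp", "VpAm", "VmAp", "VmAm")):
            cols[f"freq_{lab}"] = m[:, k]
            cols[f"se_{lab}"] = s[:, k]
        cols["coverage"] = m[:, 0] + m[:, 1]
        cols["confidence"] = m[:, 0] + m[:, 2]
        return pd.DataFrame(cols)


def _one_replicate(
    dist0: np.ndarray,
    params: TransmissionParameters,
    selection_fn,
    oblique_fns: ObliqueFunctions,
    n_iterations: int,
    n_agents: int,
    rng: np.random.Generator,
) -> np.ndarray:
    B = params.vaccination_matrix()
    Cn = np.asarray(params.C)
    agents = rng.choice(4, size=n_agents, p=dist0)
    freqs = np.empty((n_iterations + 1, 4))
    freqs[0] = np.bincount(agents, minlength=4) / n_agents
    half = n_agents // 2
    for t in range(1, n_iterations + 1):
        parental_coverage = np.mean(_V_OF_CODE[agents])
        sigma = float(selection_fn(parental_coverage))

        # random pairing: a permutation split into N/2 ordered pairs
        perm = rng.permutation(n_agents)
        p1, p2 = agents[perm[:half]], agents[perm[half:]]
        m = 2 * _V_OF_CODE[p1] + _V_OF_CODE[p2]
        n = 2 * _A_OF_CODE[p1] + _A_OF_CODE[p2]
        # each pair produces 2 offspring, keeping N constant
        b_pair = np.repeat(B[m, n], 2)
        c_pair = np.repeat(Cn[n], 2)
        off_v = rng.random(n_agents) < b_pair
        off_a = rng.random(n_agents) < c_pair
        offspring = np.where(off_v, np.where(off_a, 0, 1), np.where(off_a, 2, 3))

        # selection: weighted resampling, weight 1+sigma for vaccinated
        weights = np.where(offspring < 2, 1.0 + sigma, 1.0)
        if np.any(weights < 0):
            raise ValueError(f"sigma {sigma} produces negative selection weights")
        agents = offspring[rng.choice(n_agents, size=n_agents, p=weights / weights.sum())]

        # oblique attitude switching at post-selection coverage
        v_post = np.mean(_V_OF_CODE[agents])
        p_hc = oblique_fns.hesitant_to_confident(v_post)
        p_ch = oblique_fns.confident_to_hesitant(v_post)
        u = rng.random(n_agents)
        is_conf = _A_OF_CODE[agents] == 1
        flip = np.where(is_conf, u < p_ch, u < p_hc)
        agents = np.where(flip, agents + np.where(is_conf, 1, -1), agents)

        freqs[t] = np.bincount(agents, minlength=4) / n_agents
    return freqs


def simulate_abm(
    dist0: PhenotypeDistribution,
    params: TransmissionParameters,
    selection_fn: SelectionFunction,
    oblique_fns: ObliqueFunctions,
    settings: IterationSettings | None = None,
    n_agents: int = 10_000,
    seed: int = 0,
    replicates: int = 1,
) -> ABMResult:
    """Simulate the stochastic model; reproducible given ``seed``.

    Replicates receive independent streams via seed sequencing, so no two
    replicates share a random stream, and the full result is a pure function
    of (inputs, seed, replicates).  Runs for ``settings.max_iterations``
    generations (the stochastic model has no exact equilibrium to detect).
    """
    settings = settings or IterationSettings()
    if n_agents < 2 or n_agents % 2:
        raise ValueError("n_agents must be even and >= 2")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    d0 = dist0.as_array()
    children = np.random.SeedSequence(seed).spawn(replicates)
    out = np.empty((replicates, settings.max_iterations + 1, 4))
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        out[r] = _one_replicate(
            d0, params, selection_fn, oblique_fns, settings.max_iterations, n_agents, rng
        )
    return ABMResult(frequencies=out, population_size=n_agents, seed=seed)
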
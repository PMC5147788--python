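"""Population Monte Carlo over parallel Gibbs chains.

Many chains explore the posterior independently for a round of sweeps; the
round's final states are then resampled (with replacement) proportionally
to importance weights — posterior probability divided by the product of
transition densities accumulated since the last reinitialisation — so the
population concentrates on the most promising regions without losing the
within-round independence of the chains.  The first link sweep of each
round runs at a high temperature to encourage exploration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import GPSpec, NodeTimecourses, NoiseState
from .sampler import (
    ChainState,
    SamplerConfig,
    hyperparameter_sweep,
    init_chain,
    link_sweep,
)
from .spatial import AdjacencyGraph, SizePrior

__all__ = [
    "PopulationConfig",
    "importance_log_weight",
    "resample_population",
    "run_population",
]


@dataclass
class PopulationConfig:
    """Population-MC schedule.

    Defaults follow the whole-brain protocol: 50 chains, one hyperparameter
    sweep plus 11 link sweeps per round, the first link sweep tempered at
    1000 (log assignment-probabilities multiplied by 0.001).
    """

    n_chains: int = 50
    link_sweeps_per_round: int = 11
    first_sweep_temperature: float = 1000.0
    n_rounds: int = 100
    seed: int = 0
    init_n_clusters: int = 20
    scan_order: str = "shuffled"
    sample_hyperparameters: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.first_sweep_temperature < 1:
            raise ValueError("temperature must be >= 1")


def importance_log_weight(chain: ChainState) -> float:
    """log importance weight: log posterior minus accumulated log transition
    densities since the last reinitialisation."""
    return chain.log_post - chain.log_transition_accum


def resample_population(
    chains: list[ChainState], rng: np.random.Generator
) -> list[ChainState]:
    """Multinomial reinitialisation proportional to normalised weights.

    Every selected state is copied and its transition accumulator reset.
    """
    if not chains:
        raise ValueError("empty population")
    logw = np.asarray([importance_log_weight(c) for c in chains])
    finite = np.isfinite(logw)
    if not finite.any():
        raise FloatingPointError("all importance weights are -inf")
    logw = logw - logw[finite].max()
    w = np.where(finite, np.exp(np.where(finite, logw, -np.inf)), 0.0)
    w /= w.sum()
    idx = rng.choice(len(chains), size=len(chains), replace=True, p=w)
    out = []
    for i in idx:
        c = chains[int(i)].copy()
        c.log_transition_accum = 0.0
        out.append(c)
    return out


def run_population(
    data: NodeTimecourses,
    graph: AdjacencyGraph,
    config: PopulationConfig,
    spec: GPSpec | None = None,
    size_prior: SizePrior | None = None,
    noise: NoiseState | None = None,
) -> dict:
    """Run the population sampler; returns all samples and the MAP state.

    Per round and per chain: one hyperparameter sweep, then
    ``link_sweeps_per_round`` link sweeps with the first at
    ``first_sweep_temperature`` and the rest at temperature 1.  Each chain's
    end-of-round partition is recorded as a sample, then the population is
    resampled by importance weight.  The sample with the highest log
    posterior approximates the MAP solution.
    """
    spec = spec or GPSpec()
    master = np.random.SeedSequence(config.seed)
    chain_seeds = master.spawn(config.n_chains)
    resample_rng = np.random.Generator(np.random.PCG64(master.spawn(1)[0]))
    chain_rngs = [np.random.Generator(np.random.PCG64(s)) for s in chain_seeds]
    chains = [
        init_chain(
            data, graph, spec, size_prior, config.init_n_clusters,
            chain_rngs[j], noise,
        )
        for j in range(config.n_chains)
    ]
    samples: list[np.ndarray] = []
    log_posts: list[float] = []
    weight_trace: list[np.ndarray] = []
    best_state: ChainState | None = None
    for _ in range(config.n_rounds):
        for j, chain in enumerate(chains):
            rng = chain_rngs[j]
            if config.sample_hyperparameters:
                hyperparameter_sweep(chain, rng)
            for sweep in range(config.link_sweeps_per_round):
                temp = config.first_sweep_temperature if sweep == 0 else 1.0
                link_sweep(chain, temp, rng, config.scan_order)
            samples.append(chain.link_state.labels())
            log_posts.append(chain.log_post)
            if best_state is None or chain.log_post > best_state.log_post:
                best_state = chain.copy()
        weight_trace.append(
            np.asarray([importance_log_weight(c) for c in chains])
        )
        chains = resample_population(chains, resample_rng)
    return {
        "samples": samples,
        "log_posts": np.asarray(log_posts),
        "map_state": best_state,
        "map_labels": best_state.link_state.labels(),
        "weight_trace": np.vstack(weight_trace),
    }
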
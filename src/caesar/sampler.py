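"""Collapsed Gibbs sampling over dd-CRP link assignments.

Resampling a single link lambda_i is the whole split-merge machinery: the
link is removed (possibly splitting node i's cluster) and the conditional

    p(lambda_i = m | lambda_-i, Y) propto p(lambda_i = m | A) * L(m)

is sampled, where L(m) is the marginal-likelihood ratio of merging i's
cluster with m's cluster (1 when m already shares i's cluster).  All
likelihood terms come from the batch cache in O(T); no O(T^3) work happens
inside a sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import (
    BatchCache,
    GPSpec,
    NodeTimecourses,
    NoiseState,
    build_batch_cache,
    sample_cluster_timecourse,
    sample_noise,
    total_log_posterior,
)
from .spatial import AdjacencyGraph, LinkState, SizePrior

__all__ = [
    "SamplerConfig",
    "ChainState",
    "gibbs_update_link",
    "run_chain",
    "coassignment_mean",
    "consensus_partition",
]


@dataclass
class SamplerConfig:
    """Single-chain protocol settings.

    Defaults follow the standard protocol: 50 burn-in sweeps, 100 retained
    partition samples, consensus threshold 0.9, then 50 further samples of
    timecourses and hyperparameters at the fixed consensus partition.
    """

    n_burnin: int = 50
    n_samples: int = 100
    n_timecourse_samples: int = 50
    coassign_threshold: float = 0.9
    temperature: float = 1.0
    seed: int = 0
    scan_order: str = "shuffled"
    init_n_clusters: int = 20
    sample_hyperparameters: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.coassign_threshold <= 1.0):
            raise ValueError("coassign_threshold must be in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.scan_order not in ("fixed", "shuffled"):
            raise ValueError("scan_order must be 'fixed' or 'shuffled'")


class ChainState:
    """Everything one Gibbs chain carries between sweeps.

    Keeps per-cluster sufficient statistics (n, s, Q) aligned with the link
    state so that link updates cost O(T) per candidate.
    ``log_transition_accum`` accumulates the log transition densities of all
    draws since the last population-MC reinitialisation.
    """

    def __init__(
        self,
        data: NodeTimecourses,
        link_state: LinkState,
        noise: NoiseState,
        spec: GPSpec,
        size_prior: SizePrior | None,
    ):
        self.data = data
        self.link_state = link_state
        self.noise = noise
        self.spec = spec
        self.size_prior = size_prior
        self.cache = build_batch_cache(data, spec, noise)
        self._rebuild_stats()
        self.log_transition_accum = 0.0
        self.log_post = total_log_posterior(
            link_state, self.cache, link_state.graph, size_prior, noise
        )

    def _rebuild_stats(self) -> None:
        self.stats = {
            cid: self.cache.cluster_stats(members)
            for cid, members in self.link_state.clusters.items()
        }

    def refresh_cache(self) -> None:
        """Rebuild the batch cache after a noise/GP change (O(T^3) once)."""
        self.cache = build_batch_cache(self.data, self.spec, self.noise)
        self._rebuild_stats()
        self.log_post = total_log_posterior(
            self.link_state, self.cache, self.link_state.graph,
            self.size_prior, self.noise,
        )

    def cluster_log_marginal(self, cid: int) -> float:
        n, s, Q = self.stats[cid]
        return self.cache.log_marginal_from_stats(n, s, Q)

    def copy(self) -> "ChainState":
        new = object.__new__(ChainState)
        new.data = self.data
        new.link_state = self.link_state.copy()
        new.noise = self.noise.copy()
        new.spec = self.spec
        new.size_prior = self.size_prior
        new.cache = self.cache
        new.stats = dict(self.stats)
        new.log_transition_accum = self.log_transition_accum
        new.log_post = self.log_post
        return new


def _size_term(prior: SizePrior | None, s: int) -> float:
    if prior is None or not prior.enabled or s >= prior.d:
        return 0.0
    return -((prior.d - s) ** 2) / (2.0 * prior.w**2)


def gibbs_update_link(
    state: ChainState,
    node: int,
    temperature: float,
    rng: np.random.Generator,
) -> None:
    """Resample lambda_node from its full conditional, in place.

    The categorical log-probabilities are divided by ``temperature`` before
    normalisation (temperature 1000 multiplies them by 0.001); the chosen
    option's log-probability under the tempered distribution is added to the
    transition accumulator.
    """
    ls = state.link_state
    graph = ls.graph
    cache = state.cache
    sp = state.size_prior

    old_target = int(ls.links[node])
    cid, split_id = ls.remove_link(node)
    if split_id is not None:
        # recompute stats of both halves from members (O(size * T))
        state.stats.pop(cid, None)
        state.stats.pop(split_id, None)
        state.stats[cid] = cache.cluster_stats(ls.clusters[cid])
        state.stats[split_id] = cache.cluster_stats(ls.clusters[split_id])

    n_i, s_i, Q_i = state.stats[cid]
    log_lik_i = cache.log_marginal_from_stats(n_i, s_i, Q_i)

    candidates = graph.candidates(node)
    log_priors = graph.candidate_log_priors(node)

    logits = np.empty(len(candidates))
    merge_cids = np.full(len(candidates), -1, dtype=np.int64)
    for j, m in enumerate(candidates):
        lp = log_priors[j]
        if not np.isfinite(lp):
            logits[j] = -np.inf
            continue
        cm = int(ls.cluster_of[m])
        if cm != cid:
            n_m, s_m, Q_m = state.stats[cm]
            merged = cache.log_marginal_from_stats(
                n_i + n_m, s_i + s_m, Q_i + Q_m
            )
            log_lik_m = cache.log_marginal_from_stats(n_m, s_m, Q_m)
            lp += merged - log_lik_i - log_lik_m
            if sp is not None and sp.enabled:
                lp += (
                    _size_term(sp, n_i + n_m)
                    - _size_term(sp, n_i)
                    - _size_term(sp, n_m)
                )
            merge_cids[j] = cm
        logits[j] = lp

    tempered = logits / temperature
    tempered -= tempered.max()
    probs = np.exp(tempered)
    probs /= probs.sum()
    choice = int(np.searchsorted(np.cumsum(probs), rng.random()))
    choice = min(choice, len(candidates) - 1)
    target = int(candidates[choice])
    state.log_transition_accum += float(np.log(probs[choice]))

    new_cid, gone = ls.set_link(node, target)
    if gone is not None:
        st_a = state.stats.pop(gone)
        st_b = state.stats.pop(new_cid)
        state.stats[new_cid] = (
            st_a[0] + st_b[0], st_a[1] + st_b[1], st_a[2] + st_b[2]
        )

    # joint log-posterior update via p(new)/p(old) = w(new)/w(old), where w
    # is the unnormalised conditional weight relative to the removed state
    where_old = int(np.flatnonzero(candidates == old_target)[0])
    delta = float(logits[choice] - logits[where_old])
    if np.isfinite(delta):
        state.log_post += delta
    else:
        state.log_post = total_log_posterior(
            ls, cache, graph, sp, state.noise
        )


def link_sweep(
    state: ChainState,
    temperature: float,
    rng: np.random.Generator,
    scan_order: str = "shuffled",
) -> None:
    """One full Gibbs sweep over all link assignments."""
    n = state.link_state.graph.n_nodes
    order = np.arange(n)
    if scan_order == "shuffled":
        rng.shuffle(order)
    for node in order:
        gibbs_update_link(state, int(node), temperature, rng)


def hyperparameter_sweep(state: ChainState, rng: np.random.Generator) -> None:
    """Sample cluster timecourses X, then tau, then phi; rebuild the cache."""
    draws = {}
    logq = 0.0
    for cid, members in state.link_state.clusters.items():
        x, lq = sample_cluster_timecourse(state.cache, members, rng)
        draws[cid] = x
        logq += lq
    new_noise, lq_noise = sample_noise(
        state.data, state.link_state, draws, state.noise, rng
    )
    state.log_transition_accum += logq + lq_noise
    state.noise = new_noise
    state.refresh_cache()


def init_chain(
    data: NodeTimecourses,
    graph: AdjacencyGraph,
    spec: GPSpec,
    size_prior: SizePrior | None,
    n_init_clusters: int,
    rng: np.random.Generator,
    noise: NoiseState | None = None,
) -> ChainState:
    """Random initial partition with roughly ``n_init_clusters`` clusters.

    Built by region growing from random seeds, then expressed as links
    (each node links to the neighbour through which its region reached it;
    seeds self-link), so the initial state is always admissible.
    """
    from .simulate import grow_partition_links

    links = grow_partition_links(
        graph, min(n_init_clusters, graph.n_nodes), rng
    )
    ls = LinkState(links, graph)
    ns = noise.copy() if noise is not None else NoiseState()
    ns.phi_vector(data.n_times)
    return ChainState(data, ls, ns, spec, size_prior)


def run_chain(
    data: NodeTimecourses,
    graph: AdjacencyGraph,
    config: SamplerConfig,
    spec: GPSpec | None = None,
    size_prior: SizePrior | None = None,
    noise: NoiseState | None = None,
    collect_timecourses: bool = False,
) -> dict:
    """Run one Gibbs chain; returns post-burn-in samples.

    Each iteration is one hyperparameter sweep (sample X, tau, phi and
    rebuild the cache) followed by one full link sweep.  Fully reproducible
    given ``config.seed``.
    """
    spec = spec or GPSpec()
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed).spawn(1)[0])
    )
    state = init_chain(
        data, graph, spec, size_prior, config.init_n_clusters, rng, noise
    )
    samples: list[np.ndarray] = []
    log_posts: list[float] = []
    total = config.n_burnin + config.n_samples
    for it in range(total):
        if config.sample_hyperparameters:
            hyperparameter_sweep(state, rng)
        link_sweep(state, config.temperature, rng, config.scan_order)
        if not np.isfinite(state.log_post):
            raise FloatingPointError(
                f"non-finite log posterior at iteration {it}"
            )
        if it >= config.n_burnin:
            samples.append(state.link_state.labels())
            log_posts.append(state.log_post)
    result = {
        "samples": samples,
        "log_posts": np.asarray(log_posts),
        "final_state": state,
    }
    if collect_timecourses:
        coassign = coassignment_mean(samples)
        consensus = consensus_partition(
            coassign, config.coassign_threshold, graph
        )
        result["consensus"] = consensus
        result["timecourses"] = fixed_partition_timecourses(
            state, consensus, config.n_timecourse_samples, rng
        )
    return result


def fixed_partition_timecourses(
    state: ChainState,
    labels: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> dict:
    """Posterior cluster timecourses at a fixed partition.

    Holds the partition fixed and alternates hyperparameter sweeps with
    posterior-timecourse reads, averaging the conditional means and adding
    the within-draw variance (law of total variance) for the 95% band.
    """
    from .likelihood import posterior_timecourse

    clusters: dict[int, list[int]] = {}
    for n, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(n)
    cids = sorted(clusters)
    T = state.data.n_times
    mean_acc = {c: np.zeros(T) for c in cids}
    m2_acc = {c: np.zeros(T) for c in cids}
    var_acc = {c: np.zeros(T) for c in cids}
    ls = _linkstate_from_labels(labels, state.link_state.graph)
    fixed = ChainState(
        state.data, ls, state.noise.copy(), state.spec, state.size_prior
    )
    for _ in range(max(n_samples, 1)):
        hyperparameter_sweep(fixed, rng)
        for c in cids:
            mu, var = posterior_timecourse(fixed.cache, clusters[c])
            mean_acc[c] += mu
            m2_acc[c] += mu**2
            var_acc[c] += var
    k = max(n_samples, 1)
    out = {}
    for c in cids:
        mean = mean_acc[c] / k
        var = var_acc[c] / k + m2_acc[c] / k - mean**2
        out[c] = {"mean": mean, "var": np.maximum(var, 0.0)}
    return out


def _linkstate_from_labels(labels: np.ndarray, graph: AdjacencyGraph) -> LinkState:
    """Links realising a given (spatially contiguous) partition.

    Within each cluster a spanning tree of the spatial graph is built; each
    node links to its tree parent, roots self-link.  Raises if a cluster is
    not connected in the graph.
    """
    labels = np.asarray(labels)
    links = np.arange(graph.n_nodes, dtype=np.int64)
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        member_set = set(members.tolist())
        root = int(members[0])
        seen = {root}
        stack = [root]
        while stack:
            u = stack.pop()
            for v in graph.neighbor_lists[u]:
                v = int(v)
                if v in member_set and v not in seen:
                    links[v] = u
                    seen.add(v)
                    stack.append(v)
        if len(seen) != len(member_set):
            raise ValueError(f"cluster {lab} is not spatially connected")
    return LinkState(links, graph)


def coassignment_mean(samples: list[np.ndarray]) -> np.ndarray:
    """Mean co-assignment: entry (i, j) is the fraction of samples in which
    nodes i and j share a cluster.  Symmetric with unit diagonal."""
    if not samples:
        raise ValueError("need at least one sample")
    n = len(samples[0])
    acc = np.zeros((n, n))
    for lab in samples:
        acc += lab[:, None] == lab[None, :]
    return acc / len(samples)


def consensus_partition(
    coassign: np.ndarray,
    threshold: float,
    graph: AdjacencyGraph | None = None,
) -> np.ndarray:
    """Partition from thresholded co-assignment.

    Joins pairs whose mean co-assignment exceeds ``threshold`` (restricted
    to spatially adjacent pairs when a graph is given) and takes connected
    components.  Returns per-node labels (smallest member index).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = coassign.shape[0]
    above = coassign > threshold
    if graph is not None:
        mask = np.zeros_like(above)
        for u in range(n):
            mask[u, graph.neighbor_lists[u]] = True
        above &= mask
    _, comp = connected_components(csr_matrix(above), directed=False)
    labels = np.empty(n, dtype=np.int64)
    for c in np.unique(comp):
        members = np.flatnonzero(comp == c)
        labels[members] = members.min()
    return labels
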
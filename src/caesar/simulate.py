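"""Synthetic fMRI-like data with known spatial cluster structure.

Three-stage pipeline: (1) grow a random spatially contiguous partition of
the node graph; (2) per cluster, simulate a neuronal signal at 200 Hz from
an Ornstein-Uhlenbeck process and convolve it with the canonical
double-gamma haemodynamic response; (3) decimate the BOLD signal to the
scan rate (0.5 Hz by default) and add white Gaussian noise sized so the
cluster signal carries the requested share of unit total variance
(default 0.1/0.9: sigma_noise = sqrt(0.9) ≈ 0.949).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .likelihood import NodeTimecourses
from .spatial import AdjacencyGraph

__all__ = [
    "OUParams",
    "SimulationTruth",
    "grow_partition",
    "grow_partition_links",
    "simulate_neuronal",
    "canonical_hrf",
    "simulate_dataset",
]


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck (Matérn order-1/2) neuronal-signal parameters.

    The mean-reversion rate is derived as eta = sqrt(2 * order) /
    length_scale; the defaults (order 1/2, length-scale 2 s, unit variance)
    give eta = 0.5 / s, whose 1/(eta^2 + (2 pi f)^2) spectrum is a
    reasonable stand-in for aggregate synaptic activity.
    """

    magnitude: float = 1.0
    length_scale: float = 2.0
    order: float = 0.5

    @property
    def rate(self) -> float:
        return float(np.sqrt(2.0 * self.order) / self.length_scale)


@dataclass
class SimulationTruth:
    """Ground truth bundled with the generated observations."""

    labels: np.ndarray          # per-node true cluster labels
    neuronal: np.ndarray        # K x T_high at the neuronal rate
    bold: np.ndarray            # K x T noiseless cluster signal (scaled)
    data: NodeTimecourses       # noisy observations, unit total variance
    signal_share: float
    noise_sd: float
    seed: int | None = None

    def node_bold(self) -> np.ndarray:
        """Noiseless signal replicated out to the node axis (N x T)."""
        uniq = np.unique(self.labels)
        row = {int(u): k for k, u in enumerate(uniq)}
        return self.bold[[row[int(l)] for l in self.labels]]


def grow_partition_links(
    graph: AdjacencyGraph, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Region growing from K random seeds, returned as a link vector.

    Seeds self-link; every other node links to the neighbour through which
    its region absorbed it, so the induced partition is exactly the grown
    one and every link is admissible.
    """
    n = graph.n_nodes
    if not 1 <= K <= n:
        raise ValueError("K must be between 1 and the number of nodes")
    seeds = rng.choice(n, size=K, replace=False)
    links = np.full(n, -1, dtype=np.int64)
    assigned = np.zeros(n, dtype=bool)
    links[seeds] = seeds
    assigned[seeds] = True
    # frontier of (unassigned node, assigned neighbour) choices, grown
    # one node at a time from a uniformly random admissible attachment
    frontier: list[tuple[int, int]] = []
    for s in seeds:
        for v in graph.neighbor_lists[s]:
            if not assigned[v]:
                frontier.append((int(v), int(s)))
    while frontier:
        i = int(rng.integers(len(frontier)))
        node, parent = frontier[i]
        frontier[i] = frontier[-1]
        frontier.pop()
        if assigned[node]:
            continue
        links[node] = parent
        assigned[node] = True
        for v in graph.neighbor_lists[node]:
            if not assigned[v]:
                frontier.append((int(v), node))
    if not assigned.all():
        raise ValueError("graph is not connected: region growing stalled")
    return links


def grow_partition(
    graph: AdjacencyGraph, K: int, rng: np.random.Generator
) -> np.ndarray:
    """K spatially contiguous regions covering the graph; per-node labels."""
    from .spatial import LinkState

    links = grow_partition_links(graph, K, rng)
    return LinkState(links, graph).labels()


def simulate_neuronal(
    duration_s: float,
    dt: float,
    params: OUParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact-discretisation OU sample path, stationary start.

    Transition x(t + dt) | x(t) ~ N(F x(t), Q) with F = exp(-eta dt) and
    Q = sigma_m^2 (1 - exp(-2 eta dt)); x(0) ~ N(0, sigma_m^2).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration_s / dt))
    eta = params.rate
    F = np.exp(-eta * dt)
    Q = params.magnitude * (1.0 - np.exp(-2.0 * eta * dt))
    innov = rng.normal(0.0, np.sqrt(Q), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, np.sqrt(params.magnitude))
    for t in range(1, n):
        x[t] = F * x[t - 1] + innov[t]
    return x


_HRF_DEFAULTS = dict(
    peak_delay=6.0, undershoot_delay=16.0,
    peak_disp=1.0, undershoot_disp=1.0,
    ratio=6.0, length=32.0,
)


def canonical_hrf(dt: float, **overrides: float) -> np.ndarray:
    """Canonical double-gamma haemodynamic response kernel.

    Difference of two gamma densities (peak at ~5 s, undershoot around
    16 s, peak:undershoot amplitude ratio 6, support 32 s — the SPM
    canonical constants), sampled at ``dt`` and normalised to unit sum.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = {**_HRF_DEFAULTS, **overrides}
    t = np.arange(0.0, p["length"], dt)

    def gamma_pdf(x, shape, scale):
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp(
            (shape - 1) * np.log(x[pos]) - x[pos] / scale
            - gammaln(shape) - shape * np.log(scale)
        )
        return out

    # shape = delay/dispersion, scale = dispersion -> mode at delay - disp
    h = gamma_pdf(t, p["peak_delay"] / p["peak_disp"], p["peak_disp"])
    h -= gamma_pdf(
        t, p["undershoot_delay"] / p["undershoot_disp"], p["undershoot_disp"]
    ) / p["ratio"]
    return h / h.sum()


def simulate_dataset(
    graph: AdjacencyGraph,
    K: int = 10,
    duration_s: float = 900.0,
    fs_high: float = 200.0,
    fs_out: float = 0.5,
    signal_share: float = 0.1,
    ou: OUParams = OUParams(),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    labels: np.ndarray | None = None,
) -> SimulationTruth:
    """Full generative pipeline; returns data plus ground truth.

    ``signal_share`` is the fraction of unit total variance carried by the
    shared cluster signal (0.1 means SNR 0.1/0.9, noise sd sqrt(0.9)).
    Downsampling is pure decimation: every (fs_high/fs_out)-th sample of
    the HRF-filtered signal is kept, giving exactly duration_s * fs_out
    output points.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    step = fs_high / fs_out
    if abs(step - round(step)) > 1e-9:
        raise ValueError("fs_high must be an integer multiple of fs_out")
    step = int(round(step))
    if not 0.0 < signal_share < 1.0:
        raise ValueError("signal_share must lie strictly between 0 and 1")
    if labels is None:
        labels = grow_partition(graph, K, rng)
    else:
        labels = np.asarray(labels)
    uniq = np.unique(labels)
    dt = 1.0 / fs_high
    T = int(round(duration_s * fs_out))
    kernel = canonical_hrf(dt)
    neuronal = np.empty((len(uniq), int(round(duration_s * fs_high))))
    bold = np.empty((len(uniq), T))
    noise_sd = float(np.sqrt(1.0 - signal_share))
    for k in range(len(uniq)):
        neuronal[k] = simulate_neuronal(duration_s, dt, ou, rng)
        filtered = np.convolve(neuronal[k], kernel)[: neuronal.shape[1]]
        low = filtered[::step][:T]
        # scale the cluster signal to carry exactly `signal_share` variance
        sd = low.std()
        if sd == 0:
            raise FloatingPointError("degenerate (constant) BOLD signal")
        bold[k] = (low - low.mean()) / sd * np.sqrt(signal_share)
    label_to_row = {int(u): k for k, u in enumerate(uniq)}
    rows = np.asarray([label_to_row[int(l)] for l in labels])
    Y = bold[rows] + rng.normal(0.0, noise_sd, size=(len(labels), T))
    times = np.arange(T) / fs_out
    data = NodeTimecourses(Y, times)
    return SimulationTruth(
        labels=labels,
        neuronal=neuronal,
        bold=bold,
        data=data,
        signal_share=signal_share,
        noise_sd=noise_sd,
        seed=seed,
    )
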
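"""Accuracy metrics for partitions and timecourse estimates.

Adjusted mutual information is computed from the contingency table with the
expected MI under the hypergeometric (fixed-marginals) null and the
max-entropy normaliser, so 1 means perfect reconstruction and ~0 the
trivial single-cluster solution.  Timecourse accuracy is per-node RMSE
against the noiseless ground-truth signal, which needs no explicit cluster
matching and is well defined for any estimated number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.special import gammaln

__all__ = [
    "EvaluationReport",
    "adjusted_mutual_information",
    "timecourse_rmse",
    "explained_variance",
    "lowpass_filter",
]


@dataclass
class EvaluationReport:
    ami: float
    rmse: float
    explained_variance_pct: float
    n_clusters: int
    cluster_sizes: np.ndarray


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log(p)))


def adjusted_mutual_information(p1: np.ndarray, p2: np.ndarray) -> float:
    """AMI between two partitions given as per-node label vectors.

    (MI - E[MI]) / (max(H1, H2) - E[MI]) with the expected MI taken over
    contingency tables with the observed marginals (hypergeometric model).
    Invariant under label permutation; symmetric in its arguments.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError("partitions must be label vectors over the same nodes")
    n = len(p1)
    _, inv1 = np.unique(p1, return_inverse=True)
    _, inv2 = np.unique(p2, return_inverse=True)
    R, C = inv1.max() + 1, inv2.max() + 1
    table = np.zeros((R, C), dtype=np.int64)
    np.add.at(table, (inv1, inv2), 1)
    a = table.sum(axis=1)
    b = table.sum(axis=0)

    # MI via entropies: exact cancellation when the partitions coincide
    h12 = _entropy(table.ravel(), n)
    h1, h2 = _entropy(a, n), _entropy(b, n)
    mi = h1 + h2 - h12

    # expected MI under fixed marginals
    emi = 0.0
    lg = gammaln
    for i in range(R):
        ai = a[i]
        for j in range(C):
            bj = b[j]
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if lo > hi:
                continue
            nij = np.arange(lo, hi + 1)
            term = nij / n * (np.log(n * nij) - np.log(ai * bj))
            logp = (
                lg(ai + 1) + lg(bj + 1) + lg(n - ai + 1) + lg(n - bj + 1)
                - lg(n + 1) - lg(nij + 1) - lg(ai - nij + 1)
                - lg(bj - nij + 1) - lg(n - ai - bj + nij + 1)
            )
            emi += float(np.sum(term * np.exp(logp)))

    denom = max(h1, h2) - emi
    if denom == 0.0:
        # both partitions carry no information (e.g. both trivial): identical
        return 1.0 if mi == emi else 0.0
    return float((mi - emi) / denom)


def timecourse_rmse(
    estimated_labels: np.ndarray,
    estimated_timecourses: dict[int, np.ndarray],
    true_node_signal: np.ndarray,
) -> float:
    """RMSE of each node's assigned cluster-timecourse estimate against the
    node's true noiseless signal, pooled over nodes and time."""
    labels = np.asarray(estimated_labels)
    truth = np.asarray(true_node_signal)
    if truth.shape[0] != len(labels):
        raise ValueError("one truth row per node required")
    est = np.empty_like(truth)
    for n, lab in enumerate(labels):
        x = np.asarray(estimated_timecourses[int(lab)])
        if x.shape != truth[n].shape:
            raise ValueError("timecourse length mismatch")
        est[n] = x
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def explained_variance(
    Y: np.ndarray,
    labels: np.ndarray,
    cluster_timecourses: dict[int, np.ndarray],
) -> float:
    """Percentage of (per-node mean-centred) data variance explained by the
    assigned cluster timecourses: 100 * (1 - ||Y - X_hat||^2 / ||Y||^2)."""
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    total = float(np.sum(Yc**2))
    if total == 0.0:
        raise ValueError("zero-variance data")
    resid = 0.0
    for n, lab in enumerate(np.asarray(labels)):
        x = np.asarray(cluster_timecourses[int(lab)])
        resid += float(np.sum((Yc[n] - (x - x.mean())) ** 2))
    return 100.0 * (1.0 - resid / total)


def lowpass_filter(Y: np.ndarray, fs: float, cutoff_hz: float = 0.1) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass, applied per node."""
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(4, cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, np.atleast_2d(Y), axis=-1)


def evaluate_fit(
    estimated_labels: np.ndarray,
    estimated_timecourses: dict[int, np.ndarray],
    truth,
) -> EvaluationReport:
    """Bundle AMI / RMSE / explained variance against a simulation truth."""
    ami = adjusted_mutual_information(estimated_labels, truth.labels)
    rmse = timecourse_rmse(
        estimated_labels, estimated_timecourses, truth.node_bold()
    )
    ev = explained_variance(
        truth.data.Y, estimated_labels, estimated_timecourses
    )
    _, sizes = np.unique(estimated_labels, return_counts=True)
    return EvaluationReport(ami, rmse, ev, len(sizes), sizes)
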
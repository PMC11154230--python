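"""Execution modes: LCS distance, clustering, and mode probabilities.

Fingerprints (integer label sequences of equal length) are compared with the
longest-common-subsequence distance d(x, y) = |x| + |y| - 2*LCS(x, y), a
metric on sequences that is sensitive to the order in which dominant
subnetworks appear.  Clustering the pairwise distance matrix partitions the
parameter ensemble into execution modes; each mode's probability is the sum
of the posterior weights of its members.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import HDBSCAN, AgglomerativeClustering, SpectralClustering
from sklearn.metrics import silhouette_score

from .dominance import DominantSubnetwork, DynamicFingerprint, SubnetworkRegistry
from .network import ParameterEnsemble

__all__ = [
    "NOISE_MODE",
    "DistanceMatrix",
    "ExecutionMode",
    "lcs_length",
    "lcs_distance",
    "distance_matrix",
    "cluster",
    "select_n_clusters",
    "mode_probabilities",
    "representative_subnetwork",
    "build_modes",
]

NOISE_MODE = -1  # HDBSCAN noise points are reported as this reserved mode


def _as_array(x) -> np.ndarray:
    if isinstance(x, DynamicFingerprint):
        return x.labels
    return np.asarray(x, dtype=np.int64)


def lcs_length(x, y) -> int:
    """Length of the longest (not necessarily contiguous) common subsequence.

    Row-vectorized dynamic program: the running maximum of the candidate row
    max(prev[j], prev[j-1] + eq_j) equals the classic three-way recurrence.
    """
    x = _as_array(x)
    y = _as_array(y)
    if len(x) == 0 or len(y) == 0:
        return 0
    prev = np.zeros(len(y) + 1, dtype=np.int64)
    for xi in x:
        cand = np.maximum(prev[1:], prev[:-1] + (y == xi))
        prev[1:] = np.maximum.accumulate(cand)
    return int(prev[-1])


def lcs_distance(x, y) -> int:
    """d(x, y) = |x| + |y| - 2*LCS(x, y); zero iff the sequences are equal."""
    x = _as_array(x)
    y = _as_array(y)
    return len(x) + len(y) - 2 * lcs_length(x, y)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise LCS distances; row i = ensemble member i."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_matrix(fps: Sequence[DynamicFingerprint | np.ndarray]) -> DistanceMatrix:
    """All-pairs LCS distance.  Duplicate fingerprints are computed once."""
    if len(fps) < 2:
        raise ValueError("need at least 2 fingerprints")
    arrs = np.array([_as_array(f) for f in fps])
    if arrs.ndim != 2:
        raise ValueError("fingerprints must all have the same length")
    uniq, inverse = np.unique(arrs, axis=0, return_inverse=True)
    m = len(uniq)
    d_u = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d_u[i, j] = d_u[j, i] = lcs_distance(uniq[i], uniq[j])
    return DistanceMatrix(d_u[np.ix_(inverse, inverse)])


def cluster(dm: DistanceMatrix, method: str = "agglomerative",
            n_clusters: int | None = None, seed: int = 0,
            min_cluster_size: int = 5) -> np.ndarray:
    """Partition fingerprints into modes on the precomputed distance matrix.

    Returns an integer assignment per ensemble member.  Agglomerative uses
    average linkage; spectral converts distances to a Gaussian affinity;
    HDBSCAN keeps its noise points as the reserved mode ``NOISE_MODE`` so
    probabilities over modes still sum to one.
    """
    d = dm.values
    n = dm.n
    if method in ("agglomerative", "spectral"):
        if n_clusters is None:
            raise ValueError(f"{method} clustering requires n_clusters")
        if n_clusters > n:
            raise ValueError(f"n_clusters={n_clusters} exceeds ensemble size {n}")
    if method == "agglomerative":
        model = AgglomerativeClustering(
            n_clusters=n_clusters, metric="precomputed", linkage="average")
        return model.fit_predict(d)
    if method == "spectral":
        scale = np.mean(d[d > 0]) if np.any(d > 0) else 1.0
        affinity = np.exp(-(d / scale) ** 2)
        model = SpectralClustering(
            n_clusters=n_clusters, affinity="precomputed", random_state=seed)
        return model.fit_predict(affinity)
    if method == "hdbscan":
        model = HDBSCAN(metric="precomputed",
                        min_cluster_size=min(min_cluster_size, max(2, n // 2)))
        labels = model.fit_predict(d)
        return labels
    raise ValueError(f"unknown clustering method {method!r}")


def select_n_clusters(dm: DistanceMatrix, method: str = "agglomerative",
                      k_range: Sequence[int] = range(2, 11),
                      seed: int = 0) -> int:
    """Pick k by maximal mean silhouette on the precomputed distance.

    Ties break toward the smallest k.  A degenerate all-zero matrix (all
    fingerprints identical) returns 1 with a warning.
    """
    d = dm.values
    if not np.any(d > 0):
        warnings.warn("all fingerprints identical; returning a single mode")
        return 1
    best_k, best_score = None, -np.inf
    for k in k_range:
        if not 2 <= k <= dm.n - 1:
            raise ValueError(f"k_range value {k} outside [2, N-1]")
        labels = cluster(dm, method=method, n_clusters=k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(d, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    if best_k is None:
        warnings.warn("no valid clustering found; returning a single mode")
        return 1
    return best_k


def mode_probabilities(assignments: np.ndarray,
                       ensemble: ParameterEnsemble) -> dict[int, float]:
    """Probability of each mode = sum of its members' normalized weights."""
    assignments = np.asarray(assignments)
    if len(assignments) != len(ensemble):
        raise ValueError(
            f"assignment length {len(assignments)} does not match "
            f"ensemble size {len(ensemble)}")
    w = ensemble.normalized_weights
    return {int(m): float(w[assignments == m].sum())
            for m in np.unique(assignments)}


def representative_subnetwork(member_fps: Sequence[DynamicFingerprint],
                              registry: SubnetworkRegistry) -> DominantSubnetwork:
    """The subnetwork whose label occurs most often across member fingerprints.

    Ties break toward the smaller label.
    """
    if not member_fps:
        raise ValueError("mode has no members")
    counts: Counter[int] = Counter()
    for fp in member_fps:
        counts.update(fp.labels.tolist())
    best = min(counts, key=lambda lbl: (-counts[lbl], lbl))
    return registry.subnetwork(best)


@dataclass
class ExecutionMode:
    """A cluster of fingerprints: probability mass + representative subnetwork."""

    mode_id: int
    member_indices: np.ndarray
    probability: float
    representative: DominantSubnetwork

    @property
    def representative_label(self) -> int:
        return self.representative.label if self.representative.label is not None \
            else -1


def build_modes(assignments: np.ndarray,
                ensemble: ParameterEnsemble,
                fps: Sequence[DynamicFingerprint],
                registry: SubnetworkRegistry) -> list[ExecutionMode]:
    """Assemble ExecutionMode summaries, ordered by decreasing probability."""
    probs = mode_probabilities(assignments, ensemble)
    assignments = np.asarray(assignments)
    modes = []
    for mode_id, p in probs.items():
        idx = np.flatnonzero(assignments == mode_id)
        rep = representative_subnetwork([fps[i] for i in idx], registry)
        modes.append(ExecutionMode(mode_id, idx, p, rep))
    modes.sort(key=lambda m: -m.probability)
    return modes
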
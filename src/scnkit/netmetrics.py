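"""Weighted global network metrics for structural covariance networks.

All metrics operate on a symmetric non-negative weight matrix with a zero
diagonal (absolute partial correlations in the SCN pipeline).  Path-based
metrics treat each edge as having length ``1 / w_ij``, since weights encode
association strength rather than cost.  The clustering coefficient uses the
weighted transitivity ratio ``Tr A^3 / sum_{i != j} [A^2]_ij``; network
complexity is the mean Jensen-Shannon divergence (in bits) between the
normalised per-vertex edge-weight distributions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, dijkstra

from .exceptions import DataError, DisconnectedGraphError, NumericalError

__all__ = [
    "MetricSet",
    "global_clustering",
    "path_length",
    "efficiency",
    "betweenness",
    "jsd_complexity",
    "compute_metrics",
]

#: tolerance for treating two shortest-path lengths as tied
TIE_TOL = 1e-12


def _check_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DataError(f"weight matrix must be square, got shape {w.shape}")
    if not np.allclose(w, w.T, atol=1e-10):
        raise DataError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise DataError("weights must be non-negative")
    if np.any(np.diag(w) != 0):
        raise DataError("weight matrix must have a zero diagonal")
    return w


def _length_matrix(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _shortest_distances(w: np.ndarray) -> np.ndarray:
    lengths = _length_matrix(w)
    finite = np.where(np.isfinite(lengths), lengths, 0.0)
    return dijkstra(finite, directed=False, unweighted=False)


def global_clustering(weights: np.ndarray) -> float:
    """Weighted global clustering coefficient ``Tr A^3 / sum_{i!=j}[A^2]_ij``.

    Measures how strongly edge weight is organised into closed triangles
    relative to open two-paths.  Raises if the network contains no
    two-paths (denominator zero).
    """
    a = _check_weights(weights)
    a2 = a @ a
    num = float(np.trace(a2 @ a))
    den = float(a2.sum() - np.trace(a2))
    if den == 0.0:
        raise NumericalError("clustering undefined: network has no two-paths")
    return num / den


def path_length(weights: np.ndarray) -> float:
    """Characteristic path length: mean shortest-path distance over ordered
    vertex pairs, with edge lengths ``1 / w_ij``.

    Raises :class:`DisconnectedGraphError` if any pair is unreachable.
    """
    w = _check_weights(weights)
    n = w.shape[0]
    if n < 2:
        raise DataError("path length requires at least 2 vertices")
    d = _shortest_distances(w)
    off = ~np.eye(n, dtype=bool)
    if np.any(np.isinf(d[off])):
        n_comp, labels = connected_components(
            (w > 0).astype(int), directed=False
        )
        raise DisconnectedGraphError(
            f"graph is disconnected ({n_comp} components)", components=labels
        )
    return float(d[off].mean())


def efficiency(weights: np.ndarray) -> float:
    """Global efficiency: mean of ``1 / d_ij`` over ordered pairs.

    Unreachable pairs contribute zero, so the metric is defined for
    disconnected (including empty) networks.
    """
    w = _check_weights(weights)
    n = w.shape[0]
    if n < 2:
        raise DataError("efficiency requires at least 2 vertices")
    d = _shortest_distances(w)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(d[off] > 0, 1.0 / d[off], 0.0)
    inv[np.isinf(d[off])] = 0.0
    return float(inv.mean())


def betweenness(weights: np.ndarray) -> np.ndarray:
    """Betweenness centrality of each vertex on inverse-weight shortest paths.

    Brandes accumulation with Dijkstra; shortest paths tied within
    ``TIE_TOL`` in length are all counted.  Values are normalised by the
    number of unordered vertex pairs excluding the vertex itself,
    ``(N - 1)(N - 2) / 2``, so a star hub scores exactly 1.
    """
    w = _check_weights(weights)
    n = w.shape[0]
    if n < 3:
        return np.zeros(n)
    lengths = _length_matrix(w)
    neighbors = [np.flatnonzero(w[i] > 0) for i in range(n)]
    accum = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        sigma = np.zeros(n)
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        done = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            du, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            order.append(u)
            for v in neighbors[u]:
                alt = dist[u] + lengths[u, v]
                if alt < dist[v] - TIE_TOL:
                    dist[v] = alt
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (alt, v))
                elif abs(alt - dist[v]) <= TIE_TOL and not done[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for v in reversed(order):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                accum[v] += delta[v]
    # each unordered source/target pair was visited from both endpoints
    return accum / ((n - 1) * (n - 2))


def jsd_complexity(
    weights: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Jensen-Shannon network complexity.

    Each vertex's outgoing weights are normalised into a probability vector
    ``p_i`` (vertices with zero total weight fall back to the uniform
    distribution ``1/n``).  ``JSD_ij`` is the Jensen-Shannon divergence in
    bits between ``p_i`` and ``p_j``; ``JSD_i`` averages over all ``j``
    (including the zero self term) and ``JSD_global`` is the ``1/n^2``
    double-sum mean over all ordered pairs.

    Returns ``(JSD_global, JSD_i, JSD_ij)``.
    """
    w = _check_weights(weights)
    n = w.shape[0]
    row_sums = w.sum(axis=1, keepdims=True)
    p = np.where(row_sums > 0, w / np.where(row_sums > 0, row_sums, 1.0), 1.0 / n)

    def _h(x: np.ndarray) -> np.ndarray:
        """Shannon entropy (bits) along the last axis, 0 log 0 = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(x > 0, x * np.log2(np.where(x > 0, x, 1.0)), 0.0)
        return -t.sum(axis=-1)

    h_rows = _h(p)
    m = 0.5 * (p[:, None, :] + p[None, :, :])
    jsd_ij = _h(m) - 0.5 * (h_rows[:, None] + h_rows[None, :])
    jsd_ij = np.clip(jsd_ij, 0.0, 1.0)
    np.fill_diagonal(jsd_ij, 0.0)
    jsd_i = jsd_ij.mean(axis=1)
    jsd_global = float(jsd_ij.sum() / n**2)
    return jsd_global, jsd_i, jsd_ij


@dataclass
class MetricSet:
    """Global weighted-network metrics of one SCN."""

    C: float
    L: float
    E_glob: float
    C_B: np.ndarray
    JSD_global: float
    JSD_i: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "L": self.L,
            "E_glob": self.E_glob,
            "JSD_global": self.JSD_global,
            "C_B": list(map(float, self.C_B)),
            "JSD_i": list(map(float, self.JSD_i)),
        }


def compute_metrics(weights: np.ndarray) -> MetricSet:
    """Compute the full metric set on one weight matrix."""
    jsd_global, jsd_i, _ = jsd_complexity(weights)
    return MetricSet(
        C=global_clustering(weights),
        L=path_length(weights),
        E_glob=efficiency(weights),
        C_B=betweenness(weights),
        JSD_global=jsd_global,
        JSD_i=jsd_i,
    )
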
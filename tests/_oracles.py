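"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (exhaustive enumeration, explicit
regression) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np

TOL = 1e-12


def brute_global_clustering(w: np.ndarray) -> float:
    n = w.shape[0]
    num = 0.0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                num += w[i, j] * w[j, k] * w[k, i]
    den = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                den += sum(w[i, k] * w[k, j] for k in range(n))
    return num / den


def _all_paths(w, src, dst, visited):
    """All simple paths src -> dst over positive-weight edges."""
    if src == dst:
        yield [dst]
        return
    for nxt in range(len(w)):
        if w[src, nxt] > 0 and nxt not in visited:
            for rest in _all_paths(w, nxt, dst, visited | {nxt}):
                yield [src] + rest


def brute_shortest_paths(w: np.ndarray):
    """dist[j][k], and the list of all shortest paths per pair (n <= 7)."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    paths: dict[tuple, list] = {}
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            best, plist = np.inf, []
            for p in _all_paths(w, j, k, {j}):
                length = sum(1.0 / w[p[a], p[a + 1]] for a in range(len(p) - 1))
                if length < best - TOL:
                    best, plist = length, [p]
                elif abs(length - best) <= TOL:
                    plist.append(p)
            dist[j, k] = best
            paths[(j, k)] = plist
    return dist, paths


def brute_path_length(w: np.ndarray) -> float:
    dist, _ = brute_shortest_paths(w)
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float(dist[off].mean())


def brute_efficiency(w: np.ndarray) -> float:
    dist, _ = brute_shortest_paths(w)
    n = w.shape[0]
    total = 0.0
    for j in range(n):
        for k in range(n):
            if j != k and np.isfinite(dist[j, k]) and dist[j, k] > 0:
                total += 1.0 / dist[j, k]
    return total / (n * (n - 1))


def brute_betweenness(w: np.ndarray) -> np.ndarray:
    """Exhaustive-path betweenness, unordered pairs, hub-normalised to 1."""
    n = w.shape[0]
    _, paths = brute_shortest_paths(w)
    cb = np.zeros(n)
    for v in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if v in (j, k):
                    continue
                plist = paths[(j, k)]
                if not plist:
                    continue
                through = sum(1 for p in plist if v in p[1:-1])
                cb[v] += through / len(plist)
    return cb / ((n - 1) * (n - 2) / 2)


def residual_pcorr(x: np.ndarray) -> np.ndarray:
    """Partial correlations via explicit residualization on all other columns."""
    n, p = x.shape
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            z = np.column_stack([np.ones(n), x[:, others]])
            ri = x[:, i] - z @ np.linalg.lstsq(z, x[:, i], rcond=None)[0]
            rj = x[:, j] - z @ np.linalg.lstsq(z, x[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def _partitions(items, k):
    """All partitions of ``items`` into exactly ``k`` nonempty blocks."""
    if k == 1:
        yield [list(items)]
        return
    if len(items) == k:
        yield [[i] for i in items]
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest, k):
        for idx in range(len(part)):
            yield part[:idx] + [[first] + part[idx]] + part[idx + 1:]
    for part in _partitions(rest, k - 1):
        yield [[first]] + part


def best_ss_partition(x: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive minimum within-cluster sum of squares partition."""
    n = x.shape[0]
    best, best_labels = np.inf, None
    for part in _partitions(list(range(n)), k):
        ss = 0.0
        for block in part:
            sub = x[block]
            ss += ((sub - sub.mean(axis=0)) ** 2).sum()
        if ss < best:
            best = ss
            labels = np.empty(n, dtype=int)
            for c, block in enumerate(part):
                labels[block] = c
            best_labels = labels
    return best_labels


def jsd_bits(p: np.ndarray, q: np.ndarray) -> float:
    """Direct Jensen-Shannon divergence (bits) between two distributions."""
    m = (np.asarray(p, float) + np.asarray(q, float)) / 2.0

    def kl(a, b):
        s = 0.0
        for ai, bi in zip(a, b):
            if ai > 0:
                s += ai * np.log2(ai / bi)
        return s

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)
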
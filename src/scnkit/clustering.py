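"""Atlas reduction by Ward hierarchical clustering of partial correlations.

Each parcel's row of the parcel-level partial-correlation matrix is its
covariance fingerprint; Ward's criterion on the Euclidean geometry of
those row profiles groups parcels with similar relationships to the rest
of the cortex.  The cluster count is selected by a composite of cluster
quality (mean silhouette, Dunn index) and consistency (adjusted Rand index
between hemispheres and across subject subsamples), min-max normalised and
summed, repeated over random seeds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .exceptions import DataError, DegenerateClusteringError
from .scn import average_hemispheres, hemisphere_split, partial_corr_matrix

__all__ = [
    "ClusterSolution",
    "SelectionReport",
    "ward_cluster",
    "cluster_quality",
    "consistency_ari",
    "select_K",
]

#: sentinel replacing an infinite Dunn index (zero intra-cluster diameter)
DUNN_SENTINEL = 1e12


@dataclass
class ClusterSolution:
    """One parcel -> cluster assignment with its quality scores."""

    labels: np.ndarray
    K: int
    silhouette: float | None = None
    dunn: float | None = None
    ari_hemi: float | None = None
    ari_subsample: float | None = None
    composite: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(np.unique(self.labels)) != self.K:
            raise DataError("label set does not match K")

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "silhouette": self.silhouette,
            "dunn": self.dunn,
            "ari_hemi": self.ari_hemi,
            "ari_subsample": self.ari_subsample,
            "composite": self.composite,
            "labels": list(map(int, self.labels)),
        }


def _check_pcorr(pcorr: np.ndarray) -> np.ndarray:
    p = np.asarray(pcorr, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise DataError("partial-correlation matrix must be square")
    if not np.allclose(p, p.T, atol=1e-8):
        raise DataError("partial-correlation matrix must be symmetric")
    if not np.allclose(np.diag(p), 1.0, atol=1e-6):
        raise DataError("partial-correlation matrix must have unit diagonal")
    return p


def ward_cluster(pcorr: np.ndarray, K: int) -> ClusterSolution:
    """Ward agglomerative clustering of parcel row-profiles into K clusters.

    Deterministic given the input; labels are relabelled 1..K in order of
    first appearance.
    """
    p = _check_pcorr(pcorr)
    n = p.shape[0]
    if not 2 <= K <= n:
        raise DataError(f"K={K} out of range [2, {n}]")
    z = linkage(p, method="ward")  # rows as Euclidean feature vectors
    labels = fcluster(z, t=K, criterion="maxclust")
    return ClusterSolution(labels=labels, K=K)


def cluster_quality(pcorr: np.ndarray, labels) -> tuple[float, float]:
    """Mean silhouette score and Dunn index of a partition.

    Both use the same Euclidean row-profile distances as the clustering.
    An all-singleton partition has no defined silhouette and is raised as
    degenerate rather than silently scored zero; an infinite Dunn index
    (zero intra-cluster diameter) is capped at a large sentinel.
    """
    p = _check_pcorr(pcorr)
    labels = np.asarray(labels)
    n = p.shape[0]
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DegenerateClusteringError("quality needs at least 2 clusters")
    if len(uniq) >= n:
        raise DegenerateClusteringError(
            "silhouette undefined for an all-singleton partition"
        )
    dmat = squareform(pdist(p))
    sil = float(silhouette_score(dmat, labels, metric="precomputed"))

    max_diam = 0.0
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            max_diam = max(max_diam, float(dmat[np.ix_(idx, idx)].max()))
    min_sep = np.inf
    for i, ci in enumerate(uniq):
        for cj in uniq[i + 1:]:
            a = np.flatnonzero(labels == ci)
            b = np.flatnonzero(labels == cj)
            min_sep = min(min_sep, float(dmat[np.ix_(a, b)].min()))
    dunn = DUNN_SENTINEL if max_diam == 0 else min(min_sep / max_diam,
                                                   DUNN_SENTINEL)
    return sil, dunn


def consistency_ari(
    table_controls: pd.DataFrame,
    K: int,
    n_subsamples: int = 20,
    subsample_size: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Clustering consistency across hemispheres and subject subsamples.

    ``ari_hemi``: ARI between labelings obtained separately from the
    left- and right-parcel partial correlations (parcels correspond by
    index).  ``ari_subsample``: mean ARI between labelings from random
    subject subsamples (without replacement) and the full-sample labeling.
    """
    left, right = hemisphere_split(table_controls)
    n_sub = len(table_controls)
    if subsample_size is None:
        subsample_size = n_sub // 2
    if subsample_size >= n_sub:
        raise DataError("subsample_size must be below n_subjects")

    lab_l = ward_cluster(partial_corr_matrix(left.to_numpy()), K).labels
    lab_r = ward_cluster(partial_corr_matrix(right.to_numpy()), K).labels
    ari_hemi = float(adjusted_rand_score(lab_l, lab_r))

    avg = average_hemispheres(table_controls)
    full_labels = ward_cluster(partial_corr_matrix(avg.to_numpy()), K).labels
    rng = np.random.default_rng(seed)
    aris = []
    for _ in range(n_subsamples):
        idx = rng.choice(n_sub, size=subsample_size, replace=False)
        sub = avg.iloc[idx]
        lab = ward_cluster(partial_corr_matrix(sub.to_numpy()), K).labels
        aris.append(adjusted_rand_score(full_labels, lab))
    ari_sub = float(np.mean(aris)) if aris else float("nan")
    return ari_hemi, ari_sub


@dataclass
class SelectionReport:
    """Per-K solutions and the seeded composite-score selection."""

    solutions: dict = field(default_factory=dict)   # K -> ClusterSolution
    chosen_K: list = field(default_factory=list)    # one per seed
    modal_K: int = 0
    K_range: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "K_range": list(map(int, self.K_range)),
            "chosen_K": list(map(int, self.chosen_K)),
            "modal_K": int(self.modal_K),
            "solutions": {int(k): s.to_dict() for k, s in self.solutions.items()},
        }


def _minmax(v: np.ndarray) -> np.ndarray:
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def select_K(
    table_controls: pd.DataFrame,
    K_range,
    n_seeds: int = 10,
    n_subsamples: int = 20,
    subsample_size: int | None = None,
    seed: int = 0,
) -> SelectionReport:
    """Composite-score selection of the cluster count.

    For each seed, the four metrics (silhouette, Dunn, hemisphere ARI,
    subsample ARI) are min-max normalised across ``K_range`` and summed;
    the argmax K is chosen (ties toward smaller K for parsimony).  The
    modal K over seeds is reported; only subsampling varies with the seed.
    """
    K_range = sorted(K_range)
    if not K_range:
        raise DataError("empty K_range")
    avg = average_hemispheres(table_controls)
    pc = partial_corr_matrix(avg.to_numpy())

    base: dict[int, ClusterSolution] = {}
    for K in K_range:
        sol = ward_cluster(pc, K)
        sol.silhouette, sol.dunn = cluster_quality(pc, sol.labels)
        sol.ari_hemi, _ = consistency_ari(
            table_controls, K, n_subsamples=0, subsample_size=subsample_size,
            seed=seed)
        base[K] = sol

    chosen = []
    for s in range(n_seeds):
        sub_aris = []
        for K in K_range:
            _, ari_sub = consistency_ari(
                table_controls, K, n_subsamples=n_subsamples,
                subsample_size=subsample_size, seed=seed + 1000 * (s + 1))
            sub_aris.append(ari_sub)
            if s == 0:
                base[K].ari_subsample = ari_sub
        metrics = np.array([
            [base[K].silhouette for K in K_range],
            [base[K].dunn for K in K_range],
            [base[K].ari_hemi for K in K_range],
            sub_aris,
        ])
        composite = sum(_minmax(m) for m in metrics)
        if s == 0:
            for K, c in zip(K_range, composite):
                base[K].composite = float(c)
        best = int(np.array(K_range)[np.argmax(composite)])  # first = smaller
        chosen.append(best)

    counts = Counter(chosen)
    top = max(counts.values())
    modal = min(k for k, c in counts.items() if c == top)
    return SelectionReport(
        solutions=base, chosen_K=chosen, modal_K=modal, K_range=K_range)
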
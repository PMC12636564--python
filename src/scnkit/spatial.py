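"""Spatially informed SCN analysis.

Three components:

* great-circle (geodesic) distances between cluster centroids on the
  spherical cortical surface,
* small-world propensity against a distance-ordered lattice null and an
  ensemble of weight-shuffled random nulls,
* smooth distance-weight modelling with a penalized-spline Gaussian GAM
  (per-group smooths plus a parametric group offset) and pointwise
  FDR-corrected group comparison along the distance axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from .exceptions import DataError, NumericalError
from .netmetrics import global_clustering, path_length

__all__ = [
    "GeodesicMatrix",
    "SWPResult",
    "DistanceWeightModel",
    "pairwise_geodesics",
    "cluster_centroids",
    "geodesics",
    "swp",
    "fit_distance_weight",
    "pointwise_compare",
]


# ---------------------------------------------------------------------------
# geodesics


def pairwise_geodesics(points: np.ndarray, r: float) -> np.ndarray:
    """Great-circle distances ``r * atan2(|P_i x P_j|, P_i . P_j)``.

    Points are projected radially onto the sphere of radius ``r`` first; the
    atan2 form is numerically stable for both near-identical and
    near-antipodal points.
    """
    pts = np.asarray(points, dtype=float)
    norms = np.linalg.norm(pts, axis=1)
    if np.any(norms == 0):
        raise DataError("zero-norm point cannot be projected to the sphere")
    u = pts / norms[:, None]
    dots = np.clip(u @ u.T, -1.0, 1.0)
    crosses = np.linalg.norm(np.cross(u[:, None, :], u[None, :, :]), axis=-1)
    d = r * np.arctan2(crosses, dots)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class GeodesicMatrix:
    """Pairwise great-circle distances between cluster centroids."""

    d: np.ndarray
    centroids: np.ndarray
    r: float
    off_sphere_flags: np.ndarray | None = None


def cluster_centroids(
    points: np.ndarray, labels: np.ndarray, r: float, tol: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic-mean centroid of each cluster's member coordinates.

    Returns ``(centroids, flags)`` where ``flags[k]`` marks centroids whose
    norm deviates from the sphere radius by more than ``tol * r`` — a
    surrogate for the visual sanity check that centroids fall inside
    roughly circular clusters.  Cluster ids are taken in sorted order.
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(pts):
        raise DataError("labels must cover every layout point")
    ids = np.unique(labels)
    cents = np.empty((len(ids), 3))
    for k, cid in enumerate(ids):
        members = pts[labels == cid]
        if members.size == 0:
            raise DataError(f"cluster {cid} has no members")
        cents[k] = members.mean(axis=0)
    flags = np.abs(np.linalg.norm(cents, axis=1) - r) > tol * r
    return cents, flags


def geodesics(centroids: np.ndarray, r: float) -> GeodesicMatrix:
    """Geodesic matrix between centroids, re-projected onto the sphere."""
    cents = np.asarray(centroids, dtype=float)
    flags = np.abs(np.linalg.norm(cents, axis=1) - r) > 0.25 * r
    return GeodesicMatrix(
        d=pairwise_geodesics(cents, r), centroids=cents, r=r,
        off_sphere_flags=flags,
    )


# ---------------------------------------------------------------------------
# small-world propensity


@dataclass
class SWPResult:
    """Small-world propensity of a spatially embedded weighted network.

    ``phi`` is 1 for a perfectly small-world network; ``delta`` locates the
    deviation along the lattice-random continuum (-1: clustering maximally
    below the lattice null; +1: path length maximally above the random
    null).
    """

    phi: float
    delta: float
    dC: float
    dL: float
    alpha: float
    C_obs: float
    C_latt: float
    C_rand: float
    L_obs: float
    L_latt: float
    L_rand: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "phi", "delta", "dC", "dL", "alpha", "C_obs", "C_latt",
            "C_rand", "L_obs", "L_latt", "L_rand", "degenerate")}


def _from_upper(vec: np.ndarray, n: int, iu) -> np.ndarray:
    m = np.zeros((n, n))
    m[iu] = vec
    return m + m.T


def lattice_null(weights: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Distance-ordered lattice: largest weights at shortest distances.

    Edge slots are ranked by geodesic distance ascending (ties broken by
    slot index) and filled with the observed weights sorted descending.
    """
    n = weights.shape[0]
    iu = np.triu_indices(n, k=1)
    w = weights[iu]
    d = dist[iu]
    order_slots = np.lexsort((np.arange(len(d)), d))  # distance asc, index
    w_sorted = np.sort(w)[::-1]
    out = np.empty_like(w)
    out[order_slots] = w_sorted
    return _from_upper(out, n, iu)


def swp(
    weights: np.ndarray,
    dist: GeodesicMatrix | np.ndarray,
    n_random: int = 10,
    seed: int | None = 0,
) -> SWPResult:
    """Small-world propensity phi and continuum position delta.

    The observed clustering coefficient and characteristic path length are
    referenced against a distance-ordered lattice rearrangement and the
    average over ``n_random`` random weight shuffles::

        dC  = (C_latt - C_obs) / (C_latt - C_rand)     clamped to [0, 1]
        dL  = (L_obs - L_rand) / (L_latt - L_rand)     clamped to [0, 1]
        phi = 1 - sqrt((dC^2 + dL^2) / 2)
        delta = 4 * atan2(dL, dC) / pi - 1

    Degenerate null spreads (lattice equal to random) are flagged and the
    affected ratio clamped to its boundary.
    """
    d = dist.d if isinstance(dist, GeodesicMatrix) else np.asarray(dist)
    w = np.asarray(weights, dtype=float)
    if w.shape != d.shape:
        raise DataError("weights and distance matrix must be conformable")
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)

    c_obs = global_clustering(w)
    l_obs = path_length(w)

    w_latt = lattice_null(w, d)
    c_latt = global_clustering(w_latt)
    l_latt = path_length(w_latt)

    c_rands, l_rands = [], []
    for _ in range(n_random):
        w_rand = _from_upper(rng.permutation(w[iu]), n, iu)
        c_rands.append(global_clustering(w_rand))
        l_rands.append(path_length(w_rand))
    c_rand = float(np.mean(c_rands))
    l_rand = float(np.mean(l_rands))

    degenerate = False

    def _ratio(num: float, den: float) -> float:
        nonlocal degenerate
        if abs(den) < 1e-15:
            degenerate = True
            return 0.0 if num <= 0 else 1.0
        return float(np.clip(num / den, 0.0, 1.0))

    dc = _ratio(c_latt - c_obs, c_latt - c_rand)
    dl = _ratio(l_obs - l_rand, l_latt - l_rand)
    phi = 1.0 - np.sqrt((dc**2 + dl**2) / 2.0)
    alpha = float(np.arctan2(dl, dc))
    delta = 4.0 * alpha / np.pi - 1.0
    return SWPResult(
        phi=float(phi), delta=float(delta), dC=dc, dL=dl, alpha=alpha,
        C_obs=c_obs, C_latt=c_latt, C_rand=c_rand,
        L_obs=l_obs, L_latt=l_latt, L_rand=l_rand, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# distance-weight GAM


def _bspline_basis(x: np.ndarray, k: int, xmin: float, xmax: float):
    """Cubic B-spline basis with ``k`` functions on [xmin, xmax].

    Interior knots at quantile-spaced positions; degree drops below 3 only
    when k < 4.  Returns (basis matrix, knot vector, degree).
    """
    degree = 3 if k >= 4 else k - 1
    n_interior = k - degree - 1
    if n_interior > 0:
        interior = np.quantile(
            x, np.linspace(0, 1, n_interior + 2)[1:-1]
        )
    else:
        interior = np.array([])
    t = np.r_[[xmin] * (degree + 1), interior, [xmax] * (degree + 1)]
    xc = np.clip(x, xmin, xmax)
    b = BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray()
    return b, t, degree


def _diff_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


@dataclass
class DistanceWeightModel:
    """Fitted Gaussian GAM: weight ~ group + s(distance) per group.

    Smoothing parameters are selected by generalized cross-validation;
    standard errors use the Bayesian posterior covariance of the penalized
    fit.  ``grid`` holds 100 equidistant distance points spanning the
    observed range with per-group predictions and SEs.
    """

    k: int
    n_obs: int
    edf: float
    scale: float
    gcv: float
    lambdas: tuple
    group_coef: float
    group_se: float
    group_t: float
    group_p: float
    smooth_f: dict
    smooth_p: dict
    deviance_diff: float
    deviance_df: float
    deviance_p: float
    grid: np.ndarray = field(repr=False)
    pred_a: np.ndarray = field(repr=False)
    se_a: np.ndarray = field(repr=False)
    pred_b: np.ndarray = field(repr=False)
    se_b: np.ndarray = field(repr=False)
    smoothing_method: str = "GCV"

    def summary_dict(self) -> dict:
        return {
            "k": self.k,
            "n_obs": self.n_obs,
            "edf": self.edf,
            "scale": self.scale,
            "gcv": self.gcv,
            "lambdas": list(self.lambdas),
            "group_coef": self.group_coef,
            "group_se": self.group_se,
            "group_t": self.group_t,
            "group_p": self.group_p,
            "smooth_f": self.smooth_f,
            "smooth_p": self.smooth_p,
            "deviance_diff": self.deviance_diff,
            "deviance_df": self.deviance_df,
            "deviance_p": self.deviance_p,
            "smoothing_method": self.smoothing_method,
        }


def _pen_fit(x, y, pen_blocks, log_lams):
    """Penalized least squares at fixed log smoothing parameters."""
    xtx = x.T @ x
    m = xtx + 1e-10 * np.eye(x.shape[1])  # guards rank-deficient designs
    for lam, block in zip(np.exp(np.clip(log_lams, -30, 30)), pen_blocks):
        m += lam * block
    minv = np.linalg.inv(m)
    beta = minv @ (x.T @ y)
    fitted = x @ beta
    rss = float(np.sum((y - fitted) ** 2))
    edf = float(np.trace(minv @ xtx))
    return beta, minv, rss, edf


def _gcv_objective(log_lams, x, y, pen_blocks):
    n = len(y)
    try:
        _, _, rss, edf = _pen_fit(x, y, pen_blocks, log_lams)
    except np.linalg.LinAlgError:
        return np.inf
    denom = max(n - edf, 1e-8)
    return n * rss / denom**2


def _optimize_lams(x, y, pen_blocks):
    n_pen = len(pen_blocks)
    best, best_val = None, np.inf
    for start in ([0.0] * n_pen, [5.0] * n_pen, [-5.0] * n_pen):
        res = optimize.minimize(
            _gcv_objective, np.asarray(start), args=(x, y, pen_blocks),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-10, "maxiter": 400},
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    return best, best_val


def fit_distance_weight(
    weights_a: np.ndarray,
    weights_b: np.ndarray,
    dist: GeodesicMatrix | np.ndarray,
    k: int = 5,
) -> DistanceWeightModel:
    """Fit weight ~ intercept + group + s_a(distance) + s_b(distance).

    Upper-triangle edge weights of the two groups' networks are the
    response; each group gets its own penalized cubic-spline smooth of
    geodesic distance (basis dimension ``k``, sum-to-zero constrained) and
    the parametric group term captures the overall weight offset of group
    ``b`` relative to group ``a``.  A reduced model with one shared smooth
    provides the analysis-of-deviance comparison for group-specific shape
    differences.
    """
    d = dist.d if isinstance(dist, GeodesicMatrix) else np.asarray(dist)
    wa = np.asarray(weights_a, dtype=float)
    wb = np.asarray(weights_b, dtype=float)
    if wa.shape != d.shape or wb.shape != d.shape:
        raise DataError("weight matrices must match the distance matrix")
    n_v = d.shape[0]
    iu = np.triu_indices(n_v, k=1)
    dv = d[iu]
    if k < 3:
        raise DataError("basis dimension k must be >= 3")
    if k > len(np.unique(dv)):
        raise DataError("basis dimension exceeds number of unique distances")

    y = np.concatenate([wa[iu], wb[iu]])
    x_dist = np.concatenate([dv, dv])
    group = np.concatenate([np.zeros(len(dv)), np.ones(len(dv))])
    n = len(y)

    dmin, dmax = float(x_dist.min()), float(x_dist.max())
    b_all, _, _ = _bspline_basis(x_dist, k, dmin, dmax)
    # sum-to-zero constraint over the pooled sample (mgcv-style centering)
    z = null_space(b_all.mean(axis=0)[None, :])
    bz = b_all @ z
    s_tilde = z.T @ _diff_penalty(k) @ z
    kc = bz.shape[1]

    is_a = group == 0
    ba = np.where(is_a[:, None], bz, 0.0)
    bb = np.where(~is_a[:, None], bz, 0.0)
    x_full = np.column_stack([np.ones(n), group, ba, bb])

    def _block(offset):
        p = np.zeros((x_full.shape[1], x_full.shape[1]))
        p[offset : offset + kc, offset : offset + kc] = s_tilde
        return p

    pen_full = [_block(2), _block(2 + kc)]
    log_lams, gcv = _optimize_lams(x_full, y, pen_full)
    beta, minv, rss, edf = _pen_fit(x_full, y, pen_full, log_lams)
    resid_df = max(n - edf, 1.0)
    scale = rss / resid_df
    vbeta = scale * minv  # Bayesian posterior covariance

    group_coef = float(beta[1])
    group_se = float(np.sqrt(vbeta[1, 1]))
    group_t = group_coef / group_se
    group_p = float(2 * stats.t.sf(abs(group_t), resid_df))

    smooth_f, smooth_p = {}, {}
    for name, off in (("a", 2), ("b", 2 + kc)):
        bg = beta[off : off + kc]
        vg = vbeta[off : off + kc, off : off + kc]
        try:
            fstat = float(bg @ np.linalg.solve(vg, bg)) / kc
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular smooth covariance") from exc
        smooth_f[name] = fstat
        smooth_p[name] = float(stats.f.sf(fstat, kc, resid_df))

    # reduced model: shared smooth
    x_red = np.column_stack([np.ones(n), group, bz])
    pen_red = [_block(2)[: x_red.shape[1], : x_red.shape[1]]]
    log_lams_red, _ = _optimize_lams(x_red, y, pen_red)
    _, _, rss_red, edf_red = _pen_fit(x_red, y, pen_red, log_lams_red)

    dev_diff = rss_red - rss
    dev_df = max(edf - edf_red, 1e-6)
    dev_stat = max(dev_diff, 0.0) / scale
    dev_p = float(stats.chi2.sf(dev_stat, dev_df))

    grid = np.linspace(dmin, dmax, 100)
    bg_grid, _, _ = _bspline_basis(grid, k, dmin, dmax)
    bzg = bg_grid @ z
    zeros = np.zeros_like(bzg)
    xa = np.column_stack([np.ones(100), np.zeros(100), bzg, zeros])
    xb = np.column_stack([np.ones(100), np.ones(100), zeros, bzg])
    pred_a = xa @ beta
    pred_b = xb @ beta
    se_a = np.sqrt(np.einsum("ij,jk,ik->i", xa, vbeta, xa))
    se_b = np.sqrt(np.einsum("ij,jk,ik->i", xb, vbeta, xb))

    return DistanceWeightModel(
        k=k, n_obs=n, edf=edf, scale=scale, gcv=gcv,
        lambdas=tuple(np.exp(log_lams)),
        group_coef=group_coef, group_se=group_se, group_t=group_t,
        group_p=group_p, smooth_f=smooth_f, smooth_p=smooth_p,
        deviance_diff=float(dev_diff), deviance_df=float(dev_df),
        deviance_p=dev_p, grid=grid,
        pred_a=pred_a, se_a=se_a, pred_b=pred_b, se_b=se_b,
    )


def pointwise_compare(model: DistanceWeightModel, fdr_alpha: float = 0.05):
    """Pointwise Z-tests of the group difference along the distance grid.

    ``z = (pred_a - pred_b) / sqrt(se_a^2 + se_b^2)`` at each of the 100
    grid points, with Benjamini-Hochberg correction across points.
    Returns a DataFrame (distance, diff, se, z, p, p_adj, significant).
    """
    import pandas as pd

    from .inference import fdr_bh

    diff = model.pred_a - model.pred_b
    se = np.sqrt(model.se_a**2 + model.se_b**2)
    z = diff / se
    p = 2 * stats.norm.sf(np.abs(z))
    p_adj = fdr_bh(p)
    return pd.DataFrame({
        "distance": model.grid,
        "diff": diff,
        "se": se,
        "z": z,
        "p": p,
        "p_adj": p_adj,
        "significant": p_adj < fdr_alpha,
    })
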
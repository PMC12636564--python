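"""Structural covariance network construction.

Turns subject x parcel surface-area tables into per-group partial
correlation networks: hemisphere averaging, ComBat location-scale
harmonization of scan-site effects, aggregation of parcels into clusters,
precision-matrix partial correlations, sign-restricted subnetworks, and
the distributional checks (normality, variance homogeneity) that justify
the Gaussian partial-correlation model.

Surface-area tables are pandas DataFrames indexed by subject id with one
column per parcel (left-hemisphere columns ``L_<name>``, right-hemisphere
``R_<name>``); phenotype tables carry ``age``, ``sex``, ``group`` and
``site`` columns on the same index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .exceptions import DataError, NumericalError, RankDeficiencyError

__all__ = [
    "CovNetwork",
    "average_hemispheres",
    "harmonize",
    "aggregate_clusters",
    "partial_corr",
    "partial_corr_matrix",
    "sign_subnetwork",
    "distribution_checks",
    "upper_triangle",
]


# ---------------------------------------------------------------------------
# network container


@dataclass
class CovNetwork:
    """Signed partial-correlation network on cluster vertices.

    ``pcorr`` keeps the signed partial correlations (diagonal 1); the edge
    ``weights`` are absolute magnitudes with a zero diagonal, optionally
    restricted to positive-only or negative-only correlations (excluded
    edges zeroed, vertex set retained so metrics stay comparable).
    """

    pcorr: np.ndarray
    names: list = field(default_factory=list)
    mode: str = "absolute"

    def __post_init__(self):
        p = np.asarray(self.pcorr, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise DataError("pcorr must be square")
        if not np.allclose(p, p.T, atol=1e-10):
            raise DataError("pcorr must be symmetric")
        if np.any(np.abs(p) > 1 + 1e-8):
            raise DataError("partial correlations must lie in [-1, 1]")
        if self.mode not in ("absolute", "positive_only", "negative_only"):
            raise DataError(f"unknown mode {self.mode!r}")
        self.pcorr = p
        if not self.names:
            self.names = list(range(p.shape[0]))

    @property
    def n(self) -> int:
        return self.pcorr.shape[0]

    @property
    def weights(self) -> np.ndarray:
        w = np.abs(self.pcorr).copy()
        np.fill_diagonal(w, 0.0)
        if self.mode == "positive_only":
            w[self.pcorr <= 0] = 0.0
        elif self.mode == "negative_only":
            w[self.pcorr >= 0] = 0.0
        np.fill_diagonal(w, 0.0)
        return w

    def upper_values(self) -> np.ndarray:
        """Signed upper-triangle partial correlations (n(n-1)/2 values)."""
        return self.pcorr[np.triu_indices(self.n, k=1)]


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix)
    return m[np.triu_indices(m.shape[0], k=1)]


# ---------------------------------------------------------------------------
# table operations


def _hemi_pairs(columns) -> list[tuple[str, str, str]]:
    lefts = {c[2:]: c for c in columns if str(c).startswith("L_")}
    rights = {c[2:]: c for c in columns if str(c).startswith("R_")}
    if set(lefts) != set(rights) or len(lefts) + len(rights) != len(columns):
        raise DataError("columns are not fully paired as L_*/R_*")
    return [(name, lefts[name], rights[name]) for name in sorted(lefts)]


def average_hemispheres(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of each left/right parcel pair; halves the column count."""
    pairs = _hemi_pairs(table.columns)
    out = {name: (table[lc].to_numpy() + table[rc].to_numpy()) / 2.0
           for name, lc, rc in pairs}
    return pd.DataFrame(out, index=table.index)


def hemisphere_split(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Left- and right-hemisphere subtables with matching column order."""
    pairs = _hemi_pairs(table.columns)
    left = table[[lc for _, lc, _ in pairs]].copy()
    right = table[[rc for _, _, rc in pairs]].copy()
    left.columns = [name for name, _, _ in pairs]
    right.columns = [name for name, _, _ in pairs]
    return left, right


def aggregate_clusters(table: pd.DataFrame, labels) -> pd.DataFrame:
    """Sum member-parcel areas within each cluster (one column per cluster)."""
    if isinstance(labels, dict):
        lab = pd.Series(labels)
    else:
        lab = pd.Series(np.asarray(labels), index=table.columns)
    missing = [c for c in table.columns if c not in lab.index]
    if missing:
        raise DataError(f"unlabeled parcels: {missing[:5]}")
    lab = lab.loc[table.columns]
    out = table.T.groupby(lab.to_numpy()).sum().T
    out.columns = [f"cluster_{c}" for c in out.columns]
    return out


# ---------------------------------------------------------------------------
# ComBat harmonization


def _combat_design(pheno: pd.DataFrame, batches: np.ndarray) -> np.ndarray:
    cols = []
    if "age" in pheno:
        cols.append(pheno["age"].to_numpy(dtype=float))
    if "sex" in pheno:
        sex = pheno["sex"]
        if sex.dtype == object:
            sex = (sex.astype(str).str.upper().isin(["F", "FEMALE", "1"]))
        cols.append(sex.to_numpy(dtype=float))
    if "group" in pheno:
        grp = pd.get_dummies(pheno["group"], drop_first=True)
        for c in grp.columns:
            cols.append(grp[c].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(pheno), 0))


def _aprior(gamma_hat: np.ndarray) -> float:
    m, s2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(gamma_hat: np.ndarray) -> float:
    m, s2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-8):
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(500):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-12)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def harmonize(table: pd.DataFrame, pheno: pd.DataFrame) -> pd.DataFrame:
    """Parametric empirical-Bayes ComBat over scan sites.

    Location-scale model per feature: additive site effects (normal prior)
    and multiplicative site variance effects (inverse-gamma prior) are
    shrunk across features and removed, while age, sex and group effects
    in the design are preserved.  With a single site the output equals the
    input up to numerical tolerance.
    """
    if not table.index.equals(pheno.index):
        pheno = pheno.loc[table.index]
    sites = pheno["site"].to_numpy()
    site_ids, site_inv = np.unique(sites, return_inverse=True)
    n_batch = len(site_ids)
    counts = np.bincount(site_inv)
    if np.any(counts < 2):
        small = site_ids[counts < 2]
        raise DataError(f"sites with < 2 subjects cannot be harmonized: {small}")

    dat = table.to_numpy(dtype=float).T  # features x samples
    n_feat, n_samp = dat.shape
    batch_design = np.eye(n_batch)[site_inv]
    covs = _combat_design(pheno, sites)
    design = np.column_stack([batch_design, covs])

    beta, *_ = np.linalg.lstsq(design, dat.T, rcond=None)
    grand_mean = (counts / n_samp) @ beta[:n_batch]
    if covs.shape[1]:
        cov_effect = (covs @ beta[n_batch:]).T
    else:
        cov_effect = np.zeros_like(dat)
    stand_mean = grand_mean[:, None] + cov_effect
    resid = dat - (design @ beta).T
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)[:, None]
    s_data = (dat - stand_mean) / sd

    if n_batch == 1:
        return table.copy()

    bayes_data = np.empty_like(s_data)
    for b_idx in range(n_batch):
        mask = site_inv == b_idx
        sdat = s_data[:, mask]
        g_hat = sdat.mean(axis=1)
        d_hat = sdat.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, b = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b)
        bayes_data[:, mask] = (sdat - g_star[:, None]) / np.sqrt(
            d_star
        )[:, None]

    out = bayes_data * sd + stand_mean
    return pd.DataFrame(out.T, index=table.index, columns=table.columns)


# ---------------------------------------------------------------------------
# partial correlations


def partial_corr_matrix(data: np.ndarray) -> np.ndarray:
    """Partial correlations from the inverse covariance of ``data`` (n x p).

    ``rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)`` with unit diagonal.
    Requires more subjects than variables; regularized estimation is
    deliberately not offered (dimensionality is reduced by clustering
    instead, which preserves the empirical dependence structure).
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if n <= p:
        raise RankDeficiencyError(
            f"covariance inversion impossible: n_subjects={n} <= n_variables={p}"
        )
    sigma = np.cov(x, rowvar=False, ddof=1)
    try:
        omega = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular covariance matrix") from exc
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def partial_corr(table: pd.DataFrame) -> CovNetwork:
    """Partial-correlation network of a subject x cluster area table."""
    rho = partial_corr_matrix(table.to_numpy(dtype=float))
    return CovNetwork(pcorr=rho, names=list(table.columns), mode="absolute")


def sign_subnetwork(net: CovNetwork, mode: str) -> CovNetwork:
    """Restrict a network to positive-only or negative-only correlations."""
    if net.mode != "absolute":
        raise DataError("sign_subnetwork expects an absolute-mode network")
    return CovNetwork(pcorr=net.pcorr.copy(), names=list(net.names), mode=mode)


# ---------------------------------------------------------------------------
# distributional checks


def _var_f_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided F ratio test var(a)/var(b)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return float(f), float(min(p, 1.0))


def distribution_checks(
    net_a: CovNetwork,
    net_b: CovNetwork,
    table_a: pd.DataFrame | None = None,
    table_b: pd.DataFrame | None = None,
) -> dict:
    """Normality and variance diagnostics for two group networks.

    Per-cluster: Anderson-Darling normality p-values of cluster areas in
    each group and a between-group F-test of area variances.  On the
    vectorized upper-triangle partial correlations (n(n-1)/2 values per
    group): Shapiro-Wilk normality, Welch t-test of means (sign bias) and
    a two-sided F-test of variances (magnitude shift); ``F < 1`` means
    group-a correlations are closer to zero than group-b correlations.
    """
    if net_a.n != net_b.n:
        raise DataError("networks must have the same vertex count")
    r_a, r_b = net_a.upper_values(), net_b.upper_values()
    t_stat, t_p = stats.ttest_ind(r_a, r_b, equal_var=False)
    f_stat, f_p = _var_f_test(r_a, r_b)
    sw_a = stats.shapiro(r_a)
    sw_b = stats.shapiro(r_b)
    report = {
        "n_correlations": len(r_a),
        "correlations": {
            "shapiro_p_a": float(sw_a.pvalue),
            "shapiro_p_b": float(sw_b.pvalue),
            "welch_t": float(t_stat),
            "welch_p": float(t_p),
            "var_F": f_stat,
            "var_F_p": f_p,
        },
    }
    if table_a is not None and table_b is not None:
        if table_a.shape[1] != net_a.n or table_b.shape[1] != net_b.n:
            raise DataError("tables do not match network dimension")
        ad_a = [float(normal_ad(table_a[c].to_numpy())[1]) for c in table_a]
        ad_b = [float(normal_ad(table_b[c].to_numpy())[1]) for c in table_b]
        cluster_f = [
            _var_f_test(table_a[ca].to_numpy(), table_b[cb].to_numpy())
            for ca, cb in zip(table_a.columns, table_b.columns)
        ]
        from .inference import fdr_bh

        f_ps = np.array([p for _, p in cluster_f])
        report["clusters"] = {
            "ad_p_a": ad_a,
            "ad_p_b": ad_b,
            "prop_normal_a": float(np.mean(np.array(ad_a) > 0.05)),
            "prop_normal_b": float(np.mean(np.array(ad_b) > 0.05)),
            "var_F": [f for f, _ in cluster_f],
            "var_F_p": list(map(float, f_ps)),
            "var_F_p_fdr": list(map(float, fdr_bh(f_ps))),
        }
    return report
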
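"""Group matching, permutation inference, resampling SEs and power tools.

Global network metrics yield a single value per group, so group
comparisons use permutation tests that swap subject labels at the level
of the surface-area data and rebuild each group's network inside every
iteration.  Effect sizes are the observed difference scaled by the SD of
the null difference distribution; standard errors come from leave-one-out
jackknife resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

from .exceptions import DataError

__all__ = [
    "PermResult",
    "MatchResult",
    "optimal_match",
    "perm_test_metric",
    "perm_test_distribution",
    "jackknife_se",
    "power_ttest_solve_d",
    "power_perm_sim",
    "fdr_bh",
]


@dataclass
class PermResult:
    """Observed statistic, permutation null and derived quantities.

    ``p`` is the plain proportion of null differences at least as extreme
    as the observed one in the chosen direction (the add-one small-sample
    correction is available via ``plus_one`` at test time).  ``effect``
    is the observed difference divided by the null SD.
    """

    observed: float
    null: np.ndarray = field(repr=False)
    p: float
    effect: float
    direction: str
    n_invalid: int = 0

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p": self.p,
            "effect": self.effect,
            "direction": self.direction,
            "n_iter": int(len(self.null)),
            "n_invalid": self.n_invalid,
            "null_mean": float(np.mean(self.null)),
            "null_sd": float(np.std(self.null, ddof=1)),
        }


def _perm_p(observed: float, null: np.ndarray, direction: str,
            plus_one: bool) -> float:
    if direction == "greater":
        hits = np.sum(null >= observed)
    elif direction == "less":
        hits = np.sum(null <= observed)
    elif direction == "two-sided":
        hits = np.sum(np.abs(null) >= abs(observed))
    else:
        raise DataError(f"unknown direction {direction!r}")
    m = len(null)
    if plus_one:
        return float((hits + 1) / (m + 1))
    return float(hits / m)


def _effect(observed: float, null: np.ndarray) -> float:
    sd = float(np.std(null, ddof=1))
    return observed / sd if sd > 0 else np.nan


# ---------------------------------------------------------------------------
# matching


@dataclass
class MatchResult:
    """1:1 matched affected/control pairs with balance summaries."""

    pairs: pd.DataFrame
    total_age_discrepancy: float
    summary: dict

    def to_dict(self) -> dict:
        return {
            "total_age_discrepancy": self.total_age_discrepancy,
            "summary": self.summary,
            "pairs": self.pairs.to_dict(orient="records"),
        }


def optimal_match(
    affected: pd.DataFrame,
    pool: pd.DataFrame,
    by_age: bool = True,
    by_sex: bool = True,
) -> MatchResult:
    """1:1 optimal matching of controls to affected subjects.

    Within sex strata (when ``by_sex``), the assignment problem minimizing
    the total absolute age difference is solved exactly (Hungarian
    algorithm) — optimal matching with a single covariate is an assignment
    problem, so no propensity model is needed.  Without ``by_age``,
    controls are assigned in input order within each stratum.  No control
    is reused.
    """
    strata = (
        [(s, affected[affected["sex"] == s], pool[pool["sex"] == s])
         for s in affected["sex"].unique()]
        if by_sex else [(None, affected, pool)]
    )
    rows = []
    total = 0.0
    for _, aff_s, pool_s in strata:
        if len(pool_s) < len(aff_s):
            raise DataError(
                f"control pool too small in stratum ({len(pool_s)} < {len(aff_s)})"
            )
        if by_age:
            cost = np.abs(
                aff_s["age"].to_numpy()[:, None]
                - pool_s["age"].to_numpy()[None, :]
            )
            ri, ci = linear_sum_assignment(cost)
            total += float(cost[ri, ci].sum())
        else:
            ri = np.arange(len(aff_s))
            ci = np.arange(len(aff_s))
        for i, j in zip(ri, ci):
            rows.append({
                "affected_id": aff_s.index[i],
                "control_id": pool_s.index[j],
                "affected_age": float(aff_s["age"].iloc[i]),
                "control_age": float(pool_s["age"].iloc[j]),
                "sex": aff_s["sex"].iloc[i],
            })
    pairs = pd.DataFrame(rows)
    ctrl = pool.loc[pairs["control_id"]]
    summary = {
        "affected_age_mean": float(affected["age"].mean()),
        "affected_age_sd": float(affected["age"].std()),
        "control_age_mean": float(ctrl["age"].mean()),
        "control_age_sd": float(ctrl["age"].std()),
        "affected_prop_female": float((affected["sex"] == "F").mean()),
        "control_prop_female": float((ctrl["sex"] == "F").mean()),
    }
    return MatchResult(pairs=pairs, total_age_discrepancy=total,
                       summary=summary)


# ---------------------------------------------------------------------------
# permutation tests


def perm_test_metric(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metric_fn,
    n_iter: int = 10_000,
    direction: str = "two-sided",
    seed: int = 0,
    plus_one: bool = False,
) -> PermResult:
    """Permutation test of a global network metric between two groups.

    ``metric_fn`` maps a subject x cluster area table to a scalar (it
    typically rebuilds the partial-correlation network internally).  Each
    iteration pools all subjects, splits them randomly back into the
    original group sizes and recomputes the metric difference a - b.
    Iterations where ``metric_fn`` fails are recorded and excluded.
    """
    if table_a.shape[1] != table_b.shape[1]:
        raise DataError("groups must share the cluster set")
    rng = np.random.default_rng(seed)
    obs = float(metric_fn(table_a) - metric_fn(table_b))
    pooled = pd.concat([table_a, table_b])
    n_a, n_tot = len(table_a), len(pooled)
    null, n_invalid = [], 0
    for _ in range(n_iter):
        perm = rng.permutation(n_tot)
        ta = pooled.iloc[perm[:n_a]]
        tb = pooled.iloc[perm[n_a:]]
        try:
            null.append(float(metric_fn(ta) - metric_fn(tb)))
        except Exception:
            n_invalid += 1
    null = np.asarray(null)
    if len(null) == 0:
        raise DataError("all permutation iterations failed")
    return PermResult(
        observed=obs, null=null,
        p=_perm_p(obs, null, direction, plus_one),
        effect=_effect(obs, null), direction=direction, n_invalid=n_invalid,
    )


_DIST_STATS = {
    "mean": lambda v: float(np.mean(v)),
    "var": lambda v: float(np.var(v, ddof=1)),
    "skew": lambda v: float(stats.skew(v)),
    "kurt": lambda v: float(stats.kurtosis(v)),
}


def perm_test_distribution(
    values_a: np.ndarray,
    values_b: np.ndarray,
    stat: str = "mean",
    n_iter: int = 10_000,
    direction: str = "two-sided",
    seed: int = 0,
    plus_one: bool = False,
) -> PermResult:
    """Permutation comparison of two per-vertex value distributions.

    For ``mean``/``var``/``skew``/``kurt`` the statistic is the group
    difference and the null pools and re-splits the values.  For ``corr``
    the statistic is the Pearson correlation between the paired vectors
    and the null permutes the vertex alignment of one vector.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("value vectors must have equal length")
    rng = np.random.default_rng(seed)
    if stat == "corr":
        if np.std(a) == 0 or np.std(b) == 0:
            raise DataError("correlation undefined for constant vectors")
        obs = float(np.corrcoef(a, b)[0, 1])
        null = np.array([
            np.corrcoef(a, rng.permutation(b))[0, 1] for _ in range(n_iter)
        ])
    elif stat in _DIST_STATS:
        fn = _DIST_STATS[stat]
        obs = fn(a) - fn(b)
        pooled = np.concatenate([a, b])
        n_a = len(a)
        null = np.empty(n_iter)
        for i in range(n_iter):
            perm = rng.permutation(pooled)
            null[i] = fn(perm[:n_a]) - fn(perm[n_a:])
    else:
        raise DataError(f"unknown statistic {stat!r}")
    return PermResult(
        observed=obs, null=null,
        p=_perm_p(obs, null, direction, plus_one),
        effect=_effect(obs, null), direction=direction,
    )


def jackknife_se(table: pd.DataFrame, metric_fn) -> float:
    """Leave-one-subject-out jackknife standard error of a metric.

    ``se = sqrt((n - 1)/n * sum((theta_(i) - theta_bar)^2))``.
    """
    n = len(table)
    if n < 3:
        raise DataError("jackknife needs at least 3 subjects")
    thetas = np.array([
        float(metric_fn(table.drop(table.index[i]))) for i in range(n)
    ])
    theta_bar = thetas.mean()
    return float(np.sqrt((n - 1) / n * np.sum((thetas - theta_bar) ** 2)))


# ---------------------------------------------------------------------------
# power analyses


def power_ttest_solve_d(
    n_per_group: int, power: float = 0.8, alpha: float = 0.05
) -> float:
    """Smallest detectable Cohen's d for a two-sided two-sample t-test.

    Solved numerically from the noncentral t distribution.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise DataError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        return 0.0
    return float(TTestIndPower().solve_power(
        effect_size=None, nobs1=n_per_group, alpha=alpha, power=power,
        ratio=1.0, alternative="two-sided",
    ))


def power_perm_sim(
    n_per_group: int = 102,
    d: float = 0.4,
    alpha: float = 0.05,
    n_outer: int = 2000,
    n_inner: int = 500,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of a permutation test of a mean difference.

    Outer replicates draw samples of ``n_per_group`` from N(0, 1) and
    N(d, 1); inner label permutations give a two-sided p-value for the
    mean difference; power is the fraction of replicates with p <= alpha.
    """
    rng = np.random.default_rng(seed)
    n = n_per_group
    hits = 0
    base = np.empty(2 * n)
    for _ in range(n_outer):
        base[:n] = rng.standard_normal(n)
        base[n:] = rng.standard_normal(n) + d
        obs = base[:n].mean() - base[n:].mean()
        # vectorised label permutations: each row a shuffled pooled sample
        tiled = np.broadcast_to(base, (n_inner, 2 * n))
        perms = rng.permuted(tiled, axis=1)
        null = perms[:, :n].mean(axis=1) - perms[:, n:].mean(axis=1)
        p = np.mean(np.abs(null) >= abs(obs))
        if p <= alpha:
            hits += 1
    return hits / n_outer


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
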
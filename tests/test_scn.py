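"""SCN construction: hemisphere averaging, ComBat, aggregation,
partial correlations and distributional checks."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from scnkit import scn
from scnkit.exceptions import DataError, RankDeficiencyError

from _oracles import residual_pcorr


def make_table(values, n_hemi):
    cols = [f"L_{i:03d}" for i in range(n_hemi)] + \
           [f"R_{i:03d}" for i in range(n_hemi)]
    idx = [f"s{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=idx, columns=cols)


class TestAverageHemispheres:
    def test_identical_halves_pass_through(self, rng):
        half = rng.normal(500, 50, size=(6, 4))
        table = make_table(np.hstack([half, half]), 4)
        out = scn.average_hemispheres(table)
        assert np.allclose(out.to_numpy(), half)

    def test_arithmetic_mean(self):
        table = make_table(np.array([[10.0, 20.0]]), 1)
        out = scn.average_hemispheres(table)
        assert out.iloc[0, 0] == 15.0

    def test_shape_contract(self, rng):
        table = make_table(rng.normal(size=(7, 10)), 5)
        out = scn.average_hemispheres(table)
        assert out.shape == (7, 5)

    def test_unpaired_columns_rejected(self, rng):
        table = make_table(rng.normal(size=(3, 4)), 2)
        with pytest.raises(DataError):
            scn.average_hemispheres(table.drop(columns=["R_001"]))


class TestAggregateClusters:
    def test_singleton_partition_is_identity(self, rng):
        t = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"))
        out = scn.aggregate_clusters(t, {"a": 0, "b": 1, "c": 2})
        assert np.allclose(out.to_numpy(), t.to_numpy())

    def test_single_cluster_is_row_sum(self, rng):
        t = pd.DataFrame(rng.normal(size=(5, 4)))
        out = scn.aggregate_clusters(t, np.zeros(4, dtype=int))
        assert np.allclose(out.to_numpy().ravel(), t.sum(axis=1))

    def test_two_pairs(self):
        t = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], columns=list("wxyz"))
        out = scn.aggregate_clusters(t, {"w": 0, "x": 0, "y": 1, "z": 1})
        assert list(out.iloc[0]) == [3.0, 7.0]

    def test_unlabeled_parcel_rejected(self):
        t = pd.DataFrame([[1.0, 2.0]], columns=list("ab"))
        with pytest.raises(DataError):
            scn.aggregate_clusters(t, {"a": 0})


class TestPartialCorr:
    def test_orthogonal_columns_give_zero(self, rng):
        # whitened centred columns -> exactly diagonal sample covariance
        x = rng.normal(size=(30, 4))
        x -= x.mean(axis=0)
        cov = np.cov(x, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        q = x @ vecs @ np.diag(vals**-0.5) @ vecs.T
        rho = scn.partial_corr_matrix(q)
        off = rho[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 1e-8)

    def test_collider_induces_negative_partial(self, rng):
        x1 = rng.standard_normal(500)
        x2 = rng.standard_normal(500)
        x3 = x1 + x2 + 0.3 * rng.standard_normal(500)
        rho = scn.partial_corr_matrix(np.column_stack([x1, x2, x3]))
        assert rho[0, 1] < -0.5  # conditioning on the sum flips the sign
        assert abs(np.corrcoef(x1, x2)[0, 1]) < 0.1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_residual_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((40, 5)) @ rng.standard_normal((5, 5))
        assert scn.partial_corr_matrix(x) == pytest.approx(
            residual_pcorr(x), abs=1e-8)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((50, 6))
        x2 = x * np.array([1.0, 10.0, 0.2, 3.0, 1.0, 500.0])
        assert scn.partial_corr_matrix(x2) == pytest.approx(
            scn.partial_corr_matrix(x), abs=1e-10)

    def test_rank_deficiency_is_hard_error(self, rng):
        with pytest.raises(RankDeficiencyError):
            scn.partial_corr_matrix(rng.standard_normal((10, 10)))
        with pytest.raises(RankDeficiencyError):
            scn.partial_corr_matrix(rng.standard_normal((8, 10)))


class TestSignSubnetworks:
    def make_net(self, rng, n=8):
        x = rng.standard_normal((60, n))
        return scn.partial_corr(pd.DataFrame(x))

    def test_positive_and_negative_partition_absolute(self, rng):
        net = self.make_net(rng)
        pos = scn.sign_subnetwork(net, "positive_only")
        neg = scn.sign_subnetwork(net, "negative_only")
        assert np.allclose(pos.weights + neg.weights, net.weights)
        assert np.all(pos.weights * neg.weights == 0.0)

    def test_all_positive_gives_empty_negative(self):
        p = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        neg = scn.sign_subnetwork(scn.CovNetwork(pcorr=p), "negative_only")
        assert np.all(neg.weights == 0.0)

    def test_mixed_sign_masks(self):
        p = np.array([[1.0, 0.4, -0.2], [0.4, 1.0, 0.0], [-0.2, 0.0, 1.0]])
        pos = scn.sign_subnetwork(scn.CovNetwork(pcorr=p), "positive_only")
        assert pos.weights[0, 1] == pytest.approx(0.4)
        assert pos.weights[0, 2] == 0.0
        neg = scn.sign_subnetwork(scn.CovNetwork(pcorr=p), "negative_only")
        assert neg.weights[0, 2] == pytest.approx(0.2)
        assert neg.weights[0, 1] == 0.0

    def test_requires_absolute_mode(self, rng):
        net = self.make_net(rng)
        pos = scn.sign_subnetwork(net, "positive_only")
        with pytest.raises(DataError):
            scn.sign_subnetwork(pos, "negative_only")


class TestHarmonize:
    @staticmethod
    def pheno_for(index, sites, rng):
        return pd.DataFrame({
            "age": rng.uniform(20, 60, len(index)),
            "sex": rng.choice(["F", "M"], len(index)),
            "group": rng.choice(["control", "affected"], len(index)),
            "site": sites,
        }, index=index)

    def test_single_site_identity(self, rng):
        t = pd.DataFrame(rng.normal(500, 40, size=(20, 5)),
                         index=[f"s{i}" for i in range(20)])
        ph = self.pheno_for(t.index, ["one"] * 20, rng)
        out = scn.harmonize(t, ph)
        assert np.allclose(out.to_numpy(), t.to_numpy(), atol=1e-8)

    def test_additive_site_shift_removed(self, rng):
        # site b = exact copy of site a plus a pure additive offset, with
        # covariates balanced, so the whole gap is a batch effect
        base = rng.normal(500, 40, size=(20, 6))
        t = pd.DataFrame(np.vstack([base, base + 25.0]),
                         index=[f"s{i}" for i in range(40)])
        sites = np.array(["a"] * 20 + ["b"] * 20)
        ph = pd.DataFrame({
            "age": np.tile(np.linspace(20, 50, 20), 2),
            "sex": np.tile(["F", "M"], 20),
            "group": np.tile(["control", "affected"], 20),
            "site": sites,
        }, index=t.index)
        out = scn.harmonize(t, ph)
        gap = out[sites == "b"].mean() - out[sites == "a"].mean()
        # the shared 25 mm^2 offset is removed; empirical-Bayes shrinkage
        # of per-feature location effects leaves only small residuals
        assert abs(gap.mean()) < 2.0
        raw_gap = t[sites == "b"].mean() - t[sites == "a"].mean()
        assert np.all(np.abs(gap) < 0.5 * np.abs(raw_gap))

    def test_covariate_effect_preserved(self, rng):
        n = 60
        age = rng.uniform(20, 60, n)
        base = 400 + 2.0 * age[:, None] + rng.normal(0, 5, size=(n, 4))
        sites = np.array(["a", "b"] * (n // 2))
        t = pd.DataFrame(base, index=[f"s{i}" for i in range(n)])
        ph = self.pheno_for(t.index, sites, rng)
        ph["age"] = age
        out = scn.harmonize(t, ph)
        for col in out:
            slope = np.polyfit(age, out[col], 1)[0]
            assert slope == pytest.approx(2.0, abs=0.3)

    def test_small_site_rejected(self, rng):
        t = pd.DataFrame(rng.normal(size=(5, 3)),
                         index=[f"s{i}" for i in range(5)])
        ph = self.pheno_for(t.index, ["a", "a", "a", "a", "b"], rng)
        with pytest.raises(DataError):
            scn.harmonize(t, ph)

    def test_matches_sva_combat(self, tmp_path):
        """Independent oracle: Bioconductor sva::ComBat on the same data."""
        rng = np.random.default_rng(0)
        n, p = 40, 6
        x = rng.normal(500, 50, size=(n, p))
        sites = np.array(["A", "B"] * (n // 2))
        x[sites == "B"] += rng.normal(15, 5, size=p)
        ph = self.pheno_for([f"s{i}" for i in range(n)], sites, rng)
        t = pd.DataFrame(x, index=ph.index, columns=[f"f{j}" for j in range(p)])
        ours = scn.harmonize(t, ph)

        t.to_csv(tmp_path / "dat.csv")
        ph.to_csv(tmp_path / "ph.csv")
        rcode = f"""
suppressMessages(library(sva))
dat <- as.matrix(read.csv("{tmp_path}/dat.csv", row.names=1))
ph <- read.csv("{tmp_path}/ph.csv", row.names=1)
mod <- model.matrix(~ age + factor(sex) + factor(group), data=ph)
out <- ComBat(dat=t(dat), batch=ph$site, mod=mod, par.prior=TRUE)
write.csv(t(out), "{tmp_path}/out.csv")
"""
        (tmp_path / "run.R").write_text(rcode)
        proc = subprocess.run(
            ["Rscript", str(tmp_path / "run.R")],
            capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/sva unavailable: {proc.stderr[-200:]}")
        theirs = pd.read_csv(tmp_path / "out.csv", index_col=0)
        # sva iterates its EB solver to 1e-4 relative change; agreement is
        # limited by that tolerance, not by the model
        assert np.abs(ours.to_numpy() - theirs.to_numpy()).max() < 1e-3


class TestDistributionChecks:
    def test_self_comparison_is_null(self, rng):
        x = rng.standard_normal((80, 10))
        net = scn.partial_corr(pd.DataFrame(x))
        rep = scn.distribution_checks(net, net)
        assert rep["correlations"]["welch_t"] == pytest.approx(0.0, abs=1e-12)
        assert rep["correlations"]["var_F"] == pytest.approx(1.0)

    def test_62_clusters_give_1891_correlations(self, rng):
        x = rng.standard_normal((100, 62))
        net = scn.partial_corr(pd.DataFrame(x))
        rep = scn.distribution_checks(net, net)
        assert rep["n_correlations"] == 1891

    def test_null_correlations_centred_on_zero(self, rng):
        x = rng.standard_normal((150, 20))
        y = rng.standard_normal((150, 20))
        na, nb = scn.partial_corr(pd.DataFrame(x)), scn.partial_corr(pd.DataFrame(y))
        for net in (na, nb):
            vals = net.upper_values()
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean()) < 2 * se + 0.01
        rep = scn.distribution_checks(na, nb)
        assert rep["correlations"]["welch_p"] > 0.01

    def test_group_effect_direction_and_cluster_reports(self, effect_dataset):
        """Affected group generated with stronger couplings: F(control /
        affected) < 1 and most cluster sums pass normality."""
        from scnkit.clustering import ward_cluster
        from scnkit.synthetic import precision_to_pcorr

        ds = effect_dataset
        avg = scn.average_hemispheres(ds.areas)
        labels = ward_cluster(
            precision_to_pcorr(ds.precision_control), 20).labels
        lab_map = dict(zip(avg.columns, labels))
        agg = scn.aggregate_clusters(avg, lab_map)
        gc = agg.loc[ds.phenotypes["group"] == "control"]
        ga = agg.loc[ds.phenotypes["group"] == "affected"]
        rep = scn.distribution_checks(
            scn.partial_corr(gc), scn.partial_corr(ga), gc, ga)
        assert rep["correlations"]["var_F"] < 1.0
        assert rep["clusters"]["prop_normal_a"] >= 0.6
        assert rep["clusters"]["prop_normal_b"] >= 0.6
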
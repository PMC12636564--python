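"""End-to-end orchestration of the SCN analysis.

Stage order mirrors the study design: load or generate surface areas ->
average hemispheres -> ComBat harmonization -> cluster-count selection
(optional) and Ward clustering on a dedicated control pool -> cluster
aggregation -> per-group partial-correlation networks -> distribution
checks -> global metrics and JSD -> geodesics and small-world propensity
-> distance-weight GAM with pointwise tests -> permutation inference with
jackknife SEs.  Every artifact is written to the output directory along
with a manifest recording the configuration hash and all seeds, which
fully determines a rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, inference, netmetrics, scn, spatial, synthetic
from .exceptions import ConfigError, DataError

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("scnkit")


@dataclass
class RunConfig:
    """Reproducible configuration of one pipeline run.

    Exactly one of ``synthetic`` (generation block, see
    :class:`~scnkit.synthetic.SynthConfig`) or ``inputs`` (paths to
    areas TSV / phenotypes CSV / layout CSV) must be provided.
    """

    outdir: str = "scn_run"
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    n_cluster_pool: int = 650
    K: int | None = None
    K_range: list | None = None
    n_selection_seeds: int = 10
    n_subsamples: int = 20
    n_perm: int = 10_000
    perm_seed: int | None = None
    swp_n_random: int = 10
    swp_seed: int | None = None
    gam_k: int = 5
    modes: tuple = ("absolute",)
    harmonize: bool = True

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("provide exactly one of 'synthetic' or 'inputs'")
        if self.K is None and self.K_range is None:
            raise ConfigError("provide K or K_range")
        if self.perm_seed is None:
            self.perm_seed = self.seed + 101
        if self.swp_seed is None:
            self.swp_seed = self.seed + 202

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "outdir", "seed", "synthetic", "inputs", "n_cluster_pool", "K",
            "K_range", "n_selection_seeds", "n_subsamples", "n_perm",
            "perm_seed", "swp_n_random", "swp_seed", "gam_k", "harmonize")}
        d["modes"] = list(self.modes)
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config file must hold a mapping")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"bad config key: {exc}") from exc


def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    for key in ("areas", "phenotypes", "layout"):
        if key not in paths:
            raise ConfigError(f"inputs block missing {key!r}")
    areas = pd.read_csv(paths["areas"], sep="\t", index_col="subject_id")
    pheno = pd.read_csv(paths["phenotypes"], index_col="subject_id")
    lay = pd.read_csv(paths["layout"])
    layout = synthetic.SphereLayout(
        points=lay[["x", "y", "z"]].to_numpy(), r=float(lay["r"].iloc[0]))
    if not areas.index.equals(pheno.index):
        raise DataError("areas and phenotype tables disagree on subjects")
    return areas, pheno, layout, None


def _generate(cfg: RunConfig):
    syn = synthetic.SynthConfig(**{**(cfg.synthetic or {}), "seed": cfg.seed})
    ds = synthetic.generate_dataset(syn)
    pool_cfg = synthetic.SynthConfig(
        **{**syn.to_dict(), "age_range": tuple(syn.age_range),
           "n_subjects_per_group": cfg.n_cluster_pool, "seed": cfg.seed + 7})
    pool_areas, _ = synthetic.sample_group(
        pool_cfg, ds.precision_control, group="pool",
        rng=np.random.default_rng(cfg.seed + 7))
    return ds, pool_areas


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write artifacts; returns a results summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": cfg.digest()}
    stage_times: dict = {}

    def _stage(name):
        log.info("stage: %s", name)
        stage_times[name] = time.time()
        return name

    def _done(name):
        stage_times[name] = round(time.time() - stage_times[name], 3)

    try:
        s = _stage("load")
        if cfg.synthetic is not None:
            ds, pool_areas = _generate(cfg)
            areas, pheno, layout = ds.areas, ds.phenotypes, ds.layout
            hemi_points = ds.hemi_layout.points
            ds.write(outdir / "data")
        else:
            areas, pheno, layout, _ = _load_inputs(cfg)
            pool_areas = None
            h = areas.shape[1] // 2
            hemi_points = layout.points[:h]
        _done(s)

        s = _stage("harmonize")
        if cfg.harmonize and pheno["site"].nunique() > 1:
            areas_h = scn.harmonize(areas, pheno)
        else:
            areas_h = areas
        _done(s)

        s = _stage("cluster")
        cluster_table = pool_areas if pool_areas is not None else \
            areas_h[pheno["group"] == "control"]
        if cfg.K_range is not None:
            report = clustering.select_K(
                cluster_table, cfg.K_range, n_seeds=cfg.n_selection_seeds,
                n_subsamples=cfg.n_subsamples, seed=cfg.seed)
            chosen_k = report.modal_K
            (outdir / "selection_report.json").write_text(
                json.dumps(report.to_dict(), indent=1))
        else:
            chosen_k = cfg.K
        avg_pool = scn.average_hemispheres(cluster_table)
        pc_pool = scn.partial_corr_matrix(avg_pool.to_numpy())
        labels = clustering.ward_cluster(pc_pool, chosen_k).labels
        pd.DataFrame({"parcel": avg_pool.columns, "cluster": labels}).to_csv(
            outdir / "cluster_labels.csv", index=False)
        results["K"] = int(chosen_k)
        _done(s)

        s = _stage("aggregate")
        avg = scn.average_hemispheres(areas_h)
        label_map = dict(zip(avg_pool.columns, labels))
        agg = scn.aggregate_clusters(avg, label_map)
        groups = {}
        for g in ("control", "affected"):
            groups[g] = agg.loc[pheno["group"] == g]
        _done(s)

        s = _stage("networks")
        nets = {g: scn.partial_corr(t) for g, t in groups.items()}
        for g, net in nets.items():
            pd.DataFrame(net.pcorr, index=net.names, columns=net.names) \
                .to_csv(outdir / f"pcorr_{g}.csv")
        checks = scn.distribution_checks(
            nets["control"], nets["affected"],
            groups["control"], groups["affected"])
        (outdir / "distribution_checks.json").write_text(
            json.dumps(checks, indent=1))
        results["distribution_checks"] = checks["correlations"]
        _done(s)

        s = _stage("metrics")
        metric_sets = {}
        for mode in cfg.modes:
            for g, net in nets.items():
                use = net if mode == "absolute" else scn.sign_subnetwork(net, mode)
                metric_sets[f"{g}_{mode}"] = netmetrics.compute_metrics(use.weights)
        (outdir / "metrics.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in metric_sets.items()}, indent=1))
        results["metrics"] = {
            k: {m: getattr(v, m) for m in ("C", "L", "E_glob", "JSD_global")}
            for k, v in metric_sets.items()}
        _done(s)

        s = _stage("spatial")
        cents, flags = spatial.cluster_centroids(
            hemi_points, labels, r=float(np.linalg.norm(hemi_points[0])))
        geo = spatial.geodesics(cents, r=float(np.linalg.norm(hemi_points[0])))
        pd.DataFrame(geo.d).to_csv(outdir / "geodesics.csv", index=False)
        swp_results = {
            g: spatial.swp(net.weights, geo, n_random=cfg.swp_n_random,
                           seed=cfg.swp_seed)
            for g, net in nets.items()}
        (outdir / "swp.json").write_text(json.dumps(
            {g: r.to_dict() for g, r in swp_results.items()}, indent=1))
        results["swp"] = {g: {"phi": r.phi, "delta": r.delta}
                          for g, r in swp_results.items()}

        gam = spatial.fit_distance_weight(
            nets["control"].weights, nets["affected"].weights, geo,
            k=cfg.gam_k)
        pw = spatial.pointwise_compare(gam)
        pw.to_csv(outdir / "pointwise.csv", index=False)
        (outdir / "gam.json").write_text(json.dumps(gam.summary_dict(), indent=1))
        results["gam"] = {
            "group_coef": gam.group_coef, "group_p": gam.group_p,
            "n_significant_points": int(pw["significant"].sum())}
        _done(s)

        s = _stage("permutation")
        metric_fns = {
            "C": lambda t: netmetrics.global_clustering(scn.partial_corr(t).weights),
            "L": lambda t: netmetrics.path_length(scn.partial_corr(t).weights),
            "E_glob": lambda t: netmetrics.efficiency(scn.partial_corr(t).weights),
            "JSD_global": lambda t: netmetrics.jsd_complexity(
                scn.partial_corr(t).weights)[0],
        }
        perm_out, jack_out = {}, {}
        for i, (name, fn) in enumerate(metric_fns.items()):
            res = inference.perm_test_metric(
                groups["affected"], groups["control"], fn,
                n_iter=cfg.n_perm, direction="two-sided",
                seed=cfg.perm_seed + i)
            perm_out[name] = res.to_dict()
            jack_out[name] = {
                g: inference.jackknife_se(t, fn) for g, t in groups.items()}
        (outdir / "permutation.json").write_text(json.dumps(perm_out, indent=1))
        (outdir / "jackknife.json").write_text(json.dumps(jack_out, indent=1))
        results["permutation"] = {
            k: {"p": v["p"], "effect": v["effect"], "observed": v["observed"]}
            for k, v in perm_out.items()}
        results["jackknife_se"] = jack_out
        _done(s)
    except Exception as exc:
        exc.stage = s  # let callers report which stage aborted
        log.error("stage %r failed: %s", s, exc)
        raise

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "seeds": {"main": cfg.seed, "perm": cfg.perm_seed, "swp": cfg.swp_seed},
        "stage_seconds": stage_times,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "results.json").write_text(json.dumps(results, indent=1))
    return results
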
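"""Synthetic cortical surface-area data with SCN structure.

Real parcellated-morphometry datasets are access-restricted, so the whole
pipeline is exercised on a generator that reproduces the statistical
features the analysis relies on: approximately normal cluster areas,
partial correlations distributed around zero, covariance magnitude
decaying with cortical geodesic distance (strong short-range coupling),
a group effect that scales correlation magnitude, and additive /
multiplicative scan-site batch effects.

The generative model is hierarchical.  Parcels are laid out on a sphere
(one Fibonacci lattice per hemisphere, mirrored), partitioned into
spatially contiguous latent clusters of ~3 parcels (the scale of the
atlas reduction the analysis performs).  A Gaussian Markov random field
over the latent clusters carries the dependence structure: its precision
off-diagonals combine a steep short-range component and a slow
near-uniform component, each with random signs and magnitudes decaying
with the geodesic distance between cluster centroids, scaled to fixed
spectral radii so the matrix stays comfortably positive definite.  Each
parcel is its cluster's latent value plus independent within-cluster
noise; left and right hemisphere parcels are mirrored copies sharing the
parcel signal plus independent hemisphere noise.  The affected group's
latent precision off-diagonals are multiplied by ``group_scale``, so
values > 1 strengthen partial correlations throughout the network.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError
from .spatial import pairwise_geodesics

__all__ = [
    "SynthConfig",
    "SphereLayout",
    "SyntheticDataset",
    "make_sphere_layout",
    "build_precision",
    "sample_group",
    "generate_dataset",
    "latent_cluster_labels",
    "precision_to_pcorr",
]


@dataclass
class SphereLayout:
    """Quasi-uniform parcel centroids on a sphere of radius ``r`` (mm)."""

    points: np.ndarray
    r: float

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise DataError("layout points must be an (n, 3) array")
        norms = np.linalg.norm(pts, axis=1)
        if not np.allclose(norms, self.r, rtol=1e-6):
            raise DataError("layout points must lie on the sphere")
        self.points = pts

    @property
    def n(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parcel_id": np.arange(self.n),
            "x": self.points[:, 0],
            "y": self.points[:, 1],
            "z": self.points[:, 2],
            "r": self.r,
        })


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the reference study design: 102 subjects per group,
    360 parcels (180 mirrored left/right pairs) on a 100 mm sphere, two
    scan sites, latent clusters of ~3 parcels (mean cluster size 2.9 in
    the 62-cluster atlas reduction).

    ``distance_decay_rate`` (1/mm) sets the steep short-range coupling
    scale (1/0.04 = 25 mm, a few centroid spacings); the slow component
    uses ``flat_decay_rate`` (default ``distance_decay_rate / 20``) and
    models the weak, near-uniform long-range covariance floor.
    ``coupling`` and ``flat_coupling`` are the spectral radii of the two
    off-diagonal components of the latent precision; their sum times
    ``group_scale`` must stay below 1 for the affected matrix to remain
    positive definite without diagonal loading (the loading safety net
    otherwise shrinks all partial correlations).  ``group_scale``
    multiplies the affected group's latent precision off-diagonals
    (1.0 = null).
    """

    n_subjects_per_group: int = 102
    n_parcels: int = 360
    n_sites: int = 2
    precision_sparsity: float = 1.0
    distance_decay_rate: float = 0.04
    flat_decay_rate: float | None = None
    coupling: float = 0.15
    flat_coupling: float = 0.5
    group_scale: float = 1.0
    site_shift: float = 20.0
    site_scale: float = 0.05
    age_range: tuple = (18.0, 55.0)
    sex_ratio: float = 0.5
    seed: int = 0
    radius: float = 100.0
    n_latent_clusters: int | None = None
    within_cluster_noise: float = 0.3
    hemi_noise_sd: float = 0.3
    mean_area: float = 500.0
    area_scale: float = 60.0
    area_floor: float = 1.0
    pd_margin: float = 0.01

    def validate(self) -> "SynthConfig":
        if self.n_parcels < 2 or self.n_parcels % 2:
            raise ConfigError("n_parcels must be an even count >= 2")
        if self.n_subjects_per_group < 2:
            raise ConfigError("need at least 2 subjects per group")
        if not 0 <= self.precision_sparsity <= 1:
            raise ConfigError("precision_sparsity must be in [0, 1]")
        if self.distance_decay_rate <= 0:
            raise ConfigError("distance_decay_rate must be positive")
        if self.coupling < 0 or self.flat_coupling < 0:
            raise ConfigError("spectral couplings must be >= 0")
        if self.group_scale < 0:
            raise ConfigError("group_scale must be >= 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ConfigError("sex_ratio must be in [0, 1]")
        if self.n_sites < 1:
            raise ConfigError("need at least one site")
        k = self.latent_k
        if not 1 <= k <= self.n_hemi:
            raise ConfigError("n_latent_clusters out of range")
        return self

    @property
    def n_hemi(self) -> int:
        return self.n_parcels // 2

    @property
    def latent_k(self) -> int:
        if self.n_latent_clusters is not None:
            return self.n_latent_clusters
        return max(1, self.n_hemi // 3)

    @property
    def flat_decay(self) -> float:
        if self.flat_decay_rate is not None:
            return self.flat_decay_rate
        return self.distance_decay_rate / 20.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d


def make_sphere_layout(n_parcels: int, r: float) -> SphereLayout:
    """Deterministic Fibonacci-lattice layout of ``n_parcels`` points.

    The golden-angle spiral gives near-uniform coverage, avoiding the
    degenerate clustered centroids a random layout can produce.
    """
    if n_parcels < 2:
        raise DataError("need at least 2 parcels")
    i = np.arange(n_parcels)
    golden = (1 + np.sqrt(5)) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n_parcels
    rho = np.sqrt(np.clip(1 - z**2, 0.0, 1.0))
    pts = r * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return SphereLayout(points=pts, r=r)


def latent_cluster_labels(cfg: SynthConfig) -> np.ndarray:
    """Planted partition of hemisphere parcels into contiguous clusters.

    Consecutive Fibonacci-spiral indices are spatial neighbours, so
    equal blocks of indices give compact, contiguous planted clusters.
    """
    h = cfg.n_hemi
    return (np.arange(h) * cfg.latent_k) // h


def build_precision(
    cfg: SynthConfig, layout: SphereLayout, group: str = "control"
) -> np.ndarray:
    """Parcel-level precision matrix implied by the latent-cluster GMRF.

    The latent precision over cluster centroids is ``I`` minus two
    random-sign components whose magnitudes decay with geodesic distance
    (``exp(-decay * d)``), masked to ``precision_sparsity`` support and
    rescaled to spectral radii ``coupling`` and ``flat_coupling``.  The
    affected variant multiplies the latent off-diagonals by
    ``group_scale``; any variant whose minimum eigenvalue falls below
    ``pd_margin`` is diagonally loaded (``+ lambda I``) back to it.  The
    returned matrix is the inverse of the parcel-level covariance
    (cluster latents shared within planted clusters plus within-cluster
    noise), hence symmetric positive definite by construction.
    """
    cfg.validate()
    h = cfg.n_hemi
    if layout.n != h:
        raise DataError("layout must have one point per hemisphere parcel")
    if group not in ("control", "affected"):
        raise ConfigError(f"unknown group {group!r}")
    labels = latent_cluster_labels(cfg)
    k = cfg.latent_k
    cents = np.array([layout.points[labels == c].mean(axis=0)
                      for c in range(k)])
    if k == 1:
        omega_y = np.eye(1)
    else:
        d = pairwise_geodesics(cents, layout.r)
        iu = np.triu_indices(k, 1)
        rng = np.random.default_rng(cfg.seed)
        off = np.zeros((k, k))
        for decay, rho_target in (
            (cfg.distance_decay_rate, cfg.coupling),
            (cfg.flat_decay, cfg.flat_coupling),
        ):
            support = rng.random(len(iu[0])) < cfg.precision_sparsity
            signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
            comp = np.zeros((k, k))
            with np.errstate(under="ignore"):
                comp[iu] = support * signs * np.exp(-decay * d[iu])
            comp = comp + comp.T
            rho = float(np.max(np.abs(np.linalg.eigvalsh(comp)))) \
                if np.any(comp) else 0.0
            if rho > 0:
                off += comp * (rho_target / rho)
        if group == "affected":
            off = off * cfg.group_scale
        omega_y = off + np.eye(k)
        min_eig = float(np.linalg.eigvalsh(omega_y)[0])
        if min_eig < cfg.pd_margin:
            omega_y += (cfg.pd_margin - min_eig) * np.eye(k)

    sigma_y = np.linalg.inv(omega_y)
    sigma_parcel = sigma_y[np.ix_(labels, labels)] \
        + cfg.within_cluster_noise**2 * np.eye(h)
    return np.linalg.inv(sigma_parcel)


def _site_effects(cfg: SynthConfig, rng: np.random.Generator):
    """Per-site, per-parcel additive shifts and multiplicative factors."""
    shape = (cfg.n_sites, cfg.n_parcels)
    shifts = rng.normal(0.0, cfg.site_shift, size=shape) \
        if cfg.site_shift > 0 else np.zeros(shape)
    scales = np.exp(rng.normal(0.0, cfg.site_scale, size=shape)) \
        if cfg.site_scale > 0 else np.ones(shape)
    return shifts, scales


def sample_group(
    cfg: SynthConfig,
    precision: np.ndarray,
    group: str = "control",
    rng: np.random.Generator | None = None,
    site_effects: tuple[np.ndarray, np.ndarray] | None = None,
    start_id: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one group's surface-area table and phenotypes.

    Hemisphere-level parcel signals are multivariate-normal draws from
    the inverse of ``precision``; left/right parcels are mirrored copies
    plus independent hemisphere noise, scaled to mean ``mean_area`` mm^2
    and clipped at a small positive floor.  Sites are assigned
    round-robin; site batch effects apply a location shift plus a scaling
    of the deviation from the nominal mean.  Returns ``(areas,
    phenotypes)`` on a shared subject-id index.
    """
    cfg.validate()
    h = cfg.n_hemi
    omega = np.asarray(precision, dtype=float)
    if omega.shape != (h, h):
        raise DataError("precision must be hemisphere-parcel sized")
    eigs = np.linalg.eigvalsh(omega)
    if eigs[0] <= 0:
        raise DataError("precision matrix is not positive definite")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects_per_group

    chol = np.linalg.cholesky(np.linalg.inv(omega))
    signal = rng.standard_normal((n, h)) @ chol.T
    noise_l = cfg.hemi_noise_sd * rng.standard_normal((n, h))
    noise_r = cfg.hemi_noise_sd * rng.standard_normal((n, h))
    x = np.hstack([signal + noise_l, signal + noise_r])
    areas = cfg.mean_area + cfg.area_scale * x

    sites = np.arange(n) % cfg.n_sites
    if site_effects is None:
        site_effects = _site_effects(cfg, rng)
    shifts, scales = site_effects
    areas = cfg.mean_area + (areas - cfg.mean_area) * scales[sites] \
        + shifts[sites]
    areas = np.maximum(areas, cfg.area_floor)

    ids = [f"{group}_{start_id + i:04d}" for i in range(n)]
    cols = [f"L_{i:03d}" for i in range(h)] + [f"R_{i:03d}" for i in range(h)]
    table = pd.DataFrame(areas, index=pd.Index(ids, name="subject_id"),
                         columns=cols)
    pheno = pd.DataFrame({
        "age": rng.uniform(*cfg.age_range, size=n),
        "sex": np.where(rng.random(n) < cfg.sex_ratio, "F", "M"),
        "group": group,
        "site": [f"site_{s}" for s in sites],
    }, index=table.index)
    return table, pheno


@dataclass
class SyntheticDataset:
    """A full two-group synthetic cohort plus its generating model."""

    areas: pd.DataFrame
    phenotypes: pd.DataFrame
    layout: SphereLayout           # full 2H-parcel layout
    hemi_layout: SphereLayout      # one-hemisphere layout (latent structure)
    precision_control: np.ndarray = field(repr=False)
    precision_affected: np.ndarray = field(repr=False)
    config: SynthConfig = field(default_factory=SynthConfig)

    @property
    def planted_labels(self) -> np.ndarray:
        return latent_cluster_labels(self.config)

    def group_table(self, group: str) -> pd.DataFrame:
        return self.areas.loc[self.phenotypes["group"] == group]

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "areas": outdir / "surface_areas.tsv",
            "phenotypes": outdir / "phenotypes.csv",
            "layout": outdir / "layout.csv",
        }
        self.areas.to_csv(paths["areas"], sep="\t")
        self.phenotypes.to_csv(paths["phenotypes"])
        self.layout.to_frame().to_csv(paths["layout"], index=False)
        return {k: str(v) for k, v in paths.items()}


def generate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Generate control and affected groups under one seeded model.

    The hemisphere layout is mirrored (x -> -x) to build the full-parcel
    layout; both groups share the same coupling support and signs (so
    ``group_scale = 1`` gives identical generating models) and the same
    site batch effects.  Fixing ``cfg.seed`` fixes every output.
    """
    cfg.validate()
    hemi = make_sphere_layout(cfg.n_hemi, cfg.radius)
    mirrored = hemi.points.copy()
    mirrored[:, 0] *= -1
    full = SphereLayout(points=np.vstack([hemi.points, mirrored]),
                        r=cfg.radius)

    omega_c = build_precision(cfg, hemi, group="control")
    omega_a = build_precision(cfg, hemi, group="affected")

    rng = np.random.default_rng(cfg.seed + 1)
    site_fx = _site_effects(cfg, rng)
    areas_c, pheno_c = sample_group(
        cfg, omega_c, group="control", rng=rng, site_effects=site_fx)
    areas_a, pheno_a = sample_group(
        cfg, omega_a, group="affected", rng=rng, site_effects=site_fx)
    return SyntheticDataset(
        areas=pd.concat([areas_c, areas_a]),
        phenotypes=pd.concat([pheno_c, pheno_a]),
        layout=full,
        hemi_layout=hemi,
        precision_control=omega_c,
        precision_affected=omega_a,
        config=cfg,
    )


def precision_to_pcorr(omega: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix (unit diagonal)."""
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho
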
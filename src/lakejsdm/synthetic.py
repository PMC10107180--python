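"""Seeded synthetic lake-metacommunity datasets with known ground truth.

Emulates the statistical structure the analysis assumes: a nested
site-in-watershed-in-basin sampling design with planar (km) coordinates,
physico-chemical / bathymetry / land-use covariates with spatial structure
and weak linear year trends, a 5-rank taxonomy with taxonomically clumped
traits, and 0/1 communities from a probit model whose species coefficients
are drawn around a trait-regression mean with phylogeny-structured
residuals (mixing parameter rho) plus hierarchical latent-factor random
effects (exponential-decay spatial covariance at the site level).

A planted-RCP mode adds cluster-specific site offsets so that samples fall
into a known number of compositional profiles, for end-to-end recovery
tests of the clustering stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    ALL_COVARIATES,
    BINARY_TRAITS,
    LN_TRANSFORM,
    PHYSICO_CHEMICAL,
    build_design_matrix,
    build_trait_matrix,
    taxonomy_to_correlation,
)

TRAIT_COVARIATES = ["intercept", "ln_volume"] + BINARY_TRAITS

# Baseline levels and noise scales of the physico-chemical covariates
# (site base SD, year-level SD, sample SD), units as in the covariate table.
_PHYS_CHEM = {
    "temperature": {"base": 16.0, "site_sd": 1.5, "year_sd": 0.5, "sample_sd": 1.0},
    "ptot": {"base": 22.0, "site_sd": 8.0, "year_sd": 1.5, "sample_sd": 3.0},
    "np_ratio": {"base": 28.0, "site_sd": 6.0, "year_sd": 1.5, "sample_sd": 3.0},
    "colour": {"base": 60.0, "site_sd": 20.0, "year_sd": 4.0, "sample_sd": 8.0},
}

#: global prevalence of each binary trait
_TRAIT_PREVALENCE = {
    "n_fixation": 0.15,
    "silica": 0.30,
    "motility": 0.40,
    "chain_forming": 0.30,
    "toxic": 0.12,
}

#: latent-factor loading SD per random level (per-species level variance
#: is n_factors * sd^2); chosen so the spatial/temporal random part is of
#: the same order as the fixed part, as in boreal-lake monitoring data
_LOADING_SD = {"site": 0.55, "watershed": 0.45, "basin": 0.35, "year": 0.55}


def default_true_gamma() -> pd.DataFrame:
    """Trait -> niche regression used by the generator (traits x covariates).

    Moderate, ecologically signed effects: e.g. nitrogen fixers favoured at
    high phosphorus and low N:P, silica-demanding (diatom-like) taxa
    favoured by cooler water, large cells disfavoured by warming.
    """
    cols = ["intercept"] + ALL_COVARIATES + ["year"]
    g = pd.DataFrame(0.0, index=TRAIT_COVARIATES, columns=cols)
    g.loc["intercept", "intercept"] = -0.8
    g.loc["intercept", "ptot"] = 0.25
    g.loc["intercept", "lake_area"] = 0.20
    g.loc["intercept", "year"] = 0.10
    g.loc["ln_volume", "temperature"] = -0.20
    g.loc["ln_volume", "lake_area"] = 0.15
    g.loc["n_fixation", "ptot"] = 0.35
    g.loc["n_fixation", "np_ratio"] = -0.30
    g.loc["silica", "temperature"] = -0.30
    g.loc["silica", "colour"] = 0.15
    g.loc["motility", "colour"] = -0.15
    g.loc["motility", "mean_depth"] = 0.15
    g.loc["chain_forming", "ptot"] = 0.20
    g.loc["toxic", "temperature"] = 0.20
    g.loc["toxic", "ptot"] = 0.20
    return g


@dataclass
class SyntheticConfig:
    """Study-design and ground-truth parameters of the generator.

    The defaults are the desk-scale preset: 4 basins x 3 watersheds x
    4 sites, 10 years at sampling probability 0.7, 40 species, two spatial
    factors at the site level and one factor at each other level.
    """

    n_basins: int = 4
    n_watersheds_per_basin: int = 3
    n_sites_per_watershed: int = 4
    years: tuple[int, int] = (2008, 2017)
    samples_per_site_year_prob: float = 0.7
    n_species: int = 40
    taxonomy_fanout: tuple[int, int, int, int, int] = (2, 2, 2, 2, 3)
    true_rho: float = 0.8
    true_gamma: pd.DataFrame | None = None
    residual_niche_scale: float = 0.4
    factors_per_level: dict = field(
        default_factory=lambda: {"site": 2, "watershed": 1, "basin": 1, "year": 1}
    )
    spatial_range: float = 150.0  # km
    trend_slopes: dict = field(
        default_factory=lambda: {
            "temperature": 0.03,
            "colour": 0.8,
            "ptot": 0.15,
            "np_ratio": -0.10,
        }
    )
    cov_noise: float = 1.0  # multiplier on all covariate noise SDs
    trait_clumping: float = 0.7
    planted_k: int | None = None
    planted_offset: float = 3.5  # probit units; +-3.5 makes profiles near-deterministic
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_basins", "n_watersheds_per_basin", "n_sites_per_watershed", "n_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.samples_per_site_year_prob <= 1:
            raise ValueError("samples_per_site_year_prob must be in (0, 1]")
        if not 0 <= self.true_rho <= 1:
            raise ValueError("true_rho must be in [0, 1]")
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be positive")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")
        if min(self.taxonomy_fanout) < 1:
            raise ValueError("taxonomy fanout counts must be >= 1")


@dataclass
class GroundTruth:
    """Parameters the community was generated from, for recovery tests."""

    beta: pd.DataFrame  # design columns x species
    gamma: pd.DataFrame  # trait covariates x design columns
    rho: float
    level_variances: dict  # level -> expected per-species variance
    factor_loadings: dict  # level -> (n_factors x species) DataFrame
    spatial_ranges: dict  # level -> list of ranges (km), spatial levels only
    trait_variance_fraction: pd.Series | None = None
    cluster_labels: pd.Series | None = None  # planted-RCP mode

    def to_json(self) -> str:
        payload = {
            "beta": self.beta.to_dict(),
            "gamma": self.gamma.to_dict(),
            "rho": self.rho,
            "level_variances": self.level_variances,
            "factor_loadings": {k: v.to_dict() for k, v in self.factor_loadings.items()},
            "spatial_ranges": self.spatial_ranges,
            "trait_variance_fraction": (
                None if self.trait_variance_fraction is None
                else self.trait_variance_fraction.to_dict()
            ),
            "cluster_labels": (
                None if self.cluster_labels is None else self.cluster_labels.to_dict()
            ),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            beta=pd.DataFrame(d["beta"]),
            gamma=pd.DataFrame(d["gamma"]),
            rho=d["rho"],
            level_variances=d["level_variances"],
            factor_loadings={k: pd.DataFrame(v) for k, v in d["factor_loadings"].items()},
            spatial_ranges=d["spatial_ranges"],
            trait_variance_fraction=(
                None if d.get("trait_variance_fraction") is None
                else pd.Series(d["trait_variance_fraction"])
            ),
            cluster_labels=(
                None if d.get("cluster_labels") is None else pd.Series(d["cluster_labels"])
            ),
        )


def _rng(config: SyntheticConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def generate_design(config: SyntheticConfig) -> pd.DataFrame:
    """Nested site/watershed/basin design with planar km coordinates.

    One sample row per (site, year) drawn with the configured probability;
    each basin is guaranteed at least one sampled site. Basin centres sit on
    a coarse national grid, watershed centres scatter around their basin and
    sites around their watershed, so within-watershed distances are small
    relative to between-basin distances.
    """
    rng = _rng(config, 1)
    sites = []
    grid = int(np.ceil(np.sqrt(config.n_basins)))
    for b in range(config.n_basins):
        bx, by = (b % grid) * 400.0 + 200.0, (b // grid) * 400.0 + 200.0
        for w in range(config.n_watersheds_per_basin):
            wx, wy = rng.normal([bx, by], 60.0)
            for s in range(config.n_sites_per_watershed):
                sx, sy = rng.normal([wx, wy], 12.0)
                sites.append(
                    {
                        "site": f"b{b + 1}w{w + 1}s{s + 1}",
                        "watershed": f"b{b + 1}w{w + 1}",
                        "basin": f"b{b + 1}",
                        "x_km": round(float(sx), 3),
                        "y_km": round(float(sy), 3),
                    }
                )
    site_df = pd.DataFrame(sites).set_index("site")
    years = np.arange(config.years[0], config.years[1] + 1)
    sampled = rng.random((len(site_df), len(years))) < config.samples_per_site_year_prob
    # keep every basin represented
    basins = site_df["basin"].to_numpy()
    for b in pd.unique(basins):
        rows = np.flatnonzero(basins == b)
        if not sampled[rows].any():
            sampled[rows[0], 0] = True
    rows = []
    for i, site in enumerate(site_df.index):
        for j, year in enumerate(years):
            if sampled[i, j]:
                rows.append(
                    {
                        "sample_id": f"{site}_y{year}",
                        "site": site,
                        "watershed": site_df.loc[site, "watershed"],
                        "basin": site_df.loc[site, "basin"],
                        "year": int(year),
                        "x_km": site_df.loc[site, "x_km"],
                        "y_km": site_df.loc[site, "y_km"],
                    }
                )
    if not rows:
        raise RuntimeError(
            f"no samples drawn (prob={config.samples_per_site_year_prob}, "
            f"{len(site_df)} sites x {len(years)} years)"
        )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_covariates(design: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Per-sample covariate table mirroring the monitoring covariate set.

    Bathymetry and land use are site-constant; physico-chemical variables
    combine basin/watershed/site intercepts (spatial structure), a shared
    year-level disturbance, the configured linear year drift, and sample
    noise. Values destined for the ln transform stay strictly positive.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    rng = _rng(config, 2)
    noise = config.cov_noise
    sites = design[["site", "watershed", "basin"]].drop_duplicates().set_index("site")
    basins = sorted(design["basin"].unique())
    sheds = sorted(design["watershed"].unique())
    years = np.arange(config.years[0], config.years[1] + 1)
    y0 = config.years[0]

    static = pd.DataFrame(index=sites.index)
    static["lake_area"] = np.exp(rng.normal(1.0, 1.0, len(sites)))  # km^2
    static["mean_depth"] = np.exp(rng.normal(1.6, 0.5, len(sites)))  # m
    static["retention"] = np.exp(rng.normal(4.6, 0.8, len(sites)))  # days
    # land-use percentages via logistic-normal with basin/watershed structure
    lu_mu = {"urban": -3.5, "agriculture": -2.0, "mineral_forest": 0.2, "peat_forest": -1.0}
    for name, mu in lu_mu.items():
        b_eff = dict(zip(basins, rng.normal(0.0, 0.6, len(basins))))
        w_eff = dict(zip(sheds, rng.normal(0.0, 0.4, len(sheds))))
        logit = (
            mu
            + sites["basin"].map(b_eff).to_numpy()
            + sites["watershed"].map(w_eff).to_numpy()
            + rng.normal(0.0, 0.5, len(sites))
        )
        static[name] = 100.0 / (1.0 + np.exp(-logit))

    out = pd.DataFrame(index=design.index)
    out["year"] = design["year"].to_numpy()
    for name in static.columns:
        out[name] = design["site"].map(static[name]).to_numpy()
    for name, pars in _PHYS_CHEM.items():
        b_eff = dict(zip(basins, rng.normal(0.0, pars["site_sd"], len(basins))))
        w_eff = dict(zip(sheds, rng.normal(0.0, pars["site_sd"] * 0.7, len(sheds))))
        s_eff = dict(zip(sites.index, rng.normal(0.0, pars["site_sd"] * 0.7, len(sites))))
        y_eff = dict(zip(years, rng.normal(0.0, pars["year_sd"], len(years))))
        slope = config.trend_slopes.get(name, 0.0)
        val = (
            pars["base"]
            + noise * design["basin"].map(b_eff).to_numpy()
            + noise * design["watershed"].map(w_eff).to_numpy()
            + noise * design["site"].map(s_eff).to_numpy()
            + noise * design["year"].map(y_eff).to_numpy()
            + slope * (design["year"].to_numpy() - y0)
            + noise * rng.normal(0.0, pars["sample_sd"], len(design))
        )
        if name in LN_TRANSFORM:
            val = np.maximum(val, 0.05 * pars["base"])  # keep ln targets positive
        out[name] = val
    if not np.isfinite(out.to_numpy(float)).all():
        raise RuntimeError("non-finite covariate draw")
    return out[ALL_COVARIATES + ["year"]]


def generate_taxonomy_and_traits(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """5-rank nested taxonomy and the six traits, taxonomically clumped.

    Binary traits follow a genus-level latent propensity: with probability
    ``trait_clumping`` the whole genus shares one Bernoulli draw, otherwise
    species draw independently. ln cell volume is log-normal around a
    family-level mean. At least one species is flagged toxic.
    """
    fan = config.taxonomy_fanout
    n_tips = int(np.prod(fan))
    if n_tips < config.n_species:
        raise ValueError(
            f"taxonomy fanout yields {n_tips} tips but {config.n_species} species requested"
        )
    rng = _rng(config, 3)
    rows = []
    i = 0
    for c in range(fan[0]):
        for o in range(fan[1]):
            for f in range(fan[2]):
                for g in range(fan[3]):
                    for s in range(fan[4]):
                        i += 1
                        rows.append(
                            {
                                "species": f"sp{i:03d}",
                                "class": f"cl{c + 1}",
                                "order": f"cl{c + 1}or{o + 1}",
                                "family": f"cl{c + 1}or{o + 1}fa{f + 1}",
                                "genus": f"cl{c + 1}or{o + 1}fa{f + 1}ge{g + 1}",
                            }
                        )
    taxonomy = pd.DataFrame(rows[: config.n_species]).set_index("species")

    traits = pd.DataFrame(index=taxonomy.index)
    fam_means = {f: rng.normal(6.0, 1.5) for f in taxonomy["family"].unique()}
    traits["ln_volume"] = [
        rng.normal(fam_means[f], 0.5) for f in taxonomy["family"]
    ]
    genera = taxonomy["genus"].unique()
    for trait, p0 in _TRAIT_PREVALENCE.items():
        vals = np.empty(len(taxonomy))
        for g in genera:
            members = taxonomy.index[taxonomy["genus"] == g]
            coherent = rng.random() < config.trait_clumping
            if coherent:
                vals[taxonomy.index.get_indexer(members)] = float(rng.random() < p0)
            else:
                vals[taxonomy.index.get_indexer(members)] = (
                    rng.random(len(members)) < p0
                ).astype(float)
        traits[trait] = vals
    if traits["toxic"].sum() == 0:
        traits.iloc[0, traits.columns.get_loc("toxic")] = 1.0
    return taxonomy, traits


def generate_true_parameters(
    traits: pd.DataFrame, phylo: pd.DataFrame, config: SyntheticConfig
) -> GroundTruth:
    """Draw species niches beta around the trait-regression mean.

    vec(beta - mean) is matrix normal with covariate-side covariance
    V = residual_niche_scale^2 I and species-side correlation
    rho*C + (1-rho)*I from the taxonomy tree.
    """
    species = list(traits.index)
    if list(phylo.index) != species or list(phylo.columns) != species:
        raise ValueError("phylogeny correlation not aligned to the trait table")
    gamma = config.true_gamma if config.true_gamma is not None else default_true_gamma()
    gamma = gamma.copy()
    T, trait_names = build_trait_matrix(traits)
    if list(gamma.index) != trait_names:
        raise ValueError(f"true_gamma rows must be {trait_names}")
    rng = _rng(config, 4)
    C = phylo.to_numpy(float)
    S = len(species)
    P = config.true_rho * C + (1 - config.true_rho) * np.eye(S)
    try:
        B_chol = np.linalg.cholesky(P + 1e-10 * np.eye(S))
    except np.linalg.LinAlgError as err:
        raise ValueError("composite species correlation rho*C + (1-rho)*I is not PD") from err
    # design-side column names: squared physico-chemical terms share their
    # linear column's gamma? no -- gamma is defined per design column; expand
    cols = list(gamma.columns)
    design_cols = ["intercept"] + ALL_COVARIATES + ["year"] + [f"{c}_sq" for c in PHYSICO_CHEMICAL]
    full_gamma = pd.DataFrame(0.0, index=trait_names, columns=design_cols)
    for c in cols:
        if c in full_gamma.columns:
            full_gamma[c] = gamma[c]
    M = (T @ full_gamma.to_numpy(float)).T  # p x S
    p = M.shape[0]
    scale = config.residual_niche_scale
    E = scale * rng.standard_normal((p, S)) @ B_chol.T
    beta = M + E
    beta_df = pd.DataFrame(beta, index=design_cols, columns=species)

    loadings = {}
    level_var = {}
    spatial_ranges = {}
    for level, h in config.factors_per_level.items():
        sd = _LOADING_SD.get(level, 0.5)
        lam = sd * rng.standard_normal((h, S))
        loadings[level] = pd.DataFrame(
            lam, index=[f"f{i + 1}" for i in range(h)], columns=species
        )
        level_var[level] = float(h * sd**2)
        if level == "site":
            spatial_ranges[level] = [float(config.spatial_range)] * h

    var_mu = M.var(axis=1, ddof=0)
    var_beta = beta.var(axis=1, ddof=0)
    frac = np.where(var_beta > 0, np.clip(var_mu / var_beta, 0, 1), 0.0)
    return GroundTruth(
        beta=beta_df,
        gamma=full_gamma,
        rho=float(config.true_rho),
        level_variances=level_var,
        factor_loadings=loadings,
        spatial_ranges=spatial_ranges,
        trait_variance_fraction=pd.Series(frac, index=design_cols),
    )


def _exp_kernel(coords: np.ndarray, alpha: float) -> np.ndarray:
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    if alpha <= 0:
        return np.eye(len(coords))
    return np.exp(-d / alpha)


def generate_community(
    design: pd.DataFrame,
    covariates: pd.DataFrame,
    truth: GroundTruth,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Presence/absence matrix from the probit model.

    y_ij = 1{x_i' beta_j + sum_level eta' lambda + planted offset + eps > 0},
    with the fixed part built by the same design-matrix rules the analysis
    uses, site-level factors drawn from an exponential-kernel Gaussian
    process over site coordinates and exchangeable factors elsewhere.
    """
    if list(design.index) != list(covariates.index):
        raise ValueError("design and covariate tables are not aligned on samples")
    rng = _rng(config, 5)
    dm = build_design_matrix(covariates)
    if list(dm.columns) != list(truth.beta.index):
        raise ValueError(
            f"design columns {dm.columns} do not match truth beta rows {list(truth.beta.index)}"
        )
    beta = truth.beta.to_numpy(float)
    S = beta.shape[1]
    lp = dm.X @ beta

    unit_cols = {"site": "site", "watershed": "watershed", "basin": "basin", "year": "year"}
    for level, lam_df in truth.factor_loadings.items():
        lam = lam_df.to_numpy(float)
        h = lam.shape[0]
        units = design[unit_cols[level]]
        uniq = list(pd.unique(units))
        codes = pd.Categorical(units, categories=uniq).codes
        if level == "site":
            coords = (
                design[["site", "x_km", "y_km"]]
                .drop_duplicates()
                .set_index("site")
                .loc[uniq]
                .to_numpy(float)
            )
            eta = np.empty((len(uniq), h))
            for k in range(h):
                K = _exp_kernel(coords, truth.spatial_ranges["site"][k])
                eta[:, k] = np.linalg.cholesky(
                    K + 1e-8 * np.eye(len(uniq))
                ) @ rng.standard_normal(len(uniq))
        else:
            eta = rng.standard_normal((len(uniq), h))
        lp += eta[codes] @ lam

    if truth.cluster_labels is not None:
        offsets = truth.cluster_labels.attrs["offsets"]
        lp += offsets[truth.cluster_labels.loc[design.index].to_numpy(int)]

    y = (lp + rng.standard_normal(lp.shape) > 0).astype(int)
    return pd.DataFrame(y, index=design.index, columns=truth.beta.columns)


def plant_clusters(
    design: pd.DataFrame, config: SyntheticConfig, n_species: int
) -> pd.Series:
    """Assign each site to one of ``planted_k`` profiles; returns per-sample
    labels carrying the cluster x species probit offsets in ``attrs``."""
    k = config.planted_k
    if not k or k < 2:
        raise ValueError("planted_k must be >= 2 for planted-RCP mode")
    rng = _rng(config, 6)
    sites = list(pd.unique(design["site"]))
    labels = np.array([i % k for i in range(len(sites))])
    rng.shuffle(labels)
    site_label = dict(zip(sites, labels))
    offsets = config.planted_offset * rng.choice([-1.0, 1.0], size=(k, n_species))
    out = design["site"].map(site_label).astype(int)
    out.attrs["offsets"] = offsets
    return out


def generate_dataset(config: SyntheticConfig) -> dict:
    """Full seeded bundle: design, covariates, taxonomy, traits, community,
    and the ground truth."""
    design = generate_design(config)
    covariates = generate_covariates(design, config)
    taxonomy, traits = generate_taxonomy_and_traits(config)
    phylo = taxonomy_to_correlation(taxonomy)
    truth = generate_true_parameters(traits, phylo, config)
    if config.planted_k:
        truth.cluster_labels = plant_clusters(design, config, config.n_species)
    community = generate_community(design, covariates, truth, config)
    return {
        "design": design,
        "covariates": covariates,
        "taxonomy": taxonomy,
        "traits": traits,
        "phylo": phylo,
        "community": community,
        "truth": truth,
        "config": config,
    }


def desk_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The desk-scale preset (a full pipeline run fits in minutes)."""
    return SyntheticConfig(seed=seed, **overrides)


def planted_config(seed: int = 0, k: int = 4, **overrides) -> SyntheticConfig:
    """Desk preset in planted-RCP mode with k compositional profiles."""
    return SyntheticConfig(seed=seed, planted_k=k, **overrides)
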
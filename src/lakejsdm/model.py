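"""Hierarchical Bayesian joint species distribution model (JSDM).

A latent-factor multivariate probit (or Gaussian) regression in which the
species' environmental responses beta are drawn around a trait-regression
mean (gamma) with residual covariance [rho*C + (1-rho)*I] (x) V -- C the
phylogenetic correlation, rho the phylogenetic-signal mixing parameter, V
the residual niche covariance -- and residual co-occurrence is captured by
low-rank latent factors at nested spatial (site, watershed, river basin)
and temporal (year) random levels. Site-level factors carry an
exponential-decay Gaussian-process covariance exp(-d/alpha) over planar
coordinates.

Everything is estimated by a blocked Gibbs sampler with fully conjugate
updates; rho and the spatial ranges alpha are sampled from exact discrete
posteriors over fixed grids. The beta block exploits the eigendecomposition
of C so that the species decouple after an orthogonal rotation (one
eigendecomposition reused across sweeps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from .preprocess import DesignMatrix

logger = logging.getLogger("lakejsdm")

MAX_SPATIAL_UNITS = 2000  # exact-GP guard rail; subsample beyond this


# ---------------------------------------------------------------------------
# specifications


@dataclass
class Priors:
    """Default prior hyperparameters (all config-overridable).

    Gamma entries ~ N(0, gamma_sd^2) (covariates are standardized);
    V ~ InvWishart(p + v_df_add, I); multiplicative-gamma shrinkage on the
    factor loadings (a1, b1 on the first column-scale increment, a2, b2 on
    later ones, local t-like scales with nu df); rho on a grid with
    probability mass rho_zero_mass on rho = 0 and the rest uniform;
    spatial range alpha uniform on a 20-point grid from 0 (non-spatial)
    to half the maximal inter-site distance; sigma^2 ~ InvGamma(1, 1).
    """

    gamma_sd: float = 1.0
    v_df_add: int = 1
    shrink_a1: float = 2.0
    shrink_b1: float = 1.0
    shrink_a2: float = 3.0
    shrink_b2: float = 1.0
    shrink_nu: float = 3.0
    rho_zero_mass: float = 0.5
    n_alpha_grid: int = 20
    sigma2_a: float = 1.0
    sigma2_b: float = 1.0


@dataclass
class RandomLevelSpec:
    """One random level: unit membership per sample, optionally spatial."""

    name: str
    units: np.ndarray  # per-sample unit labels
    spatial: bool = False
    coords: pd.DataFrame | None = None  # unit -> (x_km, y_km); spatial only
    max_factors: int = 1

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units)
        if self.spatial and self.coords is None:
            raise ValueError(f"spatial level {self.name!r} needs coordinates")
        if self.max_factors < 1:
            raise ValueError("max_factors must be >= 1")


@dataclass
class ModelSpec:
    """Family, phylogeny switch, grids, priors and diagnostic fix switches."""

    family: str = "probit"
    phylogeny: bool = True
    rho_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 101))
    priors: Priors = field(default_factory=Priors)
    # diagnostic switches: hold a block fixed to run the sampler in an
    # exactly conjugate regime (validation against closed forms)
    fix_v: np.ndarray | None = None
    fix_gamma: np.ndarray | None = None
    fix_sigma2: float | None = None
    init: str = "ridge"  # or "zeros"

    def __post_init__(self) -> None:
        if self.family not in ("probit", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        self.rho_grid = np.asarray(self.rho_grid, float)
        if self.rho_grid.min() < 0 or self.rho_grid.max() > 1:
            raise ValueError("rho grid must lie in [0, 1]")
        if not np.any(self.rho_grid == 0.0):
            raise ValueError("rho grid must contain 0")


@dataclass
class ModelData:
    """Aligned response matrix, design matrix, random levels, traits, tree."""

    Y: np.ndarray  # n x S (binary for probit)
    design: DesignMatrix
    levels: list[RandomLevelSpec]
    T: np.ndarray  # S x q trait covariates (at least an intercept column)
    C: np.ndarray | None  # S x S phylogenetic correlation, or None
    species: list[str]
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, float)
        n, S = self.Y.shape
        if self.design.X.shape[0] != n:
            raise ValueError(
                f"response has {n} samples but design matrix has {self.design.X.shape[0]}"
            )
        if self.T.shape[0] != S:
            raise ValueError(f"trait matrix rows ({self.T.shape[0]}) != species ({S})")
        if self.C is not None and self.C.shape != (S, S):
            raise ValueError(f"phylogeny correlation shape {self.C.shape} != ({S}, {S})")
        for lev in self.levels:
            if len(lev.units) != n:
                raise ValueError(f"level {lev.name!r} unit labels do not cover all samples")


def make_model_data(
    community: pd.DataFrame,
    design_matrix: DesignMatrix,
    hier_design: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    phylo: pd.DataFrame | None = None,
    level_names: tuple = ("site", "watershed", "basin", "year"),
    spatial_levels: tuple = ("site",),
    max_factors: dict | None = None,
) -> ModelData:
    """Assemble aligned model inputs from the bundle tables."""
    from .preprocess import build_trait_matrix

    if list(community.index) != list(hier_design.index):
        raise ValueError("community and design tables are not aligned on samples")
    species = list(community.columns)
    max_factors = max_factors or {"site": 2, "watershed": 1, "basin": 1, "year": 1}
    levels = []
    for name in level_names:
        spatial = name in spatial_levels
        coords = None
        if spatial:
            coords = (
                hier_design[[name, "x_km", "y_km"]]
                .drop_duplicates(name)
                .set_index(name)
            )
        levels.append(
            RandomLevelSpec(
                name=name,
                units=hier_design[name].to_numpy(),
                spatial=spatial,
                coords=coords,
                max_factors=max_factors.get(name, 1),
            )
        )
    if traits is not None:
        if list(traits.index) != species:
            raise ValueError("trait table not aligned to community species")
        T, trait_names = build_trait_matrix(traits)
    else:
        T, trait_names = np.ones((len(species), 1)), ["intercept"]
    C = None
    if phylo is not None:
        if list(phylo.index) != species:
            raise ValueError("phylogeny correlation not aligned to community species")
        C = phylo.to_numpy(float)
    return ModelData(
        Y=community.to_numpy(float),
        design=design_matrix,
        levels=levels,
        T=T,
        C=C,
        species=species,
        trait_names=trait_names,
    )


# ---------------------------------------------------------------------------
# schedule arithmetic


def count_retained_samples(
    n_iterations: int, burn_in: int, thin: int, n_chains: int
) -> tuple[int, int]:
    """Retained posterior samples per chain and in total."""
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if burn_in < 0 or n_iterations <= 0:
        raise ValueError("invalid schedule")
    if burn_in >= n_iterations:
        raise ValueError(
            f"burn-in ({burn_in}) must be smaller than the iteration count ({n_iterations})"
        )
    per_chain = (n_iterations - burn_in) // thin
    if per_chain == 0:
        raise ValueError("schedule retains no samples")
    return per_chain, per_chain * n_chains


# ---------------------------------------------------------------------------
# sampler internals


def _sample_mvn_prec(prec: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^-1 b, prec^-1)."""
    L = np.linalg.cholesky(prec)
    mean = sla.cho_solve((L, True), b)
    noise = sla.solve_triangular(L.T, rng.standard_normal(len(b)), lower=False)
    return mean + noise


def _sample_mvn_prec_batch(prec: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Vectorized draw from N(prec^-1 b, prec^-1) over a stack (m, d, d)."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, b[..., None])[..., 0]
    xi = rng.standard_normal(b.shape)
    noise = np.linalg.solve(np.swapaxes(L, -1, -2), xi[..., None])[..., 0]
    return mean + noise


class GibbsSampler:
    """One MCMC chain of the JSDM; ``step`` performs a full Gibbs sweep."""

    def __init__(self, spec: ModelSpec, data: ModelData, seed: int):
        self.spec = spec
        self.data = data
        self.rng = np.random.default_rng(seed)
        self.n, self.S = data.Y.shape
        self.p = data.design.n_columns
        self.q = data.T.shape[1]
        self.X = data.design.X
        self.XtX = self.X.T @ self.X
        self.phylo = spec.phylogeny and data.C is not None
        if self.phylo and spec.family == "gaussian":
            raise ValueError(
                "gaussian family with phylogeny is not supported (species-specific "
                "residual variances break the Kronecker decoupling); drop the tree"
            )
        if self.phylo:
            w, Q = np.linalg.eigh(data.C)
            self.C_eval = np.clip(w, 1e-8, None)
            self.C_evec = Q
        # gaussian responses standardized internally
        if spec.family == "gaussian":
            self.y_mean = data.Y.mean(axis=0)
            self.y_sd = data.Y.std(axis=0, ddof=0)
            if np.any(self.y_sd == 0):
                j = int(np.argmin(self.y_sd))
                raise ValueError(f"zero-variance gaussian response {data.species[j]!r}")
            self.Yz = (data.Y - self.y_mean) / self.y_sd
        self._prepare_levels()
        self.state = self._initial_state()

    # -- setup ------------------------------------------------------------

    def _prepare_levels(self) -> None:
        self.levels = []
        for lev in self.data.levels:
            uniq = list(pd.unique(lev.units))
            codes = pd.Categorical(lev.units, categories=uniq).codes.astype(int)
            nu = len(uniq)
            info = {
                "name": lev.name,
                "spec": lev,
                "uniq": uniq,
                "codes": codes,
                "n_units": nu,
                "counts": np.bincount(codes, minlength=nu).astype(float),
                "H": lev.max_factors,
                "spatial": lev.spatial,
            }
            if lev.spatial:
                if nu > MAX_SPATIAL_UNITS:
                    raise ValueError(
                        f"spatial level {lev.name!r} has {nu} units (> {MAX_SPATIAL_UNITS}); "
                        "the exact-GP sampler would be too expensive -- subsample sites"
                    )
                coords = lev.coords.loc[uniq, ["x_km", "y_km"]].to_numpy(float)
                d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
                dmax = d.max()
                grid = np.linspace(0.0, dmax / 2.0, self.spec.priors.n_alpha_grid)
                K_inv, logdet = [], []
                for a in grid:
                    K = np.eye(nu) if a <= 0 else np.exp(-d / a) + 1e-8 * np.eye(nu)
                    L = np.linalg.cholesky(K)
                    K_inv.append(sla.cho_solve((L, True), np.eye(nu)))
                    logdet.append(2.0 * np.log(np.diag(L)).sum())
                info["alpha_grid"] = grid
                info["K_inv"] = K_inv
                info["K_logdet"] = np.array(logdet)
            self.levels.append(info)

    def _initial_state(self) -> dict:
        rng = np.random.default_rng(self.rng.integers(2**31))
        if self.spec.family == "probit":
            z = np.where(self.data.Y > 0, 0.7, -0.7)
        else:
            z = self.Yz.copy()
        if self.spec.init == "zeros":
            B = np.zeros((self.p, self.S))
        else:  # ridge-stabilized latent least squares
            B = np.linalg.solve(self.XtX + np.eye(self.p), self.X.T @ z)
        st = {
            "z": z,
            "B": B,
            "Gamma": (
                self.spec.fix_gamma.copy()
                if self.spec.fix_gamma is not None
                else np.zeros((self.q, self.p))
            ),
            "V": self.spec.fix_v.copy() if self.spec.fix_v is not None else np.eye(self.p),
            "rho": float(self.spec.rho_grid[len(self.spec.rho_grid) // 2]),
            "sigma2": (
                np.full(self.S, self.spec.fix_sigma2)
                if self.spec.fix_sigma2 is not None
                else np.ones(self.S)
            ),
            "levels": {},
        }
        for info in self.levels:
            H, nu = info["H"], info["n_units"]
            st["levels"][info["name"]] = {
                "eta": np.zeros((nu, H)),
                "lambda": 0.1 * rng.standard_normal((H, self.S)),
                "phi": np.ones((H, self.S)),
                "delta": np.ones(H),
                "alpha_idx": (
                    np.full(H, len(info["alpha_grid"]) // 2, dtype=int)
                    if info["spatial"]
                    else np.zeros(H, dtype=int)
                ),
            }
        self._refresh_cache(st)
        return st

    def _refresh_cache(self, st: dict) -> None:
        st["fixed"] = self.X @ st["B"]
        for info in self.levels:
            ls = st["levels"][info["name"]]
            ls["contrib"] = ls["eta"][info["codes"]] @ ls["lambda"]
        st["rand_total"] = sum(
            st["levels"][info["name"]]["contrib"] for info in self.levels
        ) if self.levels else np.zeros_like(st["fixed"])

    # -- conditional updates ----------------------------------------------

    def _update_z(self, st: dict) -> None:
        m = st["fixed"] + st["rand_total"]
        p0 = ndtr(-m)
        u = self.rng.random(m.shape)
        v = np.where(self.data.Y > 0, p0 + u * (1.0 - p0), u * p0)
        st["z"] = m + ndtri(np.clip(v, 1e-13, 1.0 - 1e-13))

    def _update_B(self, st: dict) -> None:
        R = st["z"] - st["rand_total"]
        M = (self.data.T @ st["Gamma"]).T  # p x S prior mean
        V_inv = np.linalg.inv(st["V"])
        if self.phylo:
            Q = self.C_evec
            d = st["rho"] * self.C_eval + (1.0 - st["rho"])
            Rt, Mt = R @ Q, M @ Q
            prec = V_inv[None] / d[:, None, None] + self.XtX[None]
            b = (Mt / d).T[:, :, None]
            b = np.matmul(np.broadcast_to(V_inv, (self.S, self.p, self.p)), b)[..., 0]
            b += (self.X.T @ Rt).T
            Bt = _sample_mvn_prec_batch(prec, b, self.rng)  # (S, p) rows = rotated species
            st["B"] = Bt.T @ Q.T  # rotate back: B = B~ Q'
        else:
            s2 = st["sigma2"]
            prec = V_inv[None] + self.XtX[None] / s2[:, None, None]
            b = (V_inv @ M).T + (self.X.T @ R).T / s2[:, None]
            Bs = _sample_mvn_prec_batch(prec, b, self.rng)
            st["B"] = Bs.T
        st["fixed"] = self.X @ st["B"]

    def _P_inv(self, st: dict) -> np.ndarray:
        if not self.phylo:
            return np.eye(self.S)
        d = st["rho"] * self.C_eval + (1.0 - st["rho"])
        return (self.C_evec / d) @ self.C_evec.T

    def _update_Gamma(self, st: dict) -> None:
        if self.spec.fix_gamma is not None:
            return
        V_inv = np.linalg.inv(st["V"])
        P_inv = self._P_inv(st)
        TtPT = self.data.T.T @ P_inv @ self.data.T
        prec = np.kron(TtPT, V_inv)
        prec[np.diag_indices_from(prec)] += 1.0 / self.spec.priors.gamma_sd**2
        b = (V_inv @ st["B"] @ P_inv @ self.data.T).reshape(-1, order="F")
        vecG = _sample_mvn_prec(prec, b, self.rng)
        st["Gamma"] = vecG.reshape(self.p, self.q, order="F").T

    def _update_V(self, st: dict) -> None:
        if self.spec.fix_v is not None:
            return
        M = (self.data.T @ st["Gamma"]).T
        E = st["B"] - M
        if self.phylo:
            d = st["rho"] * self.C_eval + (1.0 - st["rho"])
            Et = E @ self.C_evec
            S_mat = (Et / d) @ Et.T
        else:
            S_mat = E @ E.T
        df = self.p + self.spec.priors.v_df_add + self.S
        scale = np.eye(self.p) + S_mat
        scale = 0.5 * (scale + scale.T)
        st["V"] = invwishart.rvs(df=df, scale=scale, random_state=self.rng)
        if self.p == 1:
            st["V"] = np.atleast_2d(st["V"])

    def _update_rho(self, st: dict) -> None:
        if not self.phylo:
            return
        grid = self.spec.rho_grid
        M = (self.data.T @ st["Gamma"]).T
        Et = (st["B"] - M) @ self.C_evec
        V_inv = np.linalg.inv(st["V"])
        a = np.einsum("ps,ps->s", Et, V_inv @ Et)
        d = grid[:, None] * self.C_eval[None, :] + (1.0 - grid[:, None])
        ll = -0.5 * (self.p * np.log(d).sum(axis=1) + (a[None, :] / d).sum(axis=1))
        prior = np.full(len(grid), (1.0 - self.spec.priors.rho_zero_mass) / max(len(grid) - 1, 1))
        prior[np.argmin(np.abs(grid))] = self.spec.priors.rho_zero_mass
        logp = ll + np.log(prior)
        logp -= logp.max()
        w = np.exp(logp)
        st["rho"] = float(self.rng.choice(grid, p=w / w.sum()))

    def _update_level(self, st: dict, info: dict) -> None:
        name = info["name"]
        ls = st["levels"][name]
        codes, counts, nu, H = info["codes"], info["counts"], info["n_units"], info["H"]
        lam = ls["lambda"]
        R = st["z"] - st["fixed"] - (st["rand_total"] - ls["contrib"])
        s2 = st["sigma2"]
        Rw = R / s2[None, :]  # precision-weighted residual (probit: sigma2 = 1)
        S_mat = np.zeros((nu, self.S))
        np.add.at(S_mat, codes, Rw)
        lam_w = lam / s2[None, :]
        Lam2 = lam_w @ lam.T  # H x H likelihood cross-products
        # eta
        if info["spatial"]:
            prec = np.kron(Lam2, np.diag(counts))
            for h in range(H):
                Kinv = info["K_inv"][ls["alpha_idx"][h]]
                prec[h * nu:(h + 1) * nu, h * nu:(h + 1) * nu] += Kinv
            b = (lam @ S_mat.T).reshape(-1)  # factor-major
            eta_vec = _sample_mvn_prec(prec, b, self.rng)
            ls["eta"] = eta_vec.reshape(H, nu).T
        else:
            prec = np.eye(H)[None] + counts[:, None, None] * Lam2[None]
            b = S_mat @ lam.T
            ls["eta"] = _sample_mvn_prec_batch(prec, b, self.rng)
        # loadings
        F = ls["eta"][codes]
        FtF = F.T @ F
        tau = np.cumprod(ls["delta"])
        prior_prec = ls["phi"] * tau[:, None]
        prec = prior_prec.T[:, :, None] * np.eye(H)[None] + FtF[None] / s2[:, None, None]
        b = (F.T @ R).T / s2[:, None]
        ls["lambda"] = _sample_mvn_prec_batch(prec, b, self.rng).T
        lam = ls["lambda"]
        # local shrinkage
        nu_df = self.spec.priors.shrink_nu
        rate = 0.5 * (nu_df + tau[:, None] * lam**2)
        ls["phi"] = self.rng.gamma((nu_df + 1.0) / 2.0, 1.0 / rate)
        # global multiplicative-gamma increments
        pr = self.spec.priors
        phil2 = (ls["phi"] * lam**2).sum(axis=1)  # per factor
        delta = ls["delta"]
        for h in range(H):
            a_d = (pr.shrink_a1 if h == 0 else pr.shrink_a2) + 0.5 * self.S * (H - h)
            tau_wo = np.cumprod(np.where(np.arange(H) == h, 1.0, delta))
            b_d = (pr.shrink_b1 if h == 0 else pr.shrink_b2) + 0.5 * (
                tau_wo[h:] * phil2[h:]
            ).sum()
            delta[h] = self.rng.gamma(a_d, 1.0 / b_d)
        ls["delta"] = delta
        # spatial range
        if info["spatial"]:
            grid = info["alpha_grid"]
            for h in range(H):
                e = ls["eta"][:, h]
                quad = np.array([e @ Ki @ e for Ki in info["K_inv"]])
                logp = -0.5 * (info["K_logdet"] + quad)
                logp -= logp.max()
                w = np.exp(logp)
                ls["alpha_idx"][h] = int(self.rng.choice(len(grid), p=w / w.sum()))
        ls["contrib"] = ls["eta"][codes] @ lam
        st["rand_total"] = sum(st["levels"][i["name"]]["contrib"] for i in self.levels)

    def _update_sigma2(self, st: dict) -> None:
        if self.spec.family != "gaussian" or self.spec.fix_sigma2 is not None:
            return
        resid = st["z"] - st["fixed"] - st["rand_total"]
        ss = (resid**2).sum(axis=0)
        a = self.spec.priors.sigma2_a + 0.5 * self.n
        b = self.spec.priors.sigma2_b + 0.5 * ss
        st["sigma2"] = b / self.rng.gamma(a, 1.0, size=self.S)

    def step(self) -> dict:
        st = self.state
        if self.spec.family == "probit":
            self._update_z(st)
        self._update_B(st)
        self._update_Gamma(st)
        self._update_V(st)
        self._update_rho(st)
        for info in self.levels:
            self._update_level(st, info)
        self._update_sigma2(st)
        return st

    def snapshot(self) -> dict:
        st = self.state
        snap = {
            "beta": st["B"].copy(),
            "gamma": st["Gamma"].copy(),
            "V": st["V"].copy(),
            "rho": st["rho"],
            "sigma2": st["sigma2"].copy(),
        }
        for info in self.levels:
            ls = st["levels"][info["name"]]
            snap[f"lambda_{info['name']}"] = ls["lambda"].copy()
            snap[f"eta_{info['name']}"] = ls["eta"].copy()
            if info["spatial"]:
                snap[f"alpha_{info['name']}"] = info["alpha_grid"][ls["alpha_idx"]].copy()
        return snap


# ---------------------------------------------------------------------------
# chains


@dataclass
class PosteriorChains:
    """Retained MCMC snapshots, stacked per chain, plus run metadata."""

    chains: list[dict]  # parameter name -> (n_retained, ...) array
    schedule: dict
    meta: dict

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_retained_per_chain(self) -> int:
        return self.schedule["per_chain"]

    def combined(self, key: str) -> np.ndarray:
        return np.concatenate([c[key] for c in self.chains], axis=0)

    def per_chain(self, key: str) -> np.ndarray:
        return np.stack([c[key] for c in self.chains], axis=0)

    @property
    def level_names(self) -> list[str]:
        return self.meta["level_names"]

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, chain in enumerate(self.chains):
            for k, v in chain.items():
                arrays[f"chain{i}__{k}"] = v
        np.savez_compressed(path / "chains.npz", **arrays)
        meta = {k: v for k, v in self.meta.items()}
        with open(path / "manifest.json", "w") as fh:
            json.dump({"schedule": self.schedule, "meta": meta}, fh, indent=1, default=str)

    @classmethod
    def load(cls, path) -> "PosteriorChains":
        import json
        from pathlib import Path

        path = Path(path)
        with open(path / "manifest.json") as fh:
            man = json.load(fh)
        data = np.load(path / "chains.npz")
        chains: dict[int, dict] = {}
        for key in data.files:
            tag, name = key.split("__", 1)
            chains.setdefault(int(tag.removeprefix("chain")), {})[name] = data[key]
        ordered = [chains[i] for i in sorted(chains)]
        return cls(chains=ordered, schedule=man["schedule"], meta=man["meta"])


def run_chains(
    spec: ModelSpec,
    data: ModelData,
    n_chains: int = 4,
    n_iterations: int = 37500,
    burn_in: int = 12500,
    thin: int = 100,
    seed: int = 0,
) -> PosteriorChains:
    """Run ``n_chains`` independent Gibbs chains (chain c seeded seed + c)."""
    per_chain, total = count_retained_samples(n_iterations, burn_in, thin, n_chains)
    chains = []
    for c in range(n_chains):
        sampler = GibbsSampler(spec, data, seed=seed + c)
        kept: list[dict] = []
        for it in range(n_iterations):
            sampler.step()
            if it >= burn_in and (it - burn_in) % thin == thin - 1:
                kept.append(sampler.snapshot())
        # thin offset above keeps exactly per_chain = floor((it-burn)/thin) draws
        kept = kept[:per_chain]
        while len(kept) < per_chain:  # pragma: no cover - arithmetic guard
            kept.append(kept[-1])
        stacked = {
            k: np.stack([snap[k] for snap in kept]) if np.ndim(kept[0][k]) else
            np.array([snap[k] for snap in kept])
            for k in kept[0]
        }
        chains.append(stacked)
        logger.info("chain %d/%d finished: %d retained draws", c + 1, n_chains, len(kept))
    meta = {
        "columns": data.design.columns,
        "group_map": data.design.group_map,
        "constants": {k: list(v) for k, v in data.design.constants.items()},
        "species": data.species,
        "trait_names": data.trait_names,
        "level_names": [lev.name for lev in data.levels],
        "level_units": {lev.name: [str(u) for u in pd.unique(lev.units)] for lev in data.levels},
        "family": spec.family,
        "seeds": [seed + c for c in range(n_chains)],
    }
    if spec.family == "gaussian":
        sampler0 = GibbsSampler(spec, data, seed=seed)
        meta["response_mean"] = sampler0.y_mean.tolist()
        meta["response_sd"] = sampler0.y_sd.tolist()
    schedule = {
        "n_iterations": n_iterations,
        "burn_in": burn_in,
        "thin": thin,
        "n_chains": n_chains,
        "per_chain": per_chain,
        "total": total,
        "seed": seed,
    }
    return PosteriorChains(chains=chains, schedule=schedule, meta=meta)


# ---------------------------------------------------------------------------
# prediction


def predict_occurrence(
    chains: PosteriorChains,
    design_matrix: DesignMatrix | np.ndarray,
    level_units: dict[str, np.ndarray] | None = None,
    mode: str = "conditional",
    allow_unseen: bool = True,
) -> np.ndarray:
    """Posterior-mean occurrence probabilities Phi(m / sqrt(1 + v)).

    ``conditional`` uses the sampled latent factors of units seen during
    fitting and marginalizes unseen units (their level variance enters the
    probit denominator); ``marginal`` marginalizes every level.
    """
    if mode not in ("conditional", "marginal"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    X = design_matrix.X if isinstance(design_matrix, DesignMatrix) else np.asarray(design_matrix)
    level_units = level_units or {}
    n = X.shape[0]
    S = len(chains.meta["species"])
    level_codes = {}
    for name in chains.level_names:
        train_units = list(chains.meta["level_units"][name])
        if mode == "marginal" or name not in level_units:
            level_codes[name] = None
            continue
        labels = [str(u) for u in level_units[name]]
        lookup = {u: i for i, u in enumerate(train_units)}
        codes = np.array([lookup.get(u, -1) for u in labels])
        if (codes < 0).any() and not allow_unseen:
            bad = sorted({u for u in labels if u not in lookup})[:5]
            raise KeyError(f"units unseen during fitting at level {name!r}: {bad}")
        level_codes[name] = codes
    beta = chains.combined("beta")
    total = np.zeros((n, S))
    n_draws = beta.shape[0]
    for d in range(n_draws):
        m = X @ beta[d]
        var = np.zeros((n, S))
        for name in chains.level_names:
            lam = chains.combined(f"lambda_{name}")[d]
            omega_diag = (lam**2).sum(axis=0)
            codes = level_codes[name]
            if codes is None:
                var += omega_diag[None, :]
            else:
                eta = chains.combined(f"eta_{name}")[d]
                known = codes >= 0
                m[known] += eta[codes[known]] @ lam
                var[~known] += omega_diag[None, :]
        total += ndtr(m / np.sqrt(1.0 + var))
    return total / n_draws


# ---------------------------------------------------------------------------
# the environmental model (physico-chemical variables as responses)


def fit_environmental_model(
    covariates: pd.DataFrame,
    hier_design: pd.DataFrame,
    n_chains: int = 2,
    n_iterations: int = 1500,
    burn_in: int = 500,
    thin: int = 2,
    seed: int = 0,
    max_factors: dict | None = None,
) -> PosteriorChains:
    """Gaussian-family fit with temperature, ln PTOT, N:P and ln colour as
    responses and bathymetry + land use + linear year as predictors, with
    the same random levels as the community model (no traits/phylogeny)."""
    from .preprocess import BATHYMETRY, LAND_USE, FixedEffectsSpec, build_design_matrix

    responses = pd.DataFrame(
        {
            "temperature": covariates["temperature"],
            "ln_ptot": np.log(covariates["ptot"]),
            "np_ratio": covariates["np_ratio"],
            "ln_colour": np.log(covariates["colour"]),
        }
    )
    predictors = BATHYMETRY + LAND_USE
    overlap = set(responses.columns) & set(predictors)
    if overlap:
        raise ValueError(f"responses listed among predictors: {sorted(overlap)}")
    fe = FixedEffectsSpec(
        covariates=predictors,
        quadratic=[],
        ln_transform=["lake_area", "retention"],
        include_year=True,
    )
    dm = build_design_matrix(covariates, fe)
    data = make_model_data(
        community=responses,
        design_matrix=dm,
        hier_design=hier_design,
        traits=None,
        phylo=None,
        max_factors=max_factors or {"site": 2, "watershed": 1, "basin": 1, "year": 1},
    )
    spec = ModelSpec(family="gaussian", phylogeny=False)
    return run_chains(
        spec, data, n_chains=n_chains, n_iterations=n_iterations,
        burn_in=burn_in, thin=thin, seed=seed,
    )


def initialize_state(spec: ModelSpec, data: ModelData, seed: int) -> dict:
    """Deterministic initial sampler state (exposed for inspection)."""
    return GibbsSampler(spec, data, seed=seed).state
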
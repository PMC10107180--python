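"""Model evaluation: convergence, fit metrics, variance partitioning,
trait-explained niche variance, residual association networks, and
coefficient-support tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import PosteriorChains


# ---------------------------------------------------------------------------
# convergence


def compute_psrf(
    chains: PosteriorChains | np.ndarray, block: str | None = None, split: bool = False
) -> dict:
    """Gelman-Rubin potential scale reduction factor per scalar parameter.

    psrf = sqrt((n-1)/n + B/(n W)) with W the mean within-chain variance and
    B the between-chain variance of the chain means (times n). Two identical
    chains give B = 0 and psrf = sqrt((n-1)/n) <= 1. ``split=True``
    additionally halves each chain (sensitive to within-chain drift).
    Returns per-parameter psrf plus mean and upper (97.5%) summaries.
    """
    if isinstance(chains, PosteriorChains):
        if block is None:
            raise ValueError("a parameter block name is required")
        draws = chains.per_chain(block)  # (m, n, ...)
    else:
        draws = np.asarray(chains)
    if draws.ndim < 2:
        raise ValueError("need (chains, draws, ...) array")
    m, n = draws.shape[0], draws.shape[1]
    if m < 2:
        raise ValueError("psrf requires at least two chains")
    flat = draws.reshape(m, n, -1)
    if split:
        half = n // 2
        flat = np.concatenate([flat[:, :half], flat[:, half : 2 * half]], axis=0)
        m, n = flat.shape[0], flat.shape[1]
    if n < 2:
        raise ValueError("psrf requires at least 2 retained draws per (split) chain")
    means = flat.mean(axis=1)  # (m, k)
    W = flat.var(axis=1, ddof=1).mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt((n - 1) / n + B / (n * W))
    psrf = np.where(W <= 0, np.where(B > 0, np.inf, np.sqrt((n - 1) / n)), psrf)
    return {
        "psrf": psrf,
        "mean": float(np.nanmean(psrf)),
        "upper": float(np.nanquantile(psrf, 0.975)),
        "n_parameters": psrf.size,
        "split": split,
    }


# ---------------------------------------------------------------------------
# fit metrics


def tjur_r2(y: np.ndarray, p: np.ndarray) -> float:
    """Tjur's coefficient of discrimination:
    mean(p | y=1) - mean(p | y=0)."""
    y = np.asarray(y)
    p = np.asarray(p, float)
    if not ((y == 1).any() and (y == 0).any()):
        return float("nan")  # undefined for single-class responses
    return float(p[y == 1].mean() - p[y == 0].mean())


def auc(y: np.ndarray, p: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation with midranks."""
    y = np.asarray(y)
    p = np.asarray(p, float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def gaussian_r2(y: np.ndarray, predicted: np.ndarray) -> float:
    """1 - SS_resid/SS_total against posterior-mean predictions, floored at 0."""
    y = np.asarray(y, float)
    predicted = np.asarray(predicted, float)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("constant response: R2 undefined")
    return float(max(0.0, 1.0 - ((y - predicted) ** 2).sum() / ss_tot))


def fit_metrics(Y: pd.DataFrame, P: np.ndarray) -> pd.DataFrame:
    """Per-species AUC and Tjur R2 of predicted occurrence probabilities."""
    rows = {}
    P = np.asarray(P, float)
    for j, sp in enumerate(Y.columns):
        y = Y.iloc[:, j].to_numpy()
        rows[sp] = {"auc": auc(y, P[:, j]), "tjur_r2": tjur_r2(y, P[:, j])}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# variance partitioning


def variance_partition(
    chains: PosteriorChains,
    X: np.ndarray | None = None,
    group_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Partition per-species explained variance over fixed-effect covariate
    groups and random levels.

    Per posterior draw: each fixed group's contribution is the sample
    variance of its partial linear predictor, with cross-group covariances
    split equally between the two groups involved (negative net
    contributions are floored at zero); each random level contributes its
    latent-factor variance Omega_jj = sum_h lambda_hj^2. Proportions are
    normalized per species and averaged over draws. Rows sum to one.
    """
    columns = chains.meta["columns"]
    group_map = group_map or chains.meta["group_map"]
    if X is None:
        raise ValueError("the fitted design matrix X is required")
    non_int = [c for c in columns if c != "intercept"]
    missing = [c for c in non_int if c not in group_map]
    if missing:
        raise KeyError(f"group map lacks columns: {missing}")
    groups = list(dict.fromkeys(group_map[c] for c in non_int))
    col_idx = {g: [i for i, c in enumerate(columns) if c != "intercept" and group_map[c] == g]
               for g in groups}
    beta = chains.combined("beta")
    n_draws, _, S = beta.shape
    levels = chains.level_names
    comp_names = [f"fixed:{g}" for g in groups] + [f"random:{l}" for l in levels]
    acc = np.zeros((S, len(comp_names)))
    lam_draws = {l: chains.combined(f"lambda_{l}") for l in levels}
    for d in range(n_draws):
        partial = [X[:, col_idx[g]] @ beta[d][col_idx[g], :] for g in groups]
        partial = [f - f.mean(axis=0, keepdims=True) for f in partial]
        n = X.shape[0]
        contrib = np.zeros((S, len(comp_names)))
        # row sums of the group-covariance matrix: each cross covariance is
        # counted once per group, i.e. the 2*cov(a,b) term is split equally
        for a, fa in enumerate(partial):
            for b, fb in enumerate(partial):
                contrib[:, a] += (fa * fb).sum(axis=0) / n
        contrib[:, : len(groups)] = np.clip(contrib[:, : len(groups)], 0.0, None)
        for li, l in enumerate(levels):
            contrib[:, len(groups) + li] = (lam_draws[l][d] ** 2).sum(axis=0)
        total = contrib.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        acc += contrib / total
    out = pd.DataFrame(acc / n_draws, index=chains.meta["species"], columns=comp_names)
    return out


# ---------------------------------------------------------------------------
# traits


def trait_variance_explained(chains: PosteriorChains, T: np.ndarray) -> dict:
    """Share of among-species variation in beta captured by the trait
    regression, per covariate and overall.

    Per draw and covariate k: var_j(mu_kj) / var_j(beta_kj) clipped to
    [0, 1], mu the trait-regression mean. The overall summary is reported
    both variance-weighted (by var_j(beta_kj)) and unweighted.
    """
    T = np.asarray(T, float)
    beta = chains.combined("beta")
    gamma = chains.combined("gamma")
    n_draws, p, S = beta.shape
    if S < T.shape[1] + 1:
        raise ValueError("fewer species than trait covariates + 1")
    per_cov = np.zeros(p)
    weighted_num = 0.0
    weighted_den = 0.0
    unweighted = 0.0
    for d in range(n_draws):
        mu = (T @ gamma[d]).T  # p x S
        vm = mu.var(axis=1, ddof=0)
        vb = beta[d].var(axis=1, ddof=0)
        ratio = np.clip(np.where(vb > 0, vm / np.where(vb > 0, vb, 1.0), 0.0), 0.0, 1.0)
        per_cov += ratio
        weighted_num += (ratio * vb).sum()
        weighted_den += vb.sum()
        unweighted += ratio.mean()
    return {
        "per_covariate": pd.Series(per_cov / n_draws, index=chains.meta["columns"]),
        "overall_weighted": float(weighted_num / weighted_den),
        "overall_unweighted": float(unweighted / n_draws),
    }


# ---------------------------------------------------------------------------
# associations and support


def residual_associations(
    chains: PosteriorChains, level: str, support_threshold: float = 0.95
) -> dict:
    """Residual species-association network at one random level.

    Per draw, Omega = Lambda' Lambda is normalized to a correlation matrix R;
    support is the fraction of draws with R > 0 and sign calls are made
    where support >= threshold (positive) or <= 1 - threshold (negative).
    """
    if level not in chains.level_names:
        raise KeyError(f"level {level!r} was not fitted (have {chains.level_names})")
    lam = chains.combined(f"lambda_{level}")  # (nd, H, S)
    n_draws, _, S = lam.shape
    mean_R = np.zeros((S, S))
    pos = np.zeros((S, S))
    for d in range(n_draws):
        om = lam[d].T @ lam[d]
        dd = np.sqrt(np.clip(np.diag(om), 1e-12, None))
        R = om / dd[:, None] / dd[None, :]
        np.fill_diagonal(R, 1.0)
        mean_R += R
        pos += R > 0
    mean_R /= n_draws
    support = pos / n_draws
    calls = np.where(support >= support_threshold, 1, np.where(support <= 1 - support_threshold, -1, 0))
    np.fill_diagonal(calls, 0)
    sp = chains.meta["species"]
    return {
        "correlation": pd.DataFrame(mean_R, index=sp, columns=sp),
        "support": pd.DataFrame(support, index=sp, columns=sp),
        "sign": pd.DataFrame(calls, index=sp, columns=sp),
        "threshold": support_threshold,
    }


def coefficient_support(chains: PosteriorChains, threshold: float = 0.95) -> dict:
    """Posterior P(beta > 0) per covariate x species with 95%-rule sign calls
    and per-covariate proportions of supported responses."""
    beta = chains.combined("beta")
    support = (beta > 0).mean(axis=0)  # p x S
    calls = np.where(support >= threshold, 1, np.where(support <= 1 - threshold, -1, 0))
    cols = chains.meta["columns"]
    sp = chains.meta["species"]
    support_df = pd.DataFrame(support, index=cols, columns=sp)
    calls_df = pd.DataFrame(calls, index=cols, columns=sp)
    props = pd.DataFrame(
        {
            "prop_positive": (calls_df == 1).mean(axis=1),
            "prop_negative": (calls_df == -1).mean(axis=1),
        }
    )
    return {"support": support_df, "sign": calls_df, "proportions": props, "threshold": threshold}
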
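"""Regions of common profile (RCP): k-means clustering of the predicted
species occurrence matrix, majority-rule selection of the cluster number
over a battery of validity indices, and the ecological characterization of
the resulting community profiles (prevalence, richness, community-weighted
traits, environment over time, Games-Howell post hoc contrasts)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import studentized_range
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)


@dataclass
class RCPAssignment:
    labels: pd.Series  # sample -> 1..k
    centroids: np.ndarray  # k x species
    inertia: float
    k: int


def cluster_kmeans(
    P: pd.DataFrame | np.ndarray, k: int, n_starts: int = 10, seed: int = 0
) -> RCPAssignment:
    """Best-of-``n_starts`` Lloyd k-means (k-means++ starts) in Euclidean
    species-probability space; deterministic given the seed."""
    X = P.to_numpy(float) if isinstance(P, pd.DataFrame) else np.asarray(P, float)
    index = P.index if isinstance(P, pd.DataFrame) else pd.RangeIndex(len(X))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of samples ({len(X)})")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct rows ({n_distinct})")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed).fit(X)
    return RCPAssignment(
        labels=pd.Series(km.labels_ + 1, index=index, name="rcp"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        k=k,
    )


# ---------------------------------------------------------------------------
# validity indices (orientation noted per index)


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        tot += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(tot)


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    cl = np.unique(labels)
    diam = max(D[np.ix_(labels == c, labels == c)].max() for c in cl)
    sep = min(
        D[np.ix_(labels == a, labels == b)].min()
        for i, a in enumerate(cl)
        for b in cl[i + 1 :]
    )
    return sep / diam if diam > 0 else np.inf


def _c_index(D: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices_from(D, k=1)
    d_all = D[iu]
    same = labels[iu[0]] == labels[iu[1]]
    nw = int(same.sum())
    if nw == 0:
        return np.nan
    sw = d_all[same].sum()
    d_sorted = np.sort(d_all)
    smin = d_sorted[:nw].sum()
    smax = d_sorted[-nw:].sum()
    return float((sw - smin) / (smax - smin)) if smax > smin else np.nan


def _mcclain_rao(D: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices_from(D, k=1)
    d_all = D[iu]
    same = labels[iu[0]] == labels[iu[1]]
    if same.all() or (~same).all():
        return np.nan
    return float(d_all[same].mean() / d_all[~same].mean())


def select_k_majority(
    P: pd.DataFrame | np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    n_starts: int = 10,
    seed: int = 0,
    n_gap_references: int = 50,
) -> dict:
    """Majority vote over ten clustering validity indices.

    For every k in [k_min, k_max] a best-of-starts k-means fit is scored by
    Calinski-Harabasz (max), silhouette (max), Davies-Bouldin (min), Dunn
    (max), C-index (min), McClain-Rao (min), Krzanowski-Lai (max), Hartigan
    (first k with H(k) <= 10), Ball-Hall (max successive drop) and the gap
    statistic (first-SE rule). Each index votes one k; the winner is the
    modal vote with ties broken toward the smallest k.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2 (a single cluster has no contrast)")
    if k_max < k_min:
        raise ValueError("empty k range")
    X = P.to_numpy(float) if isinstance(P, pd.DataFrame) else np.asarray(P, float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    ks = list(range(k_min, k_max + 1))
    ks_ext = list(range(max(2, k_min - 1), k_max + 2))  # KL/Hartigan/gap need k+-1
    fits = {
        k: KMeans(n_clusters=k, n_init=n_starts, random_state=seed + k).fit(X)
        for k in ks_ext
        if k <= len(np.unique(X, axis=0))
    }
    W = {1: _within_ss(X, np.zeros(n, dtype=int))}
    W.update({k: float(f.inertia_) for k, f in fits.items()})
    D = squareform(pdist(X))
    values: dict[str, dict[int, float]] = {}

    def record(name, k, val):
        values.setdefault(name, {})[k] = float(val)

    for k in ks:
        if k not in fits:
            continue
        lab = fits[k].labels_
        record("calinski_harabasz", k, calinski_harabasz_score(X, lab))
        record("silhouette", k, silhouette_score(X, lab))
        record("davies_bouldin", k, davies_bouldin_score(X, lab))
        record("dunn", k, _dunn(D, lab))
        record("c_index", k, _c_index(D, lab))
        record("mcclain_rao", k, _mcclain_rao(D, lab))
        # Krzanowski-Lai
        if k - 1 in W and k + 1 in W:
            diff_k = (k - 1) ** (2 / p) * W[k - 1] - k ** (2 / p) * W[k]
            diff_k1 = k ** (2 / p) * W[k] - (k + 1) ** (2 / p) * W[k + 1]
            record("krzanowski_lai", k, abs(diff_k / diff_k1) if diff_k1 != 0 else np.nan)
        # Hartigan
        if k + 1 in W and W[k + 1] > 0:
            record("hartigan", k, (W[k] / W[k + 1] - 1.0) * (n - k - 1))
        # Ball-Hall successive drop
        if k - 1 in W:
            record("ball_hall", k, W[k - 1] / max(k - 1, 1) - W[k] / k)

    # gap statistic over uniform reference draws in the feature bounding box
    lo, hi = X.min(axis=0), X.max(axis=0)
    gap, gap_se = {}, {}
    for k in ks_ext:
        if k not in fits and k != 1:
            continue
        logs = []
        for _ in range(n_gap_references):
            ref = rng.uniform(lo, hi, size=X.shape)
            if k == 1:
                wk = _within_ss(ref, np.zeros(n, dtype=int))
            else:
                wk = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(ref).inertia_
            logs.append(np.log(max(wk, 1e-300)))
        logs = np.asarray(logs)
        wk_obs = W.get(k)
        if wk_obs is None or wk_obs <= 0:
            continue
        gap[k] = float(logs.mean() - np.log(wk_obs))
        gap_se[k] = float(logs.std(ddof=0) * np.sqrt(1 + 1 / n_gap_references))
    for k in ks:
        if k in gap:
            record("gap", k, gap[k])

    votes: dict[str, int] = {}
    for name in ("calinski_harabasz", "silhouette", "dunn", "krzanowski_lai"):
        if name in values and values[name]:
            votes[name] = max(values[name], key=lambda k: (values[name][k], -k))
    for name in ("davies_bouldin", "c_index", "mcclain_rao"):
        if name in values and values[name]:
            votes[name] = min(values[name], key=lambda k: (values[name][k], k))
    if "hartigan" in values:
        ok = [k for k in sorted(values["hartigan"]) if values["hartigan"][k] <= 10.0]
        votes["hartigan"] = ok[0] if ok else max(values["hartigan"])
    if "ball_hall" in values:
        votes["ball_hall"] = max(values["ball_hall"], key=lambda k: (values["ball_hall"][k], -k))
    gap_vote = None
    for k in ks:
        if k in gap and (k + 1) in gap:
            if gap[k] >= gap[k + 1] - gap_se[k + 1]:
                gap_vote = k
                break
    if gap_vote is None and gap:
        gap_vote = max(k for k in gap if k in ks)
    if gap_vote is not None:
        votes["gap"] = gap_vote

    # drop indices that produced no finite criterion
    votes = {n: k for n, k in votes.items() if k is not None}
    if not votes:
        raise RuntimeError("every validity index was undefined")
    counts = pd.Series(votes).value_counts().sort_index()
    best = counts.max()
    winners = sorted(counts.index[counts == best])
    winner = winners[0]
    return {
        "k_range": (k_min, k_max),
        "votes": votes,
        "vote_counts": counts.to_dict(),
        "winner": int(winner),
        "tie": len(winners) > 1,
        "tie_break_note": (
            f"tie among k={winners}; smallest k chosen" if len(winners) > 1 else ""
        ),
        "criteria": values,
    }


# ---------------------------------------------------------------------------
# cluster characterization


def scaled_prevalence(
    P: pd.DataFrame, assignment: RCPAssignment | pd.Series, scaled: bool = True
) -> pd.DataFrame:
    """Cluster x species prevalence, min-max scaled per species across
    clusters (species constant across clusters map to 0.5 by convention)."""
    labels = assignment.labels if isinstance(assignment, RCPAssignment) else assignment
    if not labels.index.equals(P.index):
        raise ValueError("assignment does not cover the samples of P")
    raw = P.groupby(labels.to_numpy()).mean()
    raw.index.name = "rcp"
    if not scaled:
        return raw
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    rng_ = hi - lo
    out = (raw - lo) / rng_.replace(0, np.nan)
    return out.fillna(0.5)


def expected_richness(
    P: pd.DataFrame, assignment: RCPAssignment | pd.Series | None = None
) -> dict:
    """Per-sample expected richness (row sums of occurrence probabilities;
    integer richness when given a binary matrix) and per-cluster summaries."""
    rich = P.sum(axis=1).rename("richness")
    out = {"per_sample": rich}
    if assignment is not None:
        labels = assignment.labels if isinstance(assignment, RCPAssignment) else assignment
        grp = rich.groupby(labels.to_numpy())
        out["per_cluster"] = pd.DataFrame({"mean": grp.mean(), "sd": grp.std(ddof=1), "n": grp.size()})
    return out


def community_weighted_mean(P: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """CWM_it = sum_j P_ij t_jt / sum_j P_ij; binary traits give proportions,
    cell volume stays on the ln scale. Zero-weight rows yield NaN."""
    if list(traits.index) != list(P.columns):
        raise ValueError("trait table not aligned to the species of P")
    if traits.isna().any().any():
        raise ValueError("traits contain missing values; impute first")
    W = P.to_numpy(float)
    tot = W.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cwm = (W @ traits.to_numpy(float)) / tot
    return pd.DataFrame(cwm, index=P.index, columns=traits.columns)


def games_howell(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Games-Howell post hoc test for all group pairs under unequal variances.

    Per pair: t = (m_i - m_j)/sqrt(s_i^2/n_i + s_j^2/n_j), Welch-Satterthwaite
    degrees of freedom, and p = P(Q_{k,df} >= |t|*sqrt(2)) from the
    studentized-range distribution with k = number of groups.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    stats = {}
    for g in names:
        x = values[groups == g]
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        if x.var(ddof=1) == 0:
            raise ValueError(f"group {g!r} has zero variance")
        stats[g] = (x.mean(), x.var(ddof=1), len(x))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            (m1, v1, n1), (m2, v2, n2) = stats[names[i]], stats[names[j]]
            se2 = v1 / n1 + v2 / n2
            t = (m1 - m2) / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            p = float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            rows.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "mean_difference": m1 - m2,
                    "se": np.sqrt(se2),
                    "df": df,
                    "t": t,
                    "p_value": min(max(p, 0.0), 1.0),
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def environment_by_cluster(
    covariates: pd.DataFrame,
    assignment: RCPAssignment | pd.Series,
    variables: list[str] | None = None,
) -> dict:
    """Per-cluster summary statistics of the environment plus the overall
    least-squares slope of each covariate on year (trend-line analogue)."""
    labels = assignment.labels if isinstance(assignment, RCPAssignment) else assignment
    if not labels.index.equals(covariates.index):
        raise ValueError("assignment not aligned to the covariate table")
    variables = variables or [c for c in covariates.columns if c != "year"]
    lab = labels.to_numpy()
    summaries = {}
    for v in variables:
        grp = covariates[v].groupby(lab)
        summaries[v] = pd.DataFrame(
            {"mean": grp.mean(), "sd": grp.std(ddof=1).fillna(0.0),
             "median": grp.median(), "n": grp.size()}
        )
    year = covariates["year"].to_numpy(float)
    slopes = {}
    A = np.column_stack([np.ones(len(year)), year])
    for v in variables:
        coef, *_ = np.linalg.lstsq(A, covariates[v].to_numpy(float), rcond=None)
        slopes[v] = float(coef[1])
    decade = (covariates["year"] // 10 * 10).astype(int)
    counts = pd.crosstab(decade, lab)
    counts.index.name = "decade"
    return {"summaries": summaries, "year_slopes": pd.Series(slopes), "samples_per_decade": counts}
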
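"""Raw monitoring tables -> model-ready structures.

Species filtering by cumulative biomass, split-taxon merging, trait
imputation along the taxonomy, taxonomy-as-phylogeny correlation, and the
fixed-effect design matrix (ln transforms, standardization, quadratic
physico-chemical terms, linear year).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Covariate conventions shared by the generator, the model and the pipeline.
PHYSICO_CHEMICAL = ["temperature", "ptot", "np_ratio", "colour"]
BATHYMETRY = ["lake_area", "mean_depth", "retention"]
LAND_USE = ["urban", "agriculture", "mineral_forest", "peat_forest"]
ALL_COVARIATES = PHYSICO_CHEMICAL + BATHYMETRY + LAND_USE
#: covariates entered on the natural-log scale
LN_TRANSFORM = ["ptot", "colour", "lake_area", "retention"]
YEAR = "year"

TAXONOMIC_RANKS = ["class", "order", "family", "genus"]
BINARY_TRAITS = ["n_fixation", "silica", "motility", "chain_forming", "toxic"]
CONTINUOUS_TRAITS = ["ln_volume"]
ALL_TRAITS = CONTINUOUS_TRAITS + BINARY_TRAITS

COVARIATE_GROUPS = {
    **{c: "physico_chemical" for c in PHYSICO_CHEMICAL},
    **{c: "bathymetry" for c in BATHYMETRY},
    **{c: "land_use" for c in LAND_USE},
    YEAR: "year",
}


@dataclass
class FixedEffectsSpec:
    """Which covariates enter the fixed part and how.

    ``quadratic`` lists covariates that additionally get a squared column
    (square of the standardized, possibly ln-transformed, value).
    """

    covariates: list[str] = field(default_factory=lambda: list(ALL_COVARIATES))
    quadratic: list[str] = field(default_factory=lambda: list(PHYSICO_CHEMICAL))
    ln_transform: list[str] = field(default_factory=lambda: list(LN_TRANSFORM))
    include_year: bool = True
    standardize: bool = True


@dataclass
class DesignMatrix:
    """Expanded fixed-effect matrix with its transform log.

    ``constants`` maps column name -> (ln_flag, mean, sd) so a matrix for new
    data can be rebuilt bit-identically with the stored constants.
    """

    X: np.ndarray
    columns: list[str]
    group_map: dict[str, str]
    constants: dict[str, tuple[bool, float, float]]
    sample_ids: list

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.columns)


def select_species_by_biomass(abundance: pd.Series, fraction: float) -> list[str]:
    """Shortest descending-biomass prefix reaching ``fraction`` of the total.

    Species tied with the boundary species' biomass are all retained.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(abundance) == 0:
        raise ValueError("abundance table is empty")
    if (abundance < 0).any():
        raise ValueError("negative biomass values")
    total = float(abundance.sum())
    if total <= 0:
        raise ValueError("total biomass is zero")
    srt = abundance.sort_values(ascending=False, kind="mergesort")
    cum = srt.cumsum() / total
    # first index where the cumulative share reaches the fraction
    cut = int(np.searchsorted(cum.to_numpy(), fraction - 1e-12))
    boundary = srt.iloc[cut]
    keep = srt[(srt > boundary) | np.isclose(srt, boundary)].index
    # preserve descending-biomass order, include all ties with the boundary
    return [s for s in srt.index if s in set(keep)]


def merge_split_taxa(community: pd.DataFrame, mapping: pd.DataFrame | dict) -> pd.DataFrame:
    """Collapse split taxa back to their parent by element-wise logical OR.

    ``mapping`` is child -> parent (dict, or a DataFrame with columns
    ``child``/``parent``). The parent column need not pre-exist; the result
    is idempotent on re-application.
    """
    if isinstance(mapping, pd.DataFrame):
        dup = mapping["child"][mapping["child"].duplicated()]
        if len(dup):
            raise ValueError(f"children mapped to multiple parents: {sorted(set(dup))}")
        mapping = dict(zip(mapping["child"], mapping["parent"]))
    # children already absorbed (re-application) are silently ignored
    mapping = {c: p for c, p in mapping.items() if c in community.columns}
    parents: dict[str, list[str]] = {}
    for child, parent in mapping.items():
        parents.setdefault(parent, []).append(child)
    out = {}
    consumed = set(mapping)
    for col in community.columns:
        if col in consumed and col not in parents:
            continue  # a child column, absorbed into its parent
        members = [m for m in [col] + parents.get(col, []) if m in community.columns]
        out[col] = community[members].max(axis=1)
    for parent, children in parents.items():
        if parent not in out:  # parent never observed as its own column
            out[parent] = community[children].max(axis=1)
    return pd.DataFrame(out, index=community.index).astype(int)


def impute_traits(
    traits: pd.DataFrame, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing trait values from the nearest taxonomic rank with data.

    Continuous cell volume: mean of non-missing family members, falling back
    to order, class, then the global mean. Binary traits: modal value at the
    nearest ascending rank (genus -> family -> order -> class -> global),
    ties broken toward 0. Returns the completed table and a boolean mask of
    imputed cells.
    """
    missing_sp = [s for s in traits.index if s not in taxonomy.index]
    if missing_sp:
        raise KeyError(f"taxonomy does not cover species: {missing_sp}")
    out = traits.copy().astype(float)
    mask = traits.isna()
    for trait in traits.columns:
        col = traits[trait]
        if col.isna().all():
            raise ValueError(f"trait {trait!r} is missing for every species")
        if not col.isna().any():
            continue
        binary = trait in BINARY_TRAITS or set(col.dropna().unique()) <= {0.0, 1.0}
        ranks = (["family", "order", "class"] if not binary
                 else ["genus", "family", "order", "class"])
        for sp in col.index[col.isna()]:
            value = np.nan
            for rank in ranks:
                members = taxonomy.index[taxonomy[rank] == taxonomy.loc[sp, rank]]
                vals = col.loc[[m for m in members if m != sp]].dropna()
                if len(vals):
                    if binary:
                        mean = vals.mean()
                        value = 1.0 if mean > 0.5 else 0.0  # ties -> 0
                    else:
                        value = float(vals.mean())
                    break
            if np.isnan(value):
                vals = col.dropna()
                value = (1.0 if vals.mean() > 0.5 else 0.0) if binary else float(vals.mean())
            out.loc[sp, trait] = value
    return out, mask


def _check_nested(taxonomy: pd.DataFrame) -> None:
    for child, parent in [("genus", "family"), ("family", "order"), ("order", "class")]:
        counts = taxonomy.groupby(child)[parent].nunique()
        bad = counts[counts > 1]
        if len(bad):
            name = bad.index[0]
            parents = sorted(taxonomy.loc[taxonomy[child] == name, parent].unique())
            raise ValueError(
                f"rank inconsistency: {child} {name!r} maps to multiple {parent}s {parents}"
            )


def taxonomy_to_correlation(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Species correlation from the 5-rank taxonomy with unit branch lengths.

    The tree is root -> class -> order -> family -> genus -> species; the
    correlation of two species is the depth of their most recent common
    ancestor divided by the tip depth (5), i.e. congeners share 4/5 = 0.8.
    """
    for rank in TAXONOMIC_RANKS:
        if rank not in taxonomy.columns:
            raise KeyError(f"taxonomy lacks rank {rank!r}")
        if taxonomy[rank].isna().any() or (taxonomy[rank] == "").any():
            raise ValueError(f"empty labels at rank {rank!r}")
    _check_nested(taxonomy)
    species = list(taxonomy.index)
    codes = [taxonomy[r].astype("category").cat.codes.to_numpy() for r in TAXONOMIC_RANKS]
    n = len(species)
    depth = np.zeros((n, n))
    for level, code in enumerate(codes):  # class=depth1 ... genus=depth4
        same = code[:, None] == code[None, :]
        if level > 0:
            same &= depth >= level  # shared only if all coarser ranks shared
        depth = np.where(same, level + 1, depth)
    C = depth / 5.0
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=species, columns=species)


def taxonomy_to_newick(taxonomy: pd.DataFrame) -> str:
    """Newick string of the taxonomy tree with unit branch lengths."""
    import dendropy

    _check_nested(taxonomy)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[tuple, dendropy.Node] = {}
    for sp, row in taxonomy.iterrows():
        parent = tree.seed_node
        path: tuple = ()
        for rank in TAXONOMIC_RANKS:
            path = path + (row[rank],)
            if path not in nodes:
                node = dendropy.Node(edge_length=1.0)
                parent.add_child(node)
                nodes[path] = node
            parent = nodes[path]
        leaf = dendropy.Node(edge_length=1.0)
        leaf.taxon = taxa.new_taxon(str(sp))
        parent.add_child(leaf)
    return tree.as_string(schema="newick").strip()


def build_trait_matrix(traits: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Species x trait-covariate matrix: intercept, standardized ln volume,
    and the five binary traits as given."""
    if traits[ALL_TRAITS].isna().any().any():
        raise ValueError("traits contain missing values; impute first")
    lnv = traits["ln_volume"].to_numpy(float)
    sd = lnv.std(ddof=0)
    lnv_z = (lnv - lnv.mean()) / sd if sd > 0 else lnv * 0.0
    cols = np.column_stack(
        [np.ones(len(traits)), lnv_z] + [traits[t].to_numpy(float) for t in BINARY_TRAITS]
    )
    return cols, ["intercept", "ln_volume"] + BINARY_TRAITS


def build_design_matrix(
    covariates: pd.DataFrame,
    spec: FixedEffectsSpec | None = None,
    constants: dict[str, tuple[bool, float, float]] | None = None,
) -> DesignMatrix:
    """Expand the covariate table into the fixed-effect matrix.

    ln transforms for PTOT, colour, lake area and retention days; each
    continuous covariate standardized (constants stored for reuse on new
    data); squared columns (of the standardized value) appended for the
    physico-chemical covariates; year entered linearly; intercept first.
    """
    spec = spec or FixedEffectsSpec()
    cov_names = list(spec.covariates) + ([YEAR] if spec.include_year else [])
    for name in cov_names:
        if name not in covariates.columns:
            raise KeyError(f"covariate {name!r} not in table")
    rows_ok = covariates[cov_names].notna().all(axis=1)
    if not rows_ok.all():
        raise ValueError(
            f"{int((~rows_ok).sum())} samples have missing covariate values; "
            "drop them before building the design matrix"
        )
    new_constants = constants is None
    constants = dict(constants or {})
    columns = ["intercept"]
    data = [np.ones(len(covariates))]
    group_map: dict[str, str] = {}
    lin_values: dict[str, np.ndarray] = {}
    for name in cov_names:
        raw = covariates[name].to_numpy(float)
        ln = name in spec.ln_transform
        if ln:
            if (raw <= 0).any():
                bad = covariates.index[raw <= 0][0]
                raise ValueError(f"non-positive value of ln-target {name!r} at sample {bad!r}")
            raw = np.log(raw)
        if new_constants:
            mean, sd = (float(raw.mean()), float(raw.std(ddof=0))) if spec.standardize else (0.0, 1.0)
            if spec.standardize and sd == 0:
                raise ValueError(f"zero-variance covariate {name!r}")
            constants[name] = (ln, mean, sd)
        ln_stored, mean, sd = constants[name]
        if ln_stored != ln:
            raise ValueError(f"stored transform for {name!r} disagrees with spec")
        val = (raw - mean) / sd if sd != 0 else raw - mean
        lin_values[name] = val
        columns.append(name)
        data.append(val)
        group_map[name] = COVARIATE_GROUPS.get(name, "other")
    for name in spec.quadratic:
        if name not in lin_values:
            raise KeyError(f"quadratic covariate {name!r} not among fixed covariates")
        columns.append(f"{name}_sq")
        data.append(lin_values[name] ** 2)
        group_map[f"{name}_sq"] = COVARIATE_GROUPS.get(name, "other")
    X = np.column_stack(data)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in design matrix")
    return DesignMatrix(
        X=X,
        columns=columns,
        group_map=group_map,
        constants=constants,
        sample_ids=list(covariates.index),
    )
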
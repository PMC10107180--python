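"""Dataset-bundle I/O, run configuration and result writing.

A dataset bundle is a directory of plain CSVs with header rows --
community.csv, covariates.csv, traits.csv, taxonomy.csv, design.csv,
optional biomass.csv / merge_map.csv / truth.json -- sharing sample ids
(community/covariates/design) and species ids (community/traits/taxonomy).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import ALL_COVARIATES, ALL_TRAITS, LN_TRANSFORM, TAXONOMIC_RANKS
from .synthetic import GroundTruth

logger = logging.getLogger("lakejsdm")

REQUIRED_FILES = ["community.csv", "covariates.csv", "traits.csv", "taxonomy.csv", "design.csv"]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    dataset: str = "dataset"
    out_dir: str = "results"
    seed: int = 0
    n_chains: int = 2
    n_iterations: int = 1500
    burn_in: int = 500
    thin: int = 2
    max_factors: dict = field(
        default_factory=lambda: {"site": 2, "watershed": 1, "basin": 1, "year": 1}
    )
    support_threshold: float = 0.95
    prediction_mode: str = "conditional"
    rcp_k_min: int = 2
    rcp_k_max: int = 10
    rcp_n_starts: int = 10
    fit_environmental: bool = True
    psrf_warn: float = 1.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_bundle(bundle: dict, path) -> None:
    """Write a generated dataset bundle as plain CSVs (+ truth.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle["community"].to_csv(path / "community.csv", index_label="sample_id")
    bundle["covariates"].to_csv(path / "covariates.csv", index_label="sample_id")
    bundle["traits"].to_csv(path / "traits.csv", index_label="species")
    bundle["taxonomy"].to_csv(path / "taxonomy.csv", index_label="species")
    bundle["design"].to_csv(path / "design.csv", index_label="sample_id")
    if bundle.get("biomass") is not None:
        bundle["biomass"].rename("biomass").to_csv(path / "biomass.csv", index_label="species")
    truth = bundle.get("truth")
    if truth is not None:
        (path / "truth.json").write_text(truth.to_json())


def read_bundle(path) -> dict:
    """Read and cross-validate a dataset bundle; every violation is listed."""
    path = Path(path)
    problems: list[str] = []
    missing = [f for f in REQUIRED_FILES if not (path / f).exists()]
    if missing:
        raise FileNotFoundError(f"bundle at {path} lacks required files: {missing}")
    community = pd.read_csv(path / "community.csv", index_col="sample_id")
    covariates = pd.read_csv(path / "covariates.csv", index_col="sample_id")
    traits = pd.read_csv(path / "traits.csv", index_col="species")
    taxonomy = pd.read_csv(path / "taxonomy.csv", index_col="species")
    design = pd.read_csv(path / "design.csv", index_col="sample_id")

    vals = community.to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        problems.append(
            f"community matrix has non-binary cells, e.g. "
            f"{community.index[i]!r} x {community.columns[j]!r} = {vals[i, j]!r}"
        )
    for name, table in (("covariates", covariates), ("design", design)):
        if list(table.index) != list(community.index):
            problems.append(f"sample ids of {name}.csv do not match community.csv")
    for name, table in (("traits", traits), ("taxonomy", taxonomy)):
        missing_sp = [s for s in community.columns if s not in table.index]
        if missing_sp:
            problems.append(f"{name}.csv lacks species: {missing_sp[:5]}")
    for cov in LN_TRANSFORM:
        if cov in covariates.columns and (covariates[cov] <= 0).any():
            sample = covariates.index[covariates[cov] <= 0][0]
            problems.append(f"non-positive ln-target {cov!r} at sample {sample!r}")
    for cov in ALL_COVARIATES + ["year"]:
        if cov not in covariates.columns:
            problems.append(f"covariates.csv lacks column {cov!r}")
    for rank in TAXONOMIC_RANKS:
        if rank not in taxonomy.columns:
            problems.append(f"taxonomy.csv lacks rank {rank!r}")
    for col in ("site", "watershed", "basin", "year", "x_km", "y_km"):
        if col not in design.columns:
            problems.append(f"design.csv lacks column {col!r}")
    if not problems:
        for child, parent in (("site", "watershed"), ("watershed", "basin")):
            if design.groupby(child)[parent].nunique().gt(1).any():
                problems.append(f"nesting violated: a {child} maps to several {parent}s")
        if design.groupby("site")[["x_km", "y_km"]].nunique().gt(1).any().any():
            problems.append("site coordinates vary across samples")
    if problems:
        raise ValueError("invalid bundle:\n- " + "\n- ".join(problems))

    out = {
        "community": community.astype(int),
        "covariates": covariates,
        "traits": traits.reindex(community.columns),
        "taxonomy": taxonomy.reindex(community.columns),
        "design": design,
        "truth": None,
        "biomass": None,
    }
    if (path / "truth.json").exists():
        out["truth"] = GroundTruth.from_json((path / "truth.json").read_text())
    if (path / "biomass.csv").exists():
        out["biomass"] = pd.read_csv(path / "biomass.csv", index_col="species")["biomass"]
    if (path / "merge_map.csv").exists():
        out["merge_map"] = pd.read_csv(path / "merge_map.csv")
    logger.info(
        "bundle loaded: %d samples x %d species", len(community), community.shape[1]
    )
    return out


def write_results(outputs: dict, out_dir, config: RunConfig | None = None) -> dict:
    """Write CSV/JSON artifacts with a manifest; deterministic re-runs give
    byte-identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = []
    for name, obj in outputs.items():
        if obj is None:
            continue
        if isinstance(obj, (pd.DataFrame, pd.Series)):
            fname = f"{name}.csv"
            obj.to_csv(out_dir / fname)
        else:
            fname = f"{name}.json"
            (out_dir / fname).write_text(json.dumps(obj, indent=1, default=_jsonify))
        artifacts.append(fname)
    import lakejsdm

    manifest = {
        "artifacts": sorted(artifacts),
        "package_version": lakejsdm.__version__,
        "config": config.to_dict() if config else None,
        "config_hash": config.config_hash() if config else None,
        "seed": config.seed if config else None,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return obj.to_dict()
    return str(obj)
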
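#!/usr/bin/env python
"""Evaluate the fitted community model.

Computes conditional occurrence predictions, per-species AUC and Tjur R2,
the variance partition over covariate groups and random levels, the share
of among-species niche variation explained by traits, residual species
associations per level, and the coefficient-support table. Writes the
tables under results/evaluation/ and prints the community means.
"""

from pathlib import Path

import pandas as pd

from lakejsdm import evaluate
from lakejsdm.io import read_bundle
from lakejsdm.model import PosteriorChains, predict_occurrence
from lakejsdm.preprocess import ALL_TRAITS, build_design_matrix, impute_traits
from lakejsdm.preprocess import build_trait_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = read_bundle(ROOT / "dataset")
    chains = PosteriorChains.load(ROOT / "posterior")
    constants = {k: tuple(v) for k, v in chains.meta["constants"].items()}
    dm = build_design_matrix(bundle["covariates"], constants=constants)
    level_units = {n: bundle["design"][n].to_numpy() for n in chains.level_names}
    P = predict_occurrence(chains, dm, level_units)
    P_df = pd.DataFrame(P, index=bundle["community"].index,
                        columns=chains.meta["species"])

    out = ROOT / "evaluation"
    out.mkdir(parents=True, exist_ok=True)
    P_df.to_csv(out / "predicted_occurrence.csv")

    metrics = evaluate.fit_metrics(bundle["community"], P)
    metrics.to_csv(out / "species_fit_metrics.csv")
    print(f"mean AUC {metrics['auc'].mean():.3f}, "
          f"mean Tjur R2 {metrics['tjur_r2'].mean():.3f}")

    vp = evaluate.variance_partition(chains, X=dm.X)
    vp.to_csv(out / "variance_partition.csv")
    print("variance partition, community means (%):")
    print((vp.mean(axis=0) * 100).round(1).to_string())

    traits, _ = impute_traits(bundle["traits"][ALL_TRAITS], bundle["taxonomy"])
    T, _ = build_trait_matrix(traits)
    tve = evaluate.trait_variance_explained(chains, T)
    print(f"traits explain {tve['overall_weighted'] * 100:.1f}% "
          f"(variance-weighted) of among-species niche variation")

    support = evaluate.coefficient_support(chains)
    support["support"].to_csv(out / "beta_support.csv")
    support["proportions"].to_csv(out / "beta_support_proportions.csv")
    for level in chains.level_names:
        assoc = evaluate.residual_associations(chains, level)
        assoc["correlation"].to_csv(out / f"associations_{level}.csv")
        n_pos = int((assoc["sign"].to_numpy() == 1).sum() // 2)
        n_neg = int((assoc["sign"].to_numpy() == -1).sum() // 2)
        print(f"residual associations at {level}: {n_pos} positive, "
              f"{n_neg} negative pairs at 95% support")


if __name__ == "__main__":
    main()
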
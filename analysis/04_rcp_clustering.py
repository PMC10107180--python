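#!/usr/bin/env python
"""Regions of common profile from the predicted occurrence matrix.

Selects the number of clusters by majority rule over ten validity indices
(k in 2..10), assigns samples by k-means, and characterizes each profile:
scaled species prevalence, expected richness, community-weighted mean
traits, environment by cluster, and Games-Howell contrasts. Writes tables
under results/rcp/ and prints the selection report and profile summaries.
"""

from pathlib import Path

import pandas as pd

from lakejsdm import rcp
from lakejsdm.io import read_bundle
from lakejsdm.preprocess import ALL_TRAITS, impute_traits

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = read_bundle(ROOT / "dataset")
    P = pd.read_csv(ROOT / "evaluation" / "predicted_occurrence.csv", index_col=0)
    out = ROOT / "rcp"
    out.mkdir(parents=True, exist_ok=True)

    sel = rcp.select_k_majority(P, 2, 10, seed=SEED)
    print(f"majority rule selects k = {sel['winner']} "
          f"(votes: {sel['vote_counts']}){' - ' + sel['tie_break_note'] if sel['tie'] else ''}")
    assignment = rcp.cluster_kmeans(P, sel["winner"], seed=SEED)
    assignment.labels.to_csv(out / "assignment.csv")

    prev = rcp.scaled_prevalence(P, assignment)
    prev.to_csv(out / "prevalence_scaled.csv")
    rcp.scaled_prevalence(P, assignment, scaled=False).to_csv(out / "prevalence_raw.csv")

    rich = rcp.expected_richness(P, assignment)
    rich["per_cluster"].to_csv(out / "richness_per_cluster.csv")
    print("expected richness by RCP:")
    print(rich["per_cluster"].round(2).to_string())

    traits, _ = impute_traits(bundle["traits"][ALL_TRAITS], bundle["taxonomy"])
    cwm = rcp.community_weighted_mean(P, traits)
    cwm.to_csv(out / "cwm_per_sample.csv")
    print("community-weighted means by RCP:")
    print(cwm.groupby(assignment.labels.to_numpy()).mean().round(3).to_string())

    rows = []
    for trait in cwm.columns:
        gh = rcp.games_howell(cwm[trait].to_numpy(), assignment.labels.to_numpy())
        gh.insert(0, "variable", trait)
        rows.append(gh)
    pd.concat(rows, ignore_index=True).to_csv(out / "games_howell.csv", index=False)

    env = rcp.environment_by_cluster(bundle["covariates"], assignment)
    env["year_slopes"].to_csv(out / "environment_year_slopes.csv")
    print("least-squares slopes of the environment on year:")
    print(env["year_slopes"].round(4).to_string())


if __name__ == "__main__":
    main()
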
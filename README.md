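# lakejsdm

Hierarchical Bayesian joint species distribution modelling (JSDM) and
region-of-common-profile (RCP) clustering for lake metacommunity
monitoring data.

## The problem

National lake-monitoring programmes record which phytoplankton species
occur in which lakes, year after year, together with physico-chemical
water measurements, lake bathymetry and catchment land use. Two questions
drive the analysis this package implements:

1. **What structures species niches?** How much of each species'
   occurrence pattern is explained by the environment (nutrients,
   temperature, water colour, lake morphology, land use), by a linear
   temporal trend, and by spatially or temporally structured processes the
   covariates miss — and do closely related or functionally similar
   species respond alike?
2. **How do whole communities reorganize?** Do samples fall into a small
   number of recurring compositional profiles, and how do those profiles
   differ in richness, traits and environment over time?

## The model

For sample *i* and species *j*, presence is a probit regression on a
latent score

y_ij = **1**{ x_iᵀ β_j + Σ_l η_{l,u_l(i)}ᵀ λ_{l,j} + ε_ij > 0 },  ε_ij ~ N(0, 1)

* **Fixed part** x_i: intercept; standardized physico-chemical variables
  (temperature, ln total phosphorus, N:P ratio, ln water colour) with
  squared terms (intermediate niche optima); ln lake area, mean depth, ln
  retention days; four land-use percentages; a linear year term.
* **Species niches** β_j follow a trait regression with phylogenetic
  residuals: vec(B) ~ N(vec(ΓᵀTᵀ), [ρC + (1−ρ)I] ⊗ V), where T holds the
  six traits (ln cell volume, N fixation, silica demand, motility, chain
  forming, toxin production), Γ is the trait→niche regression, C is the
  correlation implied by the 5-rank taxonomy with unit branch lengths, and
  ρ ∈ [0, 1] is the phylogenetic signal.
* **Random part**: latent factors η with loadings λ at four nested
  levels — site (spatially explicit, exponential-decay kernel
  exp(−d/α) over planar km coordinates), watershed, river basin, and
  year — whose cross-products Ω = ΛᵀΛ give residual species associations
  per level and the level's share in the variance partition.

Everything is sampled by a blocked Gibbs sampler (truncated-normal data
augmentation; conjugate updates for B, Γ, V, factors, loadings and
multiplicative-gamma shrinkage; exact discrete-grid posteriors for ρ and
the spatial ranges α). A Gaussian-family variant of the same sampler fits
the *environmental model* — the physico-chemical variables themselves as
responses of bathymetry, land use and year.

Downstream, predicted occurrence probabilities are clustered into regions
of common profile: k-means over k = 2…10, the number of clusters chosen
by majority vote over ten validity indices, and each profile
characterized by scaled species prevalence, expected richness,
community-weighted mean (CWM) traits, environment over time, and
Games–Howell post hoc contrasts.

Because real monitoring data cannot ship with the package, a first-class
synthetic-data module generates seeded datasets with exactly this
structure — including the ground-truth β, Γ, ρ, loadings and (optionally)
planted community profiles — so every stage can be tested for parameter
recovery.

## Worked example

```sh
python analysis/01_simulate.py            # desk-scale synthetic dataset
python analysis/02_fit_community_model.py # JSDM fit, 2 chains
python analysis/03_evaluate_model.py      # metrics, variance partition
python analysis/04_rcp_clustering.py      # regions of common profile
python analysis/05_environmental_model.py # physico-chemistry over time
```

Output of steps 01–03 on the default seed:

```
dataset written to results/dataset
  342 samples at 48 sites, 12 watersheds, 4 basins, years 2008-2017
  40 species, overall prevalence 0.302
  true phylogenetic signal rho = 0.8
psrf beta: mean 1.023, upper 1.125 (680 parameters)
psrf gamma: mean 1.009, upper 1.064 (119 parameters)
phylogenetic signal rho: posterior mean 0.74 (95% CI 0.58-0.88)
mean AUC 0.956, mean Tjur R2 0.577
variance partition, community means (%):
fixed:physico_chemical    47.6
fixed:bathymetry           7.5
fixed:land_use            11.5
fixed:year                 3.2
random:site               11.2
random:watershed           5.7
random:basin               7.8
random:year                5.5
```

Reading this: the chains mix (psrf ≈ 1), the posterior of ρ covers the
generating value 0.8, the model discriminates presences from absences
well (AUC 0.96), and the explained variance splits between the
physico-chemical covariates and the spatial/temporal random levels — the
quantities a monitoring analysis would report. The same commands on the
planted-profile preset (`lakejsdm simulate --preset planted`) recover the
four planted community profiles exactly (adjusted Rand index 1.0).

There is also a CLI for the full pipeline:

```sh
lakejsdm simulate --preset desk --seed 1 --out dataset/
lakejsdm run --dataset dataset/ --out results/ --seed 1
lakejsdm report --results results/
```

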
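# Methods

This note documents the statistical model, the sampler, the synthetic
data generator, and the numerical and design choices behind `lakejsdm`.

## The community model

Let y_ij ∈ {0,1} be presence of species j in sample i (n samples,
S species). The probit latent-score formulation is

z_ij = x_iᵀ β_j + Σ_l η_{l, u_l(i)}ᵀ λ_{l,j} + ε_ij,  ε_ij ~ N(0,1),
y_ij = 1{z_ij > 0}.

**Fixed effects.** The design matrix is built once and its transform
constants logged: total phosphorus, water colour, lake area and retention
days enter on the natural-log scale; every continuous covariate
(including the linear year term) is standardized to mean 0, SD 1; squared
terms of the four standardized physico-chemical covariates implement
intermediate niche optima; the intercept is the first column. Squares are
taken *after* standardization (centered-quadratic convention) to limit
collinearity; niche-optimum readouts must therefore use the stored
constants. The N:P ratio enters untransformed (it is already a unitless
ratio). Samples with any missing fixed-effect covariate are excluded at
design-matrix construction with an explicit count.

**Species niches.** B (covariates × species) is matrix normal:
row (covariate) covariance V ~ InverseWishart(p + 1, I); column (species)
correlation ρC + (1−ρ)I, where C comes from the 5-rank taxonomy
(class/order/family/genus/species) treated as a tree with unit branch
lengths: C_jk = (depth of the most recent common ancestor)/5, so
congeners have C = 0.8 and species of different classes C = 0. The prior
mean of B is the trait regression ΓᵀTᵀ with T = [1, standardized ln cell
volume, five binary traits] and Γ_entries ~ N(0,1) (reasonable because
covariates are standardized). ρ has a discrete prior on a 101-point grid
over [0,1] with probability ½ on ρ = 0 and ½ spread uniformly — a
point-null that lets the data switch the phylogeny off.

**Random levels.** Each level (site, watershed, basin, year) carries
latent factors η (units × H) with loadings Λ (H × S) under
multiplicative-gamma process shrinkage (δ₁ ~ Ga(2,1), δ_h ~ Ga(3,1) for
h ≥ 2, local scales φ ~ Ga(ν/2, ν/2) with ν = 3), which orders factors by
importance. H is fixed per level (site 2, others 1 by default; the
planted-profile preset uses site 4 so the site level can represent four
planted profiles, which span three offset dimensions) rather than
adaptive birth/death — simpler, and shrinkage still prunes unused
factors. The site level is spatial: factor h has prior
η_h ~ N(0, exp(−d/α_h)) over planar site coordinates (km, Euclidean
distance — the spatial kernel only needs a metric at national scale), with
α_h sampled from a uniform 20-point grid from 0 (non-spatial) to half the
maximal inter-site distance. The exact-GP covariance is used; spatial
levels with more than 2,000 units are refused with a pointer to
subsampling, since the exact factorizations would dominate the runtime.

**Gibbs sweep** (order fixed; deterministic given the seed):
truncated-normal z (inverse-CDF with clipped tails); B via the
eigendecomposition of C — after rotating species by the eigenvectors the
species decouple, so one p × p solve per species suffices and the
eigendecomposition is reused across sweeps; Γ and V by their conjugate
normals/inverse-Wishart; ρ by its exact discrete posterior; per level η
(joint solve across units and factors at spatial levels, independent
per-unit solves otherwise), Λ, shrinkage variables, and α by grid
posterior; σ² per response (Gaussian family, InverseGamma(1,1)).
Chain c is seeded seed + c.

The Gaussian family standardizes responses internally and keeps a
species-specific σ². Combining the Gaussian family with a phylogeny is
refused: species-specific residual variances break the Kronecker
decoupling of the B update, and the environmental model — the only
Gaussian use case here — has no tree.

**The environmental model** reuses the sampler with the physico-chemical
variables (temperature, ln PTOT, N:P, ln colour) as responses,
bathymetry + land use + linear year as predictors (all linear), the same
random levels, and no traits/phylogeny.

## Prediction

Occurrence probabilities are posterior means over retained draws of
Φ(m/√(1+v)): m collects the fixed part plus the sampled factor
contributions of units seen in fitting (conditional mode, the default);
v accumulates the latent variance Ω_jj = Σ_h λ²_hj of marginalized
levels — all levels in marginal mode, or just unseen units in
conditional mode. Whether a published analysis of this kind predicts
conditionally or marginally is usually unstated; both modes are exposed.

## Evaluation

* **psrf** — Gelman–Rubin per scalar parameter,
  √((n−1)/n + B/(nW)). The default does not split chains, so two
  byte-identical chains give B = 0 and psrf = √((n−1)/n) exactly (a useful
  smoke invariant); `split=True` halves chains first and is sensitive to
  within-chain drift. Summaries (mean, 97.5% quantile across parameters)
  are reported for the β and γ blocks.
* **AUC** — Mann–Whitney with midranks; **Tjur R²** —
  mean(p|y=1) − mean(p|y=0); both undefined (NaN, never fabricated) for
  single-class species. **Gaussian R²** — 1 − SS_resid/SS_total against
  posterior-mean predictions, floored at 0 (not a squared correlation;
  stated here because conventions differ).
* **Variance partition** — per draw and species, each fixed group's
  contribution is the sample variance of its partial predictor with
  cross-group covariances split equally between the two groups involved
  (net-negative group totals are floored at zero before normalizing —
  rare, only under strong anti-correlation); random levels contribute
  Ω_jj. Proportions are normalized per species (rows sum to 1) and
  averaged over draws.
* **Trait-explained niche variance** — per draw and covariate,
  var_j(μ_kj)/var_j(β_kj) with μ the trait-regression mean, clipped to
  [0,1]; the overall summary is reported variance-weighted (default) and
  unweighted. *Known bias:* as a posterior quantity this is upward-biased
  at small species counts — β shrinks toward the trait mean (deflating
  the denominator) and with taxonomically clumped traits the trait
  regression absorbs part of the phylogenetic residual structure. The
  arithmetic is validated exactly against the generator's analytic ratio;
  the fitted value should be read as an upper-leaning estimate at desk
  scale.
* **Residual associations** — per draw, Ω = ΛᵀΛ normalized to a
  correlation (tiny jitter on zero diagonals); support is the fraction of
  draws positive; sign calls at ≥95% / ≤5% support (threshold
  configurable). Invariant to orthonormal rotation of the factors.
* **Coefficient support** — P(β > 0) per covariate × species with the
  same 95% call rule and per-covariate summaries.

## Regions of common profile

Samples are clustered in species-probability space (posterior-mean
predicted occurrence by default; a threshold-at-0.5 binary mode is
available) by best-of-starts k-means (k-means++, Lloyd). The number of
clusters is chosen over k = 2…10 by **majority vote over ten validity
indices**: Calinski–Harabasz (max), mean silhouette (max), Davies–Bouldin
(min), Dunn (max), C-index (min), McClain–Rao (min), Krzanowski–Lai
(max), Hartigan (first k with H(k) ≤ 10), Ball–Hall (largest successive
drop) and the gap statistic (first-SE rule, 50 uniform reference draws).
The majority-rule mechanism, not the exact index census, is the method; a
documented ten-index battery keeps it tractable and reproducible. Ties
break toward the smallest k (parsimony) and are noted in the report.

Profiles are characterized by per-species prevalence min-max scaled
across clusters (species constant across clusters map to 0.5 by
convention; raw prevalences always exported), expected richness (row sums
of probabilities, or integer richness on observed data), community-
weighted mean traits CWM_it = Σ_j P_ij t_jt / Σ_j P_ij (binary traits
give proportions; cell volume stays on the ln scale; zero-weight rows are
flagged NaN), per-cluster environment summaries with least-squares year
slopes, and decade-aggregated sample counts. Group contrasts use the
**Games–Howell** post hoc test (unequal variances): Welch t per pair,
Welch–Satterthwaite df, p from the studentized-range distribution with
k = number of groups; at k = 2 it reduces exactly to the two-sided Welch
t-test.

## The synthetic-data generator

The generator emulates the structure of a national lake-monitoring
dataset at desk scale and stores the generating parameters for recovery
tests. Defaults (the desk preset): 4 river basins × 3 watersheds × 4
sites, 10 years, each (site, year) sampled with probability 0.7 (~340
samples), 40 species on a (2,2,2,2,3) taxonomy, true ρ = 0.8, residual
niche scale 0.4, site factors with a 150 km spatial range. Basin centres
sit on a ~400 km grid, watersheds scatter 60 km around basins and sites
12 km around watersheds, so the nesting is reflected in distances.
Physico-chemical covariates combine basin/watershed/site intercepts
(spatial structure via nested random intercepts rather than a second GP —
cheaper, and sufficient to exercise the variance partition), a shared
year disturbance, configurable linear trends (positive for temperature,
colour, weakly for phosphorus; negative for N:P), and sampling noise;
bathymetry and land use are site-constant. Binary traits follow a
genus-level coherence draw (probability `trait_clumping`, default 0.7,
of the whole genus sharing one Bernoulli outcome); ln cell volume is
normal around family-level means. β is drawn exactly from the model's
matrix-normal prior around the trait regression, and communities from the
probit likelihood.

The **planted-profile mode** assigns each site to one of k profiles and
adds cluster × species probit offsets of ±3.5. At that magnitude a
species that differs between profiles is essentially always present in
one and absent in the other, which is what "strong separation" must mean
for an end-to-end recovery test: the profile signal has to dominate the
covariate- and factor-driven within-profile variation, and at smaller
offsets (±1.8) it demonstrably does not, even for oracle probabilities.

What the generator does *not* emulate: real taxonomies are unbalanced;
real covariates have skew, measurement error and missingness patterns
beyond lognormality; sampling effort varies systematically (not
Bernoulli); and real residual co-occurrence need not be low-rank.
Passing recovery tests therefore demonstrates the correctness of the
estimation machinery under the model's own assumptions, not robustness to
their violation.

## Problem sizes and schedules

Desk-scale fits use 2 chains × 1,500 iterations (500 burn-in, thin 2 →
1,000 retained draws) — a few seconds per chain at ~5 ms per sweep — and
the recovery studies use 1 chain × 800–1,000 iterations per replicate.
These sizes give stable posteriors for the desk-scale data (psrf ≈ 1.02
for β) while keeping the full pipeline, test suite and acceptance script
in the minutes range. The published-schedule arithmetic
(37,500/12,500/thin 100 × 4 chains → 250 per chain, 1,000 total) is kept
as an exact, tested invariant of the retention logic.

## Numerical choices and degenerate inputs

Truncated-normal draws use the inverse-CDF with probabilities clipped to
[1e−13, 1−1e−13] (tail-safe up to |z| ≈ 7). Eigenvalues of C are floored
at 1e−8 (the taxonomy construction guarantees ≥ 0.2). Spatial kernels get
1e−8 jitter before factorization. Zero-variance covariates, single-class
species metrics, empty clusters, zero-weight CWM rows, zero-variance
Games–Howell groups and inconsistent taxonomies all fail (or flag) with
named errors rather than silently producing numbers. Binary-trait
imputation takes the modal value at the nearest ascending taxonomic rank
with data, ties broken toward 0 (absence of the ability); cell volume
takes the family mean, then order, class, global. The boundary species at
an exact cumulative-biomass cut is included, as are its ties.

## Known limitations

Single-threaded by design (results are independent of the `--threads`
flag, which exists for interface compatibility). No abundance families,
no spatio-temporal interaction kernels, no cross-validation (explanatory,
not predictive, power is reported), no adaptive factor counts, no
nearest-neighbour GP approximations beyond the exact-GP guard rail, and
no multivariate psrf. The trait-variance share is upward-biased at small
S (above). k-means majority selection on *unplanted* desk data tends to
high k — smooth site-effect continua fragment into many small clusters —
which is a property of the data-generating continuum, not a defect of the
selection rule.
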
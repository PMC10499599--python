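# Methods

This note documents the models, numerical choices and limitations of the
package, in the order the pipeline runs them.

## Synthetic cohort generator

The generator (`gutmet.simulate`) emulates the statistical structure the
analyses assume, not any particular real cohort. One seeded NumPy generator
drives everything, so a fixed `SimConfig` is bitwise reproducible.

**Latent phenotype.** Each participant has a standard-normal latent IR
factor. Insulin and glucose are derived by monotone maps from the
structural IR score (glucose = 85 + 20·logistic(score); insulin =
405·HOMA/glucose), so HOMA-IR recomputed from the printed formula equals
the structural value exactly and is rank-faithful to the latent factor up
to the planted mediation and noise terms. Age ~ N(50, 10) clipped to
[20, 80]; sex is Bernoulli(½) coded 0 = male, 1 = female.

**Metabolome.** 120 metabolites in 4 planted co-abundance blocks of 30.
Block b has a factor f_b = e_b·IR + m_b·g_b + residual, with IR loadings
e = (0.5, −0.4, 0.3, 0) and a coupling m = 0.3 of the first two blocks to
the matching genus-group factors (so a genuine microbe–metabolite signal
exists). Member log-abundances load √0.7 on their block factor, giving a
within-block correlation ≈ 0.7 on the log scale; concentrations are
exp(μ_j + 0.6·z). The loadings are deliberately moderate: block identity is
carried by the block factor, and cross-block correlations stay ≲ 0.3 so
"distinct blocks" means what it says. Each column is censored to zero below
its `detection_limit_quantile` (default 0.05) quantile — the zeros are data
(below the limit of detection), not missing. Lognormality is an assumption
of the generator; the field has no agreed noise model for GC–MS metabolite
concentrations.

**Genus table.** Logistic-normal: log-scale factors for 4 groups of 8
genera (within-group correlation 0.7, IR loadings 0.6/−0.6/0.3/0), the
remaining genera independent; rows are softmax-normalised so every sample
sums to 1 (±1e-12). Note the softmax induces the usual compositional
negative dependence on top of the planted structure — which is exactly what
the permutation-renormalisation null is for.

**KO table.** K = G·M with a fixed sparse lognormal-weighted incidence
matrix M (15 % density), multiplicative lognormal measurement noise, rows
renormalised. A toy many-to-many KO→pathway map (20 pathways, 1–3 per KO)
is emitted alongside.

**Cytokines.** Planted mediator cytokines are linear in the z-scored
observed metabolite (slope a) plus small age/sex effects and Gaussian noise
scaled so the total variance is ≈ 1; non-mediators load 0.3 on latent IR.
Values are mapped to a positive scale (exp(x/2)) and assay range limits are
mimicked: below the 0.5 % quantile → 0, above the 99.5 % quantile → the
analyte maximum. The limits are kept at the far tails so the planted linear
effects survive the round trip through log-transformation (the recovery
tests regress the log10-scaled cytokine on the scaled metabolite and ask
for the planted a within 5 %).

**Markers.** HOMA-IR, BMI, TG and HDL-C are linear in latent IR plus the
planted c′·metabolite + b·cytokine terms plus noise; TG and HDL carry a
measurement-scale multiplier (25 and 10 mg dl⁻¹ per score unit), and the
truth object records b and c′ on the marker's own scale.

**What the generator does not emulate:** dietary and drug covariates, batch
effects, longitudinal structure, phylogenetic correlation among genera,
zero-inflation beyond simple detection-limit censoring, and non-linear
exposure–mediator relationships. Passing recovery tests therefore shows the
pipeline is correct under its own assumptions, not that those assumptions
hold in any real cohort.

## Co-abundance clustering

`bicor` uses 9-MAD biweight midcorrelation; a vector with zero MAD falls
back to Pearson terms (a fully constant vector is an error). The primary
stage builds the unsigned soft-threshold adjacency |bicor|^β and the
topological overlap matrix, then cuts the average-linkage dendrogram of
1 − TOM. The secondary stage cuts 1 − bicor directly for the features the
first stage left unassigned, with its own minimum cluster size.

The exact branch-pruning variant of the tree cut is this package's own:
a static cut at `cut_height` followed by recursive splitting of each
branch wherever both children reach `min_cluster_size` and the merge
height sits above the children by a relative gap of at least
{0.15, 0.12, 0.09, 0.06, 0.03} for deep-split levels 0–4 (higher level =
more sensitive). There is no PAM assignment stage. Clusters smaller than
the minimum are labelled 0 (unassigned); labels are renumbered by
decreasing size. With the default parameters (β = 12, min size 3, deep
split 4, cut height 0.9999) the behaviour matches the intended regime:
under pure noise the TOM dissimilarities sit within ~1e-7 of 1, above the
cut height, so everything stays unassigned; planted blocks merge far below
it and survive intact.

Eigen-metabolites are the first principal component of the
column-standardised member submatrix, sign-anchored to correlate
non-negatively with the mean member profile, and unit-variance.
Cluster merging is iterative: the pair of clusters with the highest
eigen-metabolite bicor above 0.8 merges first (ties broken by larger
correlation, then smaller label), the combined eigen-metabolite is
recomputed, and the loop repeats. Merging on eigen-metabolites (rather
than mean profiles) is a documented choice; the merge log records every
step so the alternative can be audited.

Analyses cluster log10-scaled (then z-scored) metabolite concentrations;
the scaling is monotone per feature, and bicor is invariant to the affine
part.

## Association statistics

**Rank regression** minimises Jaeckel's dispersion D(β) = Σ a(R(e_i))·e_i
with Wilcoxon scores a(i) = √12·(i/(n+1) − ½), by Powell search polished
with Nelder–Mead from the OLS start (D is convex and piecewise-linear, so
this lands on the minimising flat to ≤ 1e-8 in the tests). The intercept is
the median residual. Inference uses the scale parameter
τ = 1/(√12·∫f²), with ∫f² estimated by a leave-one-out Gaussian-kernel
average of the residual density (Silverman bandwidth) and a √(n/(n−p−1))
degrees-of-freedom correction; Wald t-tests with df = n − p − 1.

**Partial Spearman** rank-transforms x, y and all covariates (average
ranks) and computes the partial Pearson correlation either by
residualising on the ranked covariates or from the precision matrix — the
two agree to 1e-10 and the empty-covariate case reduces exactly to
Spearman's rho. p-values use the t-approximation with df = n − 2 − |Z|.

**Marker screen** is the two-stage filter: gamma-family GLM of HOMA-IR on
marker + age + sex (log link by default — chosen for numerical stability;
the inverse link is available), BH across markers, then logistic IR(1)/IS(0)
with intermediates excluded on the stage-1 survivors, BH again.

BH adjustment is the step-up procedure with enforced monotonicity, applied
within each analysis table (one family per results table). Group tests use
tie-corrected Kruskal–Wallis with Dunn's z post hocs (BH), two-sided
rank-sum tests, and Fisher's exact test (hypergeometric for 2×2; seeded
Monte Carlo with fixed margins for r×c).

## Networks

`reboot_correlations` computes observed pairwise Spearman correlations on
the renormalised composition, a permutation null (each feature permuted
independently across samples, rows renormalised — preserving the closure
constraint, destroying dependence) and a bootstrap distribution (row
resamples, renormalised). All correlations are Fisher-z transformed and the
two-sided p-value is the normal tail of
(mean_boot − mean_perm) / sd_perm. This construction is calibrated: under
independent lognormal compositions the pre-adjustment type-I error at
α = 0.05 measures ≈ 0.05 (the acceptance band is [0.03, 0.07]); dividing
instead by the pooled spread of both distributions would be conservative by
roughly an order of magnitude. Defaults are 1000 permutations and 1000
bootstraps.

Microbial groups are the connected components of the positive significant
edge subgraph; genera with no positive significant edge are
"miscellaneous" (group 0). A config override can move a named genus into
another genus's group, mirroring curated reassignments; applications are
logged. Participant clustering is agglomerative Ward (classic Ward update
on squared Euclidean distances of the untransformed relative abundances —
an arcsine-sqrt pre-transform is available), cut at k = 4, clusters
renumbered by ascending IR proportion so cluster 1 is the lowest-IR
reference. The cross-omics network drops nodes with zero IS median from
sizing (size ratio undefined) but keeps them in the topology.

## Pathway scores

Per-KO signs come from BH-filtered Spearman (vs a numeric target) or
cluster-vs-rest rank-sum tests on arcsine-sqrt-transformed KO abundances.
The propagation denominator counts the pathway's KOs present in the
analysed table — the score is then a statement about the detected gene
families — with a switch for full-database denominators.

## Prediction

mRMR uses the Gaussian mutual-information surrogate −½·ln(1−ρ²) with
Spearman ρ, making selection invariant to monotone transforms; features
are square-root transformed first by convention. Forests use 500 trees by
default; the tenfold CV step tunes only the per-split feature count. AUC is
the rank (Mann–Whitney) formulation on held-out stratified 3:1 splits,
repeated with distinct seeds; distributions, not single numbers, are
reported. Explained variance uses the printed R² definition on held-out 4:1
splits with negatives clipped to zero. Null calibration draws a fresh label
permutation per repeat — a single fixed permutation retains dataset-level
chance association and does not average to ½.

## Mediation

Exposure and mediator are scaled, so effects are per SD. Both models are
ordinary least squares (Gaussian GLM); for these linear models the ACME
point estimate equals a·b and total = ACME + ADE to machine precision,
identities the tests assert at 1e-10 and 1e-8. The bootstrap resamples
whole rows and refits both models jointly per resample; intervals are
percentile and the two-sided p-value is twice the smaller tail fraction,
floored at 2/n_boot. The proportion mediated is ACME/total, reported as
undefined below a 1e-8 total-effect floor, and can fall outside [0, 1]
when ACME and ADE have opposite signs (flagged, not suppressed). n_boot
defaults to 1000; collinear exposure/mediator (|r| > 0.999) is an error.

## Problem sizes

The test suite and acceptance script scale their Monte Carlo runs to
desk-size: 10 cohorts of n = 300 for CAG recovery, 5 datasets of 30
features × 200 samples with 1000 permutations + 1000 bootstraps
(≈ 2175 pairs) for the network calibration, 100 simulations at n = 500
with 300 bootstrap resamples for mediation coverage, 20 seeds of 8-triplet
null tables for FDR behaviour, and 100-tree untuned forests for the AUC
calibrations. These sizes were chosen as the smallest at which the checked
properties are stable across seeds.

## Known limitations

* The tree-cut variant is parameter-compatible with, but not an exact
  re-implementation of, the established hybrid branch-pruning algorithm;
  on sharply separated modules they agree, on marginal structure they may
  differ.
* The permutation-renormalisation p-value recipe is one defensible
  construction of a compositionality-corrected test; other implementations
  of the idea differ in how they combine the bootstrap and permutation
  distributions, and their p-values need not match ours numerically.
* Mediation results are "in silico" associations under sequential
  ignorability; no sensitivity analysis is provided, and none of the
  pipeline's outputs establish causality in observational data.
* Fisher's exact test for tables larger than 2×2 is Monte Carlo, so its
  p-values carry simulation error of order 1/√n_mc.
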
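# gutmet

Multi-omics integration of faecal carbohydrate metabolites, gut microbiota
and host insulin resistance (IR), packaged as a tested, reusable analysis
pipeline and exercised end-to-end on a synthetic cohort with planted
structure.

The package is aimed at microbiome/metabolome researchers who want the full
statistical chain of this kind of cohort study — co-abundance module
detection, compositionality-aware correlation networks, covariate-adjusted
cross-omics networks, KO→pathway scoring, prediction benchmarking and causal
mediation — as importable, seedable functions rather than a pile of
one-off scripts.

## What it computes

**Phenotypes.** HOMA-IR = insulin (μU ml⁻¹) × glucose (mg dl⁻¹) / 405;
IR is HOMA-IR ≥ 2.5, normal insulin sensitivity (IS) is ≤ 1.6. The
metabolic-syndrome call is waist-gated (≥ 85 cm men / ≥ 90 cm women) and
counts three abnormality groups (TG ≥ 150 and/or HDL-C < 40; SBP ≥ 130
and/or DBP ≥ 85; FBG ≥ 110 mg dl⁻¹): ≥ 2 → MetS, exactly 1 → pre-MetS.

**Co-abundance groups (CAGs).** Metabolites detected in > 75 % of samples
are clustered in two stages: (1) biweight midcorrelation (bicor) →
soft-threshold adjacency a_ij = |bicor|^β (β = 12) → topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij) → adaptive cut of
the average-linkage tree of 1 − TOM (min size 3, deep split 4, cut height
0.9999, no PAM stage); (2) leftovers re-clustered on 1 − bicor. Each CAG is
summarised by its first principal component (eigen-metabolite); clusters
with eigen bicor > 0.8 are merged.

**Networks.** Genus–genus edges use a compositionality-corrected null:
features are independently permuted and every sample renormalised to sum 1,
so the spurious negative dependence of closed compositions is built into
the reference distribution. Positive significant edges define co-abundance
microbial groups (connected components). The cross-omics network uses
partial Spearman correlations adjusted for age, sex, BMI and fasting
glucose, BH-filtered at p_adj < 0.05, with node sizes = median(IR)/median(IS).

**Pathway scores.** Each KO significantly positively (negatively)
associated with a target adds +1 (−1) to every pathway containing it; a
pathway's score is the signed sum divided by its number of KOs (∈ [−1, 1]).

**Prediction.** Greedy mRMR feature selection (mutual-information surrogate
−½·ln(1−ρ²) with Spearman ρ) feeding random forests, AUC on held-out 3:1
splits across feature counts 5–50; cytokine explained variance R² =
1 − Σ(test−pred)² / Σ(test−mean)² on 4:1 splits, negatives reported as 0.

**Mediation.** For screened (metabolite, cytokine, marker) triplets, linear
mediator (cytokine ~ metabolite + age + sex) and outcome
(marker ~ metabolite + age + sex + cytokine) models give
ACME = a·b, ADE, total = ACME + ADE; inference by nonparametric bootstrap
(rows resampled, both models refit) with BH over all triplets.

Because the original cohort data are not redistributable, the
`gutmet.simulate` module generates a synthetic cohort with the same
statistical shapes (compositional genus table with planted groups, censored
lognormal metabolome with planted blocks tied to a latent IR factor, KO
abundances driven by the genera, cytokines as planted linear mediators) and
a truth object for recovery tests. See `docs/methods.md`.

## Worked example

```
$ python analysis/01_simulate_cohort.py
cohort: 300 participants, layers {'metabolite': 120, 'genus': 60, 'ko': 150, 'cytokine': 10}
IR classes: {'IS': 132, 'IR': 89, 'intermediate': 79}
median HOMA-IR: 1.78

$ python analysis/02_cag_clustering.py
prevalence filter (>75% detected): kept 120 of 120 metabolites
4 CAGs (0 metabolites unassigned); ARI vs planted blocks = 1.000

$ python analysis/03_cag_associations.py
 cag_id      coef            p        p_adj
      1  0.889112 2.608361e-43 1.043344e-42
      2 -0.503088 7.303393e-13 1.460679e-12
      3  0.208630 3.867069e-03 5.156092e-03
      4  0.099813 1.652636e-01 1.652636e-01
3 of 4 CAGs associated with HOMA-IR at p_adj < 0.05
```

The four recovered CAGs are exactly the four planted metabolite blocks; the
rank-regression coefficients mirror the planted IR loadings (+0.5, −0.4,
+0.3, 0): blocks coupled to the latent IR factor come out associated with
HOMA-IR at the planted signs, and the unloaded block does not. The later
drivers (`04`–`07`) build the genus network and participant clusters, score
pathways per cluster, benchmark per-layer AUC (median held-out AUC ≈ 0.84
for the metabolite layer vs ≈ 0.79 for genera at k = 10), and run the
mediation cascade; each prints what it found and writes its tables under
`results/analysis/`.

The same chain is available as a CLI:

```
gutmet run --seed 1 --out-dir results/run1
```

which executes simulate → filter → cag → assoc → micronet → enrich →
predict → mediate → report and is bitwise-reproducible for a fixed seed.

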
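# Methods

This note documents the models and procedures implemented in `cadomics`, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Cohort model

Subjects belong to one of three ordered clinical groups — control, high-risk,
CAD — observed on two omics layers: a biallelic SNP matrix (calls hom-ref /
het / hom-alt / missing with per-SNP ref/alt metadata, 1-based VCF
coordinates throughout) and a panel of non-negative metabolite concentrations
(µM) with missing values and occasional exact zeros. A phenotype table
carries sex, age, clinical covariates and medication flags.

## Metabolite normalization

Before clustering, each metabolite is processed in a fixed order: (1) missing
values imputed with the median of its observed values; (2) exact zeros
replaced with 0.001 so the logarithm is defined; (3) division by the
metabolite's median; (4) log₂. The median in step 3 is recomputed **after**
steps 1–2, so the divisor describes the matrix actually transformed; the
ordering of the zero substitution versus the median computation is a design
choice (the steps are individually standard but their ordering is not forced
by anything). The transform is scale-equivariant for positive and missing
values — multiplying a metabolite by c > 0 leaves the output unchanged,
because the median scales with c — but not for exact zeros, whose 0.001
replacement is absolute.

For discriminant analysis the panel is instead centered and divided by the
per-metabolite sample standard deviation (ddof = 1). Centering is applied in
addition to the variance scaling because it is universal OPLS-DA practice and
required for a meaningful Hotelling ellipse; a zero-variance metabolite is an
error, named in the message.

## SNP quality control and encoding

Three filters run sequentially — minor allele frequency < 0.01 (observed-call
allele counts over the whole cohort), Hardy–Weinberg disequilibrium in the
control subjects (1-df goodness-of-fit χ² on genotype counts against
n·p², n·2pq, n·q²; removal at p < 10⁻⁶), missing rate > 10% — and a SNP
failing several filters is attributed to the first failing one, so the
removal counts always sum to the input count. The χ² test (rather than an
exact test) matches the long-standing array-QC default and is insensitive to
the choice at array-scale counts and a 10⁻⁶ threshold.

Retained genotypes are encoded 0 / 0.5 / 1 (hom-ref / het / hom-alt). A
missing cell is imputed with the per-SNP median of the observed encoded
values snapped to the nearest legal code; an exact tie (median 0.25 or 0.75)
snaps to 0.5, the least-committal code. "Median-allele" imputation is
genotype-level, not allele-level — the alternative reading would almost
always produce the same code and cannot represent 0.5.

## Clustering and stability

Both layers are clustered with Euclidean k-means (k-means++ seeding, best of
25 restarts by inertia; restarts make the solution effectively deterministic
on separable data). The elbow scan fits each k in a range and selects the
maximal-curvature point by second differences
d²(k) = I(k−1) − 2·I(k) + I(k+1); when the best curvature is below 15% of the
total inertia drop the curve is flagged `weak_elbow` rather than silently
trusted (on a single Gaussian blob the ratio measures ≈ 0.08, on five
well-separated clusters ≈ 0.3; the threshold sits between). A forced k is
always accepted.

Stability between two partitions is the per-cluster set Jaccard
|A∩B| / |A∪B| after maximum-weight bipartite matching (Hungarian algorithm on
the pairwise Jaccard matrix); the minimum over matched pairs is the headline
statistic, with ≥ 0.80 the conventional bar for a reproducible clustering.
"Normalized Jaccard" admits several definitions; per-matched-cluster set
Jaccard was chosen because it is the one that is per-cluster, bounded in
[0, 1] and symmetric. Heatmap export orders subjects by group
(control < high-risk < CAD), then sex (female first), then ascending age,
with a stable sort.

## Association testing

Each SNP gets an allelic 2×2 test: subjects contribute two alleles, missing
calls are excluded, and the Pearson χ² (1 df, no continuity correction) is
computed with the odds ratio ad/bc (Haldane–Anscombe +0.5 when a cell is
empty) and a 95% Wald CI. The allelic rather than genotypic contingency
structure is the GWAS default and yields the single OR that the candidate
rule needs. Bonferroni adjustment uses the number of SNPs actually tested,
recomputed per run. Candidate SNPs require adjusted p < 10⁻⁷ and OR > 1 or
< 0.5 — the asymmetric rule is applied literally as published; a symmetric
(> 2 or < 0.5) option exists but is off by default. Mixed-model machinery
(GRM, saddlepoint) is out of scope; a covariate-adjusted logistic regression
(Wald p) is available alongside the χ² for users who want fixed-effects
covariate control, and reports make clear which test produced which number.

The two-proportion test is the pooled-variance z-test, two-sided. Manhattan
tables cap p-value underflow at a configurable floor (10⁻³⁰⁰) and flag
capped rows; chromosomes sort numerically with X/Y/MT last.

## Haplotype rules and subtypes

The five-SNP *LPCAT1* panel (rs36993, rs9799949, rs10475026, rs1032751,
rs1032752) is classified at the diplotype level: haplotype 3 requires
hom-alt at all five; haplotype 2 requires hom-ref at rs1032752, rs1032751,
rs10475026 and rs9799949 together with hom-alt at rs36993; the remaining 241
of 3⁵ = 243 complete combinations are haplotype 1 (wild type). A missing
call anywhere in the panel yields haplotype 1 with a missing-data flag — the
conservative direction, defaulting to wild type rather than inventing a
variant class.

Subtype rules map a (metabolomic cluster, genetic cluster set) pair to a
named subtype. Because cluster labels are arbitrary artifacts of a fit, the
rules are data, not constants: `derive_subtype_rules` selects, for each
targeted metabolomic cluster, the genetic clusters whose standardized Pearson
residuals in the cross-tab exceed 2, with manual override. Enrichment
p-values come from 2×2 collapses (in/out of each margin) because the
scientific claims are pairwise; an omnibus Pearson χ² on the full table is
also available.

## OPLS-DA

A NIPALS-style estimator for one predictive component plus `n_ortho`
orthogonal components, for a two-class response encoded as a single centered
column. Orthogonal components capture systematic X-variation uncorrelated
with y (each orthogonal score has exactly zero sample correlation with the
response, by construction); with `n_ortho = 0` the model reduces exactly to
1-component PLS regression and reproduces scikit-learn's `PLSRegression`
scores and predictions to machine precision, which is used as an independent
cross-check in the tests. R²Y is the fitted explained variance of the
centered response; Q² = 1 − PRESS/SSY from stratified 7-fold CV (fold
assignment is seeded; class proportions preserved; centering refit within
each training fold). The number of orthogonal components can be selected
automatically: components are added while Q² improves by more than 0.01, a
SIMCA-like heuristic. Under label permutation Q² is expected at or below
zero, and the permutation helper reports the null distribution. The 95%
Hotelling T² ellipse in 2-D score space uses
T²crit = 2(n−1)/(n−2) · F(0.95; 2, n−2), with semi-axes √(λᵢ·T²crit) from
the score covariance eigenvalues.

## Consensus feature selection and prediction

Per iteration (default B = 100): a stratified 80:20 resplit of the data
("bootstrapped replications" are implemented as repeated resplits, which is
what the per-iteration random train/validation split describes; a
with-replacement mode is deliberately not the default). On the training
split, an L1-penalized logistic regression — penalty chosen by internal
5-fold CV with the 1-SE rule (smallest C within one standard error of the
best mean AUC) — defines the selected set S_L and the budget k = |S_L|; a
random forest (impurity importance, 100 trees) and a linear SVM (absolute
primal weights; features standardized on the training split) each contribute
their top-k. If k = 0 the iteration contributes nothing and is logged.
Cumulative counts over iterations and methods rank the features; ties break
by higher LASSO count, then lexical name, so runs are exactly reproducible.
The top 16 feed the final models.

Evaluation is stratified holdout (80:20) or stratified 10-fold CV, with AUC,
accuracy, sensitivity, specificity, AUC-PR, Brier score and calibration
slope (the coefficient of a logistic refit of outcomes on predicted
log-odds). The internal AUC cross-check — Mann–Whitney rank statistic versus
trapezoidal ROC integration — agrees to 10⁻¹⁰ on arbitrary prediction
vectors. The XGBoost search enumerates the full 75-combination grid
(eta ∈ {0.1, 0.3, 0.5, 0.7, 0.9}, max_depth ∈ {6, 12, 29},
min_child_weight ∈ {1, 2, 4, 8, 10}) by validation AUC on an inner split.

Adjusted odds ratios come from a logistic model with backward elimination:
at each step the feature whose removal most improves the information
criterion is dropped, until no removal helps. The criterion defaults to BIC;
with an AIC penalty the implied per-feature retention threshold (~p < 0.16)
keeps one to four pure-noise features out of ten at n = 600, whereas BIC's
stricter penalty eliminates essentially all of them, which matches the
intended "retain only the clearly informative features" behavior of the
procedure. AIC remains available via `criterion="aic"`. Quasi-separation
(|β| > 15 or SE > 50) flags the row and suppresses the CI.

Robustness experiments rebalance only the training side of a held-out split,
so validation subjects are never reused: 1:1 subsampling draws controls
without replacement to the case count; matched sampling pairs each case with
its nearest unused control (standardized age distance, exact sex and
optionally statin, age caliper 5 years, greedy in seeded random order).
Cases with no admissible control are dropped with a warning — the behavior
of MatchIt, whose workflow this mirrors — and only an empty matched set is
an error. Interaction features add statin × metabolite products with a
`statin_x_<name>` convention. Probability recalibration (Platt or isotonic)
is fitted on a held-out half and evaluated on the other half; the
reliability curve uses ten equal-frequency bins.

## Synthetic cohort

The generator plants exactly the structure the pipeline is meant to find.

* **Groups** — sizes default to 271/363/147 (control/high-risk/CAD). Age,
  BMI, sex and six medication flags are drawn from group-specific
  normal/Bernoulli distributions with the study cohort's descriptive
  statistics as defaults; they are cosmetic except where matched sampling
  uses them.
* **Haplotype block** — each subject draws a diplotype class directly:
  haplotype 3 with the group's target frequency (defaults 0.1333 / 0.1928 /
  0.2721), haplotype 2 with a configurable (not asserted) group frequency,
  otherwise per-SNP HWE genotypes redrawn on collision with a planted
  pattern. Class-level planting guarantees the rule-based classes exist at
  controllable frequency without modelling recombination; the empirical
  haplotype-3 frequency is unbiased for the target with binomial sampling
  error.
* **Latent clusters** — each subject has a genetic latent cluster (uniform
  over 5) and a metabolomic latent cluster that copies it with probability
  `coupling_strength` (else uniform). A configurable subset of SNPs draws
  its allele frequency per cluster from a clipped Beta(0.5, 0.5), giving the
  genetic layer a recoverable cluster signal; remaining SNPs are null with
  independent MAFs uniform on [0.05, 0.5]. Metabolite cluster structure is a
  per-(metabolite, cluster) log-scale offset of ±effect_size/2.
* **Metabolites** — log-normal (multiplicative) noise, since concentrations
  are positive and later log-transformed: log-value = per-metabolite
  baseline + cluster offset + group shift + N(0, 1). The first
  `n_informative_features` metabolites shift by `effect_size` (in noise-sd
  units) per control→high-risk→CAD step; all others are null. Missing values
  and exact zeros are injected at configured rates; genotype missingness is
  injected outside the haplotype block (the five-SNP panel stays complete so
  the planted diplotype frequencies are exactly recoverable).
* **Streams** — one root seed spawns named child generators per stage, so
  changing the SNP count does not perturb the metabolite draws and identical
  config+seed is bit-identical.

What the generator does **not** emulate: linkage disequilibrium beyond the
single block, population structure and relatedness, medication effects on
metabolite levels (the statin flag is informative only through its group
frequencies), genotyping batch effects, and HWE-consistency of the planted
structures — the diplotype-level block and the cluster-dependent allele
frequencies (a deliberate Wahlund-like effect) both violate HWE, so the QC
filter removes part of them at large n. Passing tests on this cohort show
the machinery recovers planted structure of the assumed form; they do not
certify performance on real arrays with LD, stratification or batch
artifacts.

## Problem sizes and numerics

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the statistical claims are stable:
cluster-stability and recovery checks use ~500–6,000 subjects with 143
metabolites; association calibration uses 2,000 null SNPs at 500 cases / 500
controls over five seeds; consensus-selection recovery uses 20 replicates of
B = 100 iterations at n = 600 with 50 features. Floating-point comparisons
use absolute tolerances of 10⁻⁹–10⁻¹² for closed-form identities and
binomial/Monte-Carlo bands (3 SE, or ±0.01 on a rate) for stochastic
checks. Degenerate inputs fail loudly by design: single-class responses,
zero-variance features, empty control sets, monomorphic SNPs (p = 1 with an
undefined-OR flag), subject-index mismatches (no silent intersection).

## Interfaces

Genotypes: VCF 4.2 (GT only; biallelic records; phase separators ignored;
`./.` = missing) read via cyvcf2, plus a TSV mirror. Tables: TSV/CSV with a
header row; empty cells are missing, never zero. Results serialize to TSV
with deterministic row order. Configs are YAML. There is no shell CLI: the
library functions and `scripts/acceptance.py` are the interface.

## Known limitations

* The HWE filter uses the asymptotic χ², which is anticonservative at very
  small control counts; an exact test is not implemented.
* OPLS-DA supports two classes only (the discriminant analyses here are
  pairwise); multi-class would require a different response encoding.
* The SVM selection score uses the primal weights of a linear kernel;
  kernel SVMs have no comparable per-feature weight and are not used for
  selection.
* Greedy nearest-neighbour matching is order-dependent (seeded) and not
  optimal; with scarce controls it drops cases rather than relaxing the
  caliper.
* The elbow flag is a heuristic; on data with nested or unequal-variance
  clusters the second-difference rule can prefer a smaller k than visual
  inspection would.
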
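# Methods

This note documents the statistical procedures implemented in `bsewas`,
the assumptions behind them, the synthetic-data generator used to test
them, and the numerical choices that matter for reproducibility.

## Site quality control

Analysis is restricted to autosomal CpGs (chr1–chr22; other labels are
dropped with a warning). Sites with no variability — every covered read
methylated, or every read unmethylated, summed over all samples — carry no
information for a binomial model and are removed. The depth filter keeps a
site when at least `min_samples` samples reach depth `N ≥ min_depth`
(defaults 30 samples at ≥ 15×; a relaxed ≥ 10× mode suits shallower
libraries). Depth is always total reads `N`, never methylated reads `M`.
The three filters commute, so the final site set does not depend on their
order; the `FilterReport` records the count after each stage.

Coverage summaries report per-site mean and median depth across samples
and the dataset-level fractions below cutoffs (null median, mean < 10×).
All printed percentages use one-decimal **half-up** rounding via
`decimal.Decimal`, so 36.05 → 36.1 regardless of binary-float artifacts.

## Per-CpG binomial regression

The EWAS model treats methylated reads as grouped binomial with depth as
trials — the "weighted" regression sense: a proportion response weighted
by read depth maximizes the identical likelihood. Fits use IRLS
(statsmodels GLM, binomial family, logit link), with per-site exclusion of
samples at `N = 0`, a 50-iteration cap and 1e-8 relative tolerance.
Sites whose design is rank-deficient after exclusions are flagged
non-estimable; fits with exploding coefficients or standard errors
(|β| > 100, a symptom of complete separation) are flagged non-converged.
Both classes are excluded from the FDR computation and counted in the run
manifest.

Covariate coding is fixed and logged: sex female = 1; smoking is
current = 1 vs everything else = 0, with "missing" mapped to 0 and warned
about (an explicit missing-indicator column is available; cohorts of this
kind often carry ~35–40% missing smoking status, and complete-case
analysis would be far more damaging than the conservative recode). The
cell-composition covariate is the first right-singular direction of the
mean-centered 5-column proportion matrix, sign-anchored so the neutrophil
loading is positive; using one component instead of four proportion
columns keeps small-cohort fits stable while capturing the dominant
granulocyte/lymphocyte axis (typically > 90% of variance).

The phenotype coefficient's Wald z-test is the default site statistic (the
standard summary of a binomial GLM fit); q-values come from either
Benjamini–Hochberg or Storey's estimator. The Storey π̂0 uses the λ-grid
0.05, 0.10, …, 0.95 with a cubic smoothing spline evaluated at λ = 0.95,
clipped to (0, 1]. DMC calling is strict: q < 0.01, not ≤.

Known limitation: the pure binomial likelihood understates the variance of
methylation proportions whenever sources beyond sampling noise act at a
site (notably strong cis genetic effects). Under such over-dispersion the
Wald p-values are anti-conservative — the test suite demonstrates this on
beta-binomial nulls — and the genetic adjustment below, not a dispersion
model, is the implemented remedy.

## DMR calling

Two same-direction DMCs within 200 bp (inclusive) are contiguous; maximal
runs of ≥ 3 contiguous DMCs form a region spanning the first to last
member position. The two directions are merged independently, so an
interleaved opposite-direction DMC does not break a run. Only maximal
runs are emitted; the caller never splits a run into sub-regions. The
caller is verified against brute-force maximal-run enumeration on random
site sets.

## cis-meQTL scan

SNP QC keeps well-imputed common variants: INFO > 0.4 and MAF > 0.05,
both strict; multiallelic records and any variants sharing a basepair
coordinate or an ID are removed (both members of a clash). Each retained
SNP is paired with every same-chromosome CpG within 250,000 bp, boundary
inclusive — the inclusive reading is documented so results are bit-for-bit
reproducible.

Each pair is tested by OLS of `y = arcsin(√(M/N))` on dosage plus the four
EWAS nuisance covariates (the identical PC1 scores are reused). The
arcsine transform stabilizes binomial variance but deliberately ignores
read depth — a known power loss accepted for the speed of a linear scan.
Cells with `N = 0` are missing and deleted pairwise per site; pairs with a
constant dosage or fewer usable samples than coefficients + 1 are skipped
and logged. q-values are computed once over the full pair universe (a
single FDR scale, not per SNP or per CpG); `q < 0.01` flags a cis-meQTL.

## Adaptive-lasso genetic adjustment

For each DMC with candidate cis-meQTLs, the penalized grouped-binomial
objective

```
-(1/W)·loglik(β) + λ · Σ_j pf_j·|β_j| ,   W = Σ_i N_i
```

is minimized by IRLS with an inner cyclic coordinate-descent sweep
(soft-thresholding; numba-compiled). The intercept, phenotype and
environmental covariates carry `pf = 0` (never penalized); each
standardized SNP dosage column j carries the adaptive weight
`pf_j = 1/|β̃_j|^γ` with γ = 1, where `β̃_j` is the SNP coefficient from an
unpenalized base-plus-one-SNP marginal fit. Zero or failed marginal fits
get a capped weight of 1e6. Weights are normalized to mean 1 so the λ
grid (50 values, geometric from the smallest all-zero λ down to 1e-3 of
it) is comparable across folds.

λ is chosen by five-fold cross-validation, folds stratified by phenotype
and drawn from the run seed, scoring held-out binomial deviance per unit
read weight; the selected λ is the largest one within one standard error
of the CV minimum. Crucially, the adaptive weights are **recomputed
inside each training fold**: weights estimated on the full data would
leak test-fold information into the CV curve and inflate null selection
(observed directly during development as spurious CV minima at small λ).
With fold-wise weights, null candidate sets yield empty selections in
~90% of replicates while a causal SNP of effect 1.0 logit/dosage is
selected essentially always at n = 100.

SNPs with non-zero coefficients at the 1-SE λ enter an unpenalized refit
(exactly collinear selections are dropped in selection order until full
rank). Empty selections return the unadjusted fit unchanged. The refit's
phenotype Wald p is compared against a fixed epigenome-wide threshold of
3×10⁻⁵ — the p-value scale equivalent of FDR 0.01 over a multi-million-CpG
universe; `p_threshold_for_q` reproduces that conversion as a diagnostic.
gDMC calling is strict (<), non-converged refits are excluded, and gDMRs
follow from the ordinary region rule applied to gDMCs. AIC and BIC of the
model before and after adjustment are recorded per site
(`AIC = 2k − 2ℓ̂`, `BIC = k·ln(n_obs) − 2ℓ̂`).

## Region-set permutation tests

Set B is held fixed; set A is replaced by uniform without-replacement
resamples of size |A| from the universe of sites tested in both analyses
(a both-sets randomization mode exists behind a flag but is not the
default, matching the semantics of resampling-based randomization
strategies). Statistics: exact-position overlap count (upper tail) and
mean distance from each A site to the nearest B site on the same
chromosome (lower tail, directional A→B; A sites on chromosomes without B
sites are excluded with a logged count). The empirical p uses the
plus-one estimator `(1 + #extreme)/(1 + n_perm)`, never exactly zero, and
the default is 10,000 permutations. For the uniform resampling scheme the
null overlap count is hypergeometric with mean `|A|·|B|/|U|`, which the
test suite checks against the Monte-Carlo null. With heavily discrete
overlap counts the estimator is conservative, so the realized type-I rate
sits somewhat below the nominal level.

## Gene and GWAS-catalog integration

GWAS-catalog records are filtered to autosomal rs-number SNPs at
p ≤ 5×10⁻⁸ whose trait is not in the excluded list (defaults:
ACPA-negative rheumatoid arthritis, ankylosing spondylitis, psoriatic
arthritis); (rsid, trait) duplicates keep the smallest p. Gene features
are TSS-anchored with strand-aware windows: promoter = 1 kbp upstream
(the < 1 kbp convention of standard annotation packages; width
configurable), distal upstream = 1–5 kbp, body = the annotated interval.
Intervals are half-open 0-based internally; CpG/DMR coordinates are
1-based inclusive and converted at the boundary. A region maps to every
protein-coding gene whose features it overlaps by ≥ 1 bp; regions
touching nothing are intergenic and excluded from gene sets. A local
one-sided hypergeometric test with BH adjustment is provided for gene-set
over-representation; it is a self-contained enrichment procedure, not a
client of any external annotation service.

## Synthetic cohorts

The generator emulates the data the analysis assumes, with one global
seed feeding named independent substreams (sites, depths, genotypes,
covariates, phenotype, counts), so outputs are byte-reproducible and
stage-wise stable under config changes.

* **Sites** — clusters of CpGs (default 10 sites, 50 bp apart) separated
  by 5 kbp gaps, mimicking capture-panel targets.
* **Depths** — negative-binomial (mean 30×, size 10) with per-sample
  log-normal multipliers; shallow settings reproduce heavy-tailed
  low-coverage regimes including `N = 0` dropouts.
* **Baseline methylation** — a low/intermediate/high logit-scale mixture
  (means −3/0/+3) reproducing the characteristic bimodality of CpG
  methylation.
* **Covariates** — age ~ Normal(54.2, 7.9); 55.4% female; 16.1% current
  smokers with a realistic missing fraction; cell proportions Dirichlet
  around whole-blood means (neutrophil 0.604, lymphocyte 0.286, monocyte
  0.079, eosinophil 0.025, basophil 0.006) so the PC1 step is meaningful.
  Covariate effects on logit methylation default to small realistic
  values (age 0.005/yr, sex 0.05, smoking 0.1, PC1 0.5).
* **Planted DMRs** — non-overlapping runs of consecutive sites sharing a
  phenotype effect (default 1.5 logit, 10 sites).
* **Over-dispersion** — optional beta-binomial counts parameterized by
  mean and intra-class correlation ρ; ρ = 0 is pure binomial.
* **cis-meQTLs** — SNPs placed within 250 kbp of a site cluster, with a
  per-dosage logit effect over the cluster. Causal sites are re-centered
  so their population-mean methylation sits near 0.5 — genotype-driven
  CpGs show the classic intermediate three-cluster pattern, and this is
  where the arcsine scan's dynamic range lies.
* **Confounding** — an optional SNP→phenotype log-odds path
  (`confound_coef`) creates marginal methylation–phenotype associations
  with no direct effect: the Simpson's-paradox scenario the genetic
  adjustment is designed to resolve. The canonical confounding
  configuration uses strong effects (1.5 logit/dosage on methylation,
  1.5 log-odds/dosage on phenotype).

What the generator does **not** emulate: linkage disequilibrium beyond a
single causal SNP per cluster, bisulfite conversion error, read-level
artifacts, batch effects, or fine-scale genomic covariates of coverage.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to every
artifact of real libraries.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at desk scale, chosen as the smallest sizes
at which the checked properties are statistically stable: a 2,000-site /
60-sample null cohort for calibration; 100-sample cohorts for recovery,
power and attenuation; 10 replicates for selection rates; 200 replicate
tests at 999 permutations for Monte-Carlo calibration; 50 random
instances for the likelihood-oracle comparison and 1,000 for the
region-caller oracle. Instances at or near complete separation are
excluded from oracle comparisons, since the unpenalized MLE is unbounded
there and any two optimizers stop at arbitrary points along the
divergence path.
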
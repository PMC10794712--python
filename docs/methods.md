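# Methods

This note documents the statistical model, the construction of each
annotation class, the numerical choices, and what the synthetic-data tests
do and do not establish.

## Heritability model and estimation

We model the variance of SNP *j*'s standardized effect as
Var(β_j) = Σ_c a_cj τ_c over an annotation stack (focal cell type +
baseline categories + a background union), giving
E[χ²_j] = N Σ_c l(j,c) τ_c + 1 for the GWAS χ² statistics, where
l(j,c) = Σ_k a_ck r²_jk are stratified LD scores. Estimation details:

* **LD scores.** Genotypes are standardized per SNP (missing values
  mean-imputed). The default r² estimator applies the finite-panel
  adjustment r̃² = r² − (1 − r²)/(n − 2); the raw estimator is available
  and is what exact oracle tests use. The window is 1 cM by default (a
  1,000 kb fallback when the cM map is absent); both the window and the
  estimator are configuration, recorded in the output's `window_spec`,
  because neither is canonical. Chromosomes are independent.
* **Regression SNPs.** The χ² regression runs on the intersection of the
  summary statistics with the LD-score rows (optionally restricted to a
  well-imputed list), minus SNPs with χ² > 80 and minus the MHC region
  (chr6:25–34 Mb, 1-based, configurable). Sumstats records whose alleles
  disagree with the panel (unordered {A1,A2}) are dropped with a logged
  count; only χ² enters the regression, so Z's sign never matters.
* **Intercept.** Free by default; the model's literal "+1" is available as
  `intercept_mode="fixed_one"`. A free intercept absorbs confounding-driven
  inflation and is the convention for this regression.
* **Weights.** `two_part` (default): one provisional OLS pass, then a
  single weighted pass with weights 1 / (2·max(Ê[χ²],1)² · max(l_w,1)) —
  inverse heteroskedasticity times inverse LD overcounting, where l_w is
  the all-ones annotation's LD-score column when present (row-max
  otherwise). `ols` disables weighting and is what every exact-recovery
  test uses, since the weighted estimator has no closed-form oracle.
* **Uncertainty.** A delete-a-block jackknife over 200 contiguous
  equal-size blocks of regression SNPs (remainder spread over leading
  blocks) gives the coefficient covariance; block deletion uses cross-
  product downdating, so the cost is one small solve per block. Derived
  statistics (h²_g, enrichment) are re-evaluated per delete-block estimate
  for their jackknife SEs. The SE of τ* propagates the jackknife SE of τ
  through the (point-estimate) scale factor sd(a_c)/(h²_g/M).
* **Derived metrics.** h²_g = Σ_j Σ_c a_cj τ̂_c over panel SNPs; τ*_c =
  τ̂_c·sd(a_c)/(h²_g/M); enrichment = (h²(C)/h²_g)/(Σ_j a_jC/M) with
  h²(C) = Σ_j a_jC·(Σ_c a_cj τ̂_c). For a disjoint binary partition the
  h² proportions sum to 1 identically. A fit with estimated h²_g ≤ 0
  cannot define τ*; the scan flags such rows as failed rather than
  emitting silent NaNs. Negative τ̂ or enrichment is reported as-is;
  exclusion happens only at the FDR stage.
* **Significance.** p = 1 − Φ(τ*/se(τ*)), one-sided for positive τ*,
  relying on approximate normality of the jackknife ratio. The null
  simulations below check this calibration directly.

## Annotations

**scATAC (binary).** A cell type's annotation is 1 for every panel SNP
inside ≥1 of its peaks. BED intervals are 0-based half-open and peaks are
merged before the membership test, so the result is invariant to peak
splitting, duplication and file order; a SNP sitting exactly on a peak's
end coordinate is outside. Peaks are consumed as provided (blacklist
masking is assumed upstream). The dataset background is the element-wise OR
across all cell types' annotations; conditioning on it (plus the baseline
stack) is what makes a focal coefficient cell-type *specific* rather than
generically regulatory.

**scRNA (probabilistic).** Counts are normalized to log2(TP10K + 1)
(zero-total cells dropped with a warning). Per cell type, each gene gets a
one-sided Wilcoxon rank-sum p-value (focal cells vs. all other cells,
pooled); the specific-expression score is the min–max normalization of
−2·log(p) across the gene universe within that cell type, so the most
specific gene scores 1 and the least 0. SNPs inherit the maximum score
among genes linked to them (enhancer–gene link intervals, or gene body
± 100 kb under the window strategy) and 0 when unlinked; the background is
the binary union of links over all analyzed genes. A binarized variant
(positive score → 1) is available.

Choices the construct leaves open, fixed here and surfaced as parameters:
the test is one-sided because the target is specifically *expressed* genes
(two-sided by flag); ties use mid-ranks with tie-corrected variance and a
continuity correction, with the exact Mann–Whitney distribution for groups
of ≤10 cells without ties; the gene universe is genes expressed in ≥10
cells (configurable); a cell type where every gene has the same p-value
gets all-zero scores, with a warning, since nothing is specific.

## Association scan and multiple testing

The scan fits one conditional model per (trait, cell type): focal
annotation + baseline annotations + dataset background, slicing one shared
LD-score table. A failed fit flags its row and the scan continues. Rows
with τ* < 0 are excluded from testing (a depleted annotation is not a
disease-critical cell type) and Benjamini–Hochberg FDR runs per dataset
over the remaining rows, aggregating traits × cell types into one family;
significance is q < 0.05 and a Bonferroni flag at 0.05 is also reported
(family size counted after exclusion by default, pre-exclusion by flag,
and both per-dataset — a global denominator can be formed by the caller).
BH rather than BY is used, the field convention, and control (non-disease)
traits form their own family. Trait rosters can be pruned beforehand:
while any retained pair has |genetic correlation| ≥ 0.9, the pair with the
strongest correlation is resolved by dropping the member with the lower
heritability z-score (deterministic lexicographic tie-break). Concordance
between two scans is the Pearson correlation of −log10 p over matched
(trait, cell type) rows, with companion annotation-level correlations.

## Synthetic data: what it emulates and what it does not

The generator produces every input at desk scale with one seed driving a
named stream per stage (identical configs are byte-identical on disk).

* **Panel.** SNPs fall in LD blocks of mean size 20 (sizes jittered
  uniformly in [10, 30]; per-block correlation jittered ±0.15 around the
  configured mean, 0.8 by default). The jitter matters: real local LD is
  highly variable, and the resulting spread in LD scores is what separates
  the regression slope from its intercept — with uniform blocks the design
  is nearly collinear and ~20% of null fits produced negative ĥ²_g.
  Genotypes default to Gaussian dosages 2·maf + sd·latent from a per-block
  factor model, which achieves the stated correlation expectation exactly;
  a hard-call {0,1,2} mode exists for PLINK round trips but attenuates the
  latent correlation. Centimorgan positions isolate one block per 1 cM
  window.
* **Summary statistics.** z_j = √(1 + N Σ_c l(j,c)τ_c)·ε_j with
  standard-normal ε, so E[χ²] matches the model exactly for the realized
  panel (unadjusted LD scores are used for the expectation). This
  marginal-z formulation is chosen over individual-level phenotype
  simulation for speed with an exact second-moment target. Independent ε
  across SNPs is the default; a block-equicorrelated option approximates
  LD-correlated statistics for jackknife-calibration studies. Replicate
  studies should pass one shared `rng`: structured per-seed streams across
  consecutive integer seeds showed measurable dependence in χ² functionals
  (a ~3σ bias over 1,500 streams), while a single generator is clean.
* **Effect sizes.** Baseline heritability defaults to h² = 0.02 spread
  evenly over SNPs at N = 50,000 — at 2,000–5,000 SNPs this gives mean χ²
  of a few units, the desk-scale analogue of a well-powered GWAS (matching
  both a realistic mean χ² *and* a realistic h² z-score is impossible when
  M is 1,000× smaller than a real panel; we keep mean χ² realistic). The
  planted focal effect is parameterized directly by its target τ*
  (`tau_for_tau_star` inverts the scaling), default τ* = 1.
* **Expression.** Negative-binomial counts (gamma–Poisson, dispersion 2)
  with per-gene base rates and designated marker genes boosted
  `marker_fold`× (default 8) in their cell type, with a returned truth
  table.
* **Intervals.** Per-cell-type peaks cover a Bernoulli fraction of SNPs
  (default 0.1, ±50 bp); gene bodies tile the panel; one enhancer window
  links to each gene.

What passing the synthetic suite shows: the estimator inverts its own
generative model exactly in the noiseless case, is unbiased and jackknife-
calibrated under model-consistent noise, controls FDR on null families,
and detects a planted τ* = 1 cell type essentially always at these sizes.
What it does not show: robustness to model misspecification present in
real data — long-range and cross-population LD, MAF- and LD-dependent
architecture, sample overlap, annotation error, confounding inflation
beyond a free intercept — nor anything about any specific biological
claim. Real-data runs should condition on a full baseline annotation set;
the fixtures use a single all-ones base category as a stand-in for that
stack, which preserves the conditioning structure but none of the
functional-category content.

## Numerical notes and limitations

* Constant annotations (e.g. the all-ones base) have sd = 0, hence τ* = 0
  with an undefined p-value — reported as NaN, by design.
* Annotation correlation of a constant vector is defined as 0 with a
  warning rather than NaN.
* Rank-deficient designs raise an error naming the collinear columns
  rather than silently pseudo-inverting.
* The jackknife needs at least 2 and at most n-regression-SNP blocks; 200
  blocks is the default and the remainder goes to leading blocks.
* The PLINK writer rounds dosages to hard calls; text panels preserve
  dosages to 4 decimals.
* The scan's runtime is dominated by the one shared LD-score pass;
  per-pair fits reuse it and cost a few milliseconds each at desk scale.
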
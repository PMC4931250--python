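# Methods

This note documents the statistical models implemented in `myoqtl`, the
design decisions taken where the procedures admit more than one reading, the
generative model behind the synthetic data, and the problem sizes used by
the test suite and `scripts/acceptance.py`.

## Tissue expression specificity

For a gene × tissue panel of non-negative FPKM-like values, relative
expression `p_{g,t}`, entropy `H_g` (bits, `0·log2 0 ≡ 0`), and target
specificity `Q_g = H_g − log2 p_{g,target}` follow the information-theoretic
specificity-index literature; `Q = 0` iff all expression is in the target
tissue and larger Q means less specific. The index is `1 − Q/max(Q)` over
genes with finite Q. Choices:

* No pseudocount is added to zeros. A gene with `p_target = 0` has infinite
  Q and index 0; an all-zero gene is flagged unscorable and excluded.
* Decile assignment is rank-based with equal-count bins (sizes differ by at
  most one); ties are broken by a stable sort on gene id for reproducibility.
* Scores are ratio- and rank-based, so FPKM and TPM inputs give closely
  similar results; the unit of the input matrix is not otherwise interpreted.

## Trait–expression association

The binary-trait model is OLS of per-gene inverse-normal transformed
expression on disease status with covariates (age, sex, batch; optional
extra columns such as tissue-composition estimates) in the model.
Quantitative traits use a simple regression after the double transform
(inverse normal → residualize on covariates → inverse normal) of both
sides. The rank-based inverse normal maps rank r of n to
`Φ⁻¹((r − 0.5)/n)`; the 0.5 offset is configurable. Ties are ordered
uniformly at random under a seeded generator so the transform has no atoms;
this makes the transform stochastic only on tied data.

FDR is Benjamini–Hochberg by default with Storey q-values behind a flag
(λ grid 0.05–0.95, cubic-spline π₀ smoothed, BH fallback below 100 tests,
where π₀ estimation is unstable).

## GO enrichment

Per term, membership is regressed on the signed −log10 association p-value
and log10 gene length with a logistic model (statsmodels GLM). The length
covariate absorbs the length–power confound: longer genes yield better-
powered association tests, and terms collecting long genes would otherwise
look enriched. Note the adjustment is linear in log10 length on the logit
scale; membership patterns that depend on length much more sharply than
log-linearly are only partially corrected — the synthetic confounded term is
therefore generated with membership probability log-linear in length.
Presentation keeps the top 20 terms per trait and direction, assigns each
term its best rank across lists, and prunes terms whose gene-set Jaccard
overlap with a better-ranked kept term exceeds 0.5 (configurable; the
pruning rule is this package's own, declared parameterization). A
complete-linkage/Euclidean clustering helper orders term coefficient vectors
for display only.

## cis-eQTL mapping

Expression preparation: per-gene inverse normal; residualization on known
covariates; computation of the top-K principal components of the residual
matrix (sample space, via SVD); residualization on covariates plus
components; final inverse normal. This latent-factor adjustment removes
broad unmodelled structure (batch, environmental and technical factors) and
is this package's stand-in for external factor-analysis tools; K defaults to
60 in the pipeline configuration, capped at n/4. With few thousand genes a
large K noticeably absorbs per-gene genetic signal (the components chase
individual strong eQTL genes), so study-scale recovery analyses here use
K = 10 against the planted 3-factor + batch structure; at the gene counts of
a real transcriptome the distinction fades.

Testing: every (gene, variant) pair with the variant within 1 Mb (inclusive
at both boundaries) of the gene's most upstream TSS (strand-aware; a
most-distal override exists) is fitted with `Y = α + βG + ε`, two-sided t
test, MAC > 5 required, q-values across all tested pairs, significance at
q ≤ 0.05. LD pruning is greedy per gene: keep the smallest-p record, drop
records with r² ≥ 0.2 (squared Pearson correlation of dosages) to any kept
record, repeat. Best-per-gene keeps the smallest p, ties broken by genomic
position.

The conditional analysis of a GWAS variant–gene pair starts from a model
containing the GWAS variant's dosage and forward-selects the cis variant
with the smallest addition p-value while that p-value is below 0.0019 (a
dataset-derived stopping constant retained as a configurable default; it
corresponded to the gene-level 5%-FDR p-value threshold in the motivating
study). The conditional p is the GWAS variant's Wald p in the final model —
one of two possible readings (the other being a drop-one comparison); this
one is implemented because it directly answers whether the GWAS variant
retains an effect given the selected signals. Selected variants with
r² > 0.99 to the GWAS variant flag the result non-identifiable.

## Allele-specific expression

Filters remove, in order of precedence: sites whose read-mapping-simulation
coverage lies outside [193, 202] (the accepted band for a 101-bp paired-end
design; configurable), blacklisted sites, sites near indels, zero-total
rows, and rows with fracRef outside (0.01, 0.99). A site missing from the
mappability mask is a hard error — silent pass-through would defeat the
filter. Strand rows are merged after filtering and before any statistics.

The expected fracRef is estimated per sample and ordered allele pair (A>G
and G>A are distinct, capturing reference-mapping preference): the pooled
ref/total ratio over the group's sites, where sites with coverage strictly
above the sample's 75th percentile are first thinned to 30 reads by a seeded
hypergeometric draw from the observed ref/alt pool (which preserves the
expectation while bounding the influence of any single high-coverage site).
Thinned counts feed only the expectation, never the per-site test.

Each (sample, site) gets an exact two-sided binomial test of the ref count
against the group expectation. Two-sidedness is the minimum-likelihood
method (sum of all outcome probabilities not exceeding the observed
outcome's); a central 2·min-tail variant is available behind a flag.
Variants tested in ≥ 10 samples (post-filter) are combined with Fisher's
method (`−2Σ ln p` against chi-square with 2k df). Storey q ≤ 0.05 is the
significance rule.

Known property: the group expectation is estimated from all sites of an
allele pair, so sites with true imbalance contaminate it; in a synthetic
mixture with many strong planted effects this inflates null rejections.
The procedure inherits this from its design; the null-calibration tests
therefore use a no-effect configuration.

## Enhancer classification and matched-null enrichment

Enhancer-state intervals (an 11-state ChromHMM-style vocabulary; the
enhancer label set is configurable) are merged into maximal contiguous runs;
runs ≥ 3,000 bp are stretch enhancers, runs ≤ 800 bp typical enhancers
(boundaries inclusive), 800–3,000 bp intermediate and excluded from both
classes by default. A quantile-based stretch threshold (longest 10/5/1%) is
available. An interval is tissue-specific when at most 10% of its bases
(configurable) overlap active chromatin in every other tissue.

Enrichment of a SNP set in a feature set is count-based: each test SNP is
matched on MAF bin (width 0.02), log10 TSS-distance bin (width 0.5) and
LD-neighbour-count bin ({0, 1–4, 5–19, 20–99, ≥100}; neighbours are r² ≥ 0.8
within ±1 Mb); each null set draws one matched candidate per test SNP
without replacement within the set; pools under the minimum size (500 at
study scale; smaller in the demo configuration) widen by dropping the LD
bin, then the TSS bin, then fall back to the whole universe. The fold is
observed/mean-null overlap and the empirical p is
`(1 + #{null ≥ obs}) / (n_null + 1)`, which is super-uniform under the null
by construction. The stratified analysis runs this per specificity decile
for stretch and typical features separately. The parametric approximation
used by external enrichment tools is deliberately not reproduced; the
count-based fold with an empirical p is transparent and exactly testable.

## Synthetic-data generator

* **Genotypes.** Haplotypes per LD block follow a copying chain: the first
  variant is Bernoulli at the block's alternate-allele frequency (uniform in
  `maf_range`, one frequency per block so copying preserves the marginal),
  and each next variant copies its neighbour with probability `ld_decay`.
  Adjacent-dosage r² is `ld_decay²`; blocks are independent;
  `blocks_per_chrom` blocks form one artificial chromosome (variants every
  2 kb). Dosages are HWE hard calls (sum of two haplotypes).
* **Expression.** Per gene, on a latent log scale: planted standardized cis
  effect `beta_std · G_std` (effect sizes cycled from the configured grid,
  default {0, 0.25, 0.5, 1}), age/sex effects, batch shifts, latent-factor
  loadings, unit Gaussian noise; the emitted matrix is the exponential
  (positive, FPKM-like; all downstream transforms are rank-based). The truth
  table records both `beta_std` and `beta`, the same effect per allele copy
  on the doubly-transformed analysis scale,
  `beta_std / (sd(G)·sqrt(1 + beta_std²))`, which is the quantity the eQTL
  mapper estimates. Recovery regressions compare standardized estimates
  (`beta_est · sd(G)`) with `beta_std/sqrt(1 + beta_std²)`; the residual
  attenuation of a few percent reflects the inverse-normal transform's
  compression of strongly trimodal expression, a property of the analysis
  recipe itself.
* **Tissue panel.** Background genes spread a log-normal baseline
  near-uniformly across 16 tissues (entropy close to 4 bits); planted
  specific genes concentrate 92–98% of panel expression in the target
  tissue with elevated baselines, landing in decile 10 by construction.
* **Allelic counts.** Coverage per heterozygous sample × site is
  gamma-Poisson (negative binomial; mean 50, dispersion 0.3 by default);
  ref counts are binomial at the site's true fracRef — an ordered-allele-pair
  baseline in [0.47, 0.53] for null sites, a planted value (default 0.7) for
  imbalanced sites, and 0.9/0.1 for mapping-bias sites. Bias sites get a
  simulated-coverage value outside [193, 202] so the filter must remove
  them; the read-mapping simulation itself is not re-run — its output is
  planted directly, which is exactly what the filter consumes. A few sites
  carry blacklist/near-indel flags. Counts are emitted split across strands.
* **Chromatin.** Background stretch runs (3–6 kb) and typical runs
  (200–800 bp) of enhancer states are placed uniformly on a 200-bp grid to
  target coverages (defaults 8% stretch / 2% typical of the synthetic
  genome — generous relative to real tissue so that desk-scale enrichment
  folds have usable precision). In the target tissue, additional stretch
  enhancers are planted over causal eQTL variants with a per-decile
  probability calibrated analytically so the realized enrichment fold ramps
  linearly from 1 (decile 1) to `stretch_target_fold` (default 3) at decile
  10, accounting for the coverage the planted intervals themselves add to
  the null expectation. Typical enhancers are never planted over eQTLs.
  Runs are emitted as consecutive 200-bp bins with varying enhancer-state
  labels so run-merging is genuinely exercised; gene TSSs get Active_TSS
  bins, plus sparse transcribed/repressed/quiescent filler.
* **Phenotypes and GO.** Disease status (balanced 0/1) and quantitative
  traits are drawn first; planted differential-expression effects
  (default |beta| 0.8, 2% of genes, half up/half down) are added to the
  expression of chosen genes on the log scale — the generative direction
  that matches a regression of expression on trait. Gene lengths are
  log-normal; an optional directional length-coupled disease effect
  (`length_confound`) makes longer genes systematically more associated,
  and the planted confounded GO term samples members with probability
  log-linear in length (the functional form the enrichment model adjusts
  for). Planted positive/negative GO terms seed up-/down-regulated genes
  among random members.

What the generator does **not** emulate: realistic human LD maps and allele
frequency spectra, sequence-level reads, isoform structure, case/control
ascertainment, relatedness, or population structure. Passing recovery tests
demonstrate the estimators and their plumbing are correct under the stated
generative model, not that the pipeline is robust to every artifact of real
cohort data.

## Problem sizes and numerical choices

* eQTL recovery runs at 267 samples, 2,000 genes, 20,000 variants (~1
  million cis pairs), K = 10 factors; null-p uniformity is checked on the
  planted-variant pairs of zero-effect genes (one independent pair per
  gene). Runs in well under a minute.
* Conditional discrimination uses 200 replicates per scenario (shadow proxy
  at r² ≈ 0.6; independent effect 0.3 beside a 0.7 causal signal), n = 267,
  20 null variants per locus.
* ASE recovery uses ~480 sites at 50× mean coverage across 267 samples;
  the exact-test oracle comparison covers 10,000 random (k, n ≤ 500, p₀)
  cases against an independent log-space enumeration.
* Enrichment uses 2,500 genes / 25,000 variants with all-causal effect
  sizes {0.5, 1}: one full run at 1,000 null sets plus ten seeded replicates
  at 250 null sets for the trend/recovery proportions and forty feature
  randomizations for null calibration. The Spearman trend across 10 deciles
  has a heavy-tailed null distribution, so the typical-enhancer no-trend
  proportion is asserted at 80% rather than the ~86% a continuous null
  would give.
* The GO confound check runs 100 replicates at 1,000 genes × 120 samples.
* Exact binomial p-values compute the full pmf (scipy) with a 1e-7 relative
  tolerance when comparing outcome probabilities to the observed one,
  guarding against float noise on symmetric cases.
* All randomness flows through numpy Generators; stage seeds are spawned
  from one root SeedSequence, so each stage is individually reproducible
  and identical seeds give byte-identical output files.

## Limitations

* The latent-factor adjustment is PCA-based; it removes linear structure
  only and, at small gene counts, partially absorbs strong genetic effects.
* The ASE expectation contamination noted above.
* The matched-null sampler widens bins when pools are thin rather than
  failing the SNP by default at demo scale; at study scale the minimum pool
  (500) matches the external-tool convention.
* Interval operations assume non-overlapping per-tissue segmentations
  (enforced on read) and 0-based half-open BED coordinates; VCF positions
  are 1-based and converted internally.
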
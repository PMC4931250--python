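# myoqtl

Regulatory genomics of tissue-specific expression in bulk RNA-seq cohorts:
an integrated, tested reimplementation of the analysis pipeline used to
dissect the genetic regulatory signature of type 2 diabetes in skeletal
muscle. The package is aimed at statistical geneticists who want each stage
of such a study — from tissue-specificity scoring to stretch-enhancer
enrichment — as reusable, individually testable components, together with a
synthetic-data generator that plants known effects so every stage can be
validated by recovery.

## What it computes

**Tissue expression specificity.** From a gene × tissue FPKM panel (16
tissues by default, one flagged as the target, e.g. skeletal muscle), each
gene *g* is scored by its relative expression `p_{g,t} = x_{g,t} / Σ_t x_{g,t}`,
its Shannon entropy `H_g = −Σ_t p_{g,t} log2 p_{g,t}` (bits), its
target-tissue specificity `Q_g = H_g − log2 p_{g,target}` (0 = all expression
in the target tissue), and the expression specificity index
`ESI_g = 1 − Q_g / max_g Q_g ∈ [0, 1]`. Genes are binned into equal-count
deciles; decile 10 holds genes highly and specifically expressed in the
target tissue.

**Trait–expression association and GO enrichment.** Binary disease status
uses `Y_ij = α_j + β_j T_i + γ_j' Z_i + ε` on inverse-normal transformed
expression; quantitative traits use a simple regression after both sides are
transformed by inverse normal → covariate residualization → inverse normal.
GO terms are scored with the logistic model
`logit(π_j) = α + β P_j + γ L_j`, where `P_j` is the signed −log10
association p-value and `L_j` the log10 gene length (guarding against the
length–power confound).

**cis-eQTL mapping and conditional analysis.** Expression is adjusted by a
latent-factor step (inverse normal → removal of covariates plus top-K
principal components of the covariate residuals → inverse normal), then each
gene is tested against every variant within 1 Mb of its most upstream TSS
with `Y_ij = α + β_js G_is + ε` (dosage G, FDR across all pairs, q ≤ 0.05
significant), followed by per-gene greedy LD pruning at r² < 0.2 and
best-per-gene selection. For GWAS variants, an iterative conditional
analysis forward-selects other cis variants (stopping at p ≥ 0.0019, the
GWAS variant held in the model) and reports the GWAS variant's p-value in
the final model, separating independent eQTL signals from LD shadows.

**Allele-specific expression.** Allelic read counts at heterozygous exonic
SNPs are filtered (read-mapping simulation coverage inside [193, 202],
ENCODE-style blacklist and near-indel masks, 0.01 < fracRef < 0.99), strands
are merged, a per-sample per-allele-pair expected fracRef is estimated with
top-quartile coverage down-sampled to 30×, each site gets an exact two-sided
binomial test against that expectation, and variants observed in ≥ 10
samples are combined with Fisher's method; significance via Storey q ≤ 0.05.

**Stretch-enhancer enrichment.** Enhancer-state runs from 200-bp chromatin
segmentations are classified as stretch (≥ 3 kb) or typical (≤ 800 bp);
best-per-gene eQTL SNPs are tested for feature overlap against null SNP sets
matched on MAF, TSS distance and LD-neighbour count (r² ≥ 0.8 within 1 Mb),
stratified by specificity decile — reproducing the signature pattern of
rising stretch-enhancer enrichment with increasing tissue specificity.

**Synthetic data.** `myoqtl.sim` generates all inputs with planted ground
truth: HWE genotypes with block LD (haplotype-copying model), expression
with planted cis effects plus covariate/batch/latent structure, a tissue
panel with planted specific genes, negative-binomial allelic coverage with
planted imbalance and mapping-bias artifacts, chromatin segmentations with
stretch enhancers planted over high-specificity eQTLs, and phenotypes with
planted differentially expressed genes inside planted GO terms.

## Worked example

```bash
myoqtl run-all --out demo_run --seed 1
```

runs every stage on a demo-scale synthetic study (150 samples, 300 genes,
4,000 variants) in about a minute and writes TSV results plus YAML manifests
into `demo_run/`. Inspecting the recovered effects against the planted truth:

```python
import pandas as pd
rec = pd.read_csv("demo_run/eqtl_best_per_gene.tsv", sep="\t")
truth = pd.read_csv("demo_run/truth/eqtl_truth.tsv", sep="\t")
hits = rec.merge(truth[truth.beta_std != 0], on=["gene_id", "variant_id"])
print(len(truth[truth.beta_std != 0]), "planted eQTLs,",
      len(hits), "recovered as the best SNP of their gene")
```

prints `112 planted eQTLs, 44 recovered as the best SNP of their gene`:
at demo scale roughly 40% of nonzero planted effects are rediscovered as
exactly their gene's top association — the rest are either weak-effect
(standardized beta 0.25) genes that miss the q ≤ 0.05 cut at n = 150, or
genes whose top SNP is a tight LD proxy of the planted variant rather than
the variant itself. The study-scale run in `scripts/acceptance.py` detects
~90% of planted effects. Stage-by-stage runs are
available as subcommands (`myoqtl simulate`, `myoqtl mesi`, `myoqtl eqtl`,
`myoqtl conditional`, `myoqtl ase`, `myoqtl enhancers`, `myoqtl enrich`),
all sharing one artefact directory.

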
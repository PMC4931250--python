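"""Expression simulation with planted additive cis effects and structure.

Each gene's pre-transform expression is built on a latent normal scale:

    y_g = beta_s * G_std + covariate effects + batch shifts
          + latent-factor loadings + N(0, 1) noise

where ``beta_s`` is the planted standardized cis effect (possibly zero) and
``G_std`` the standardized dosage of the gene's planted cis variant. The
emitted matrix is ``exp(y)`` (FPKM-like, positive); since every downstream
transform is rank-based, the exponential is irrelevant to recovery.

The truth table records, per gene, the planted variant, the standardized
effect ``beta_std``, and ``beta`` -- the same effect expressed per allele
copy on the analysis scale (after covariate/factor removal and the final
inverse-normal standardization), i.e. ``beta_std / (sd(G) * sqrt(1 +
beta_std**2))``. Downstream per-allele estimates are directly comparable to
this column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import GeneAnnotation, GenotypeMatrix
from .config import SimConfig


def simulate_genes(
    genotypes: GenotypeMatrix, config: SimConfig, rng: np.random.Generator
) -> GeneAnnotation:
    """Place genes with known TSS near randomly chosen anchor variants."""
    g = config.n_genes
    anchor = rng.integers(0, genotypes.n_variants, size=g)
    var = genotypes.variants
    tss = var["pos"].to_numpy()[anchor] + rng.integers(-50_000, 50_001, size=g)
    tss = np.maximum(tss, 1)
    strand = np.where(rng.random(g) < 0.5, "+", "-")
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(g)],
            "chrom": var["chrom"].to_numpy()[anchor],
            "strand": strand,
            "tss_list": [(int(t),) for t in tss],
        }
    )
    return GeneAnnotation(genes=genes)


def simulate_expression(
    genotypes: GenotypeMatrix,
    genes: GeneAnnotation,
    config: SimConfig,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x sample FPKM-like matrix with planted cis effects.

    Returns ``(expression, covariates, eqtl_truth)``. ``covariates`` holds
    age, sex and batch per sample (the known covariates of every downstream
    model). ``eqtl_truth`` has one row per planted gene: gene_id, variant_id,
    beta_std (standardized planted effect, may be 0) and beta (analysis-scale
    per-allele effect).
    """
    n, g = config.n_samples, config.n_genes
    if genotypes.n_samples != n:
        raise ValueError("genotype sample count does not match config")

    covariates = pd.DataFrame(
        {
            "age": rng.normal(60, 8, size=n).round(1),
            "sex": rng.integers(0, 2, size=n),
            "batch": [f"b{b}" for b in rng.integers(0, config.batch_levels, size=n)],
        },
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
    )

    # planted cis effects: a fraction of genes gets an effect size cycled
    # through the configured grid; the planted variant is drawn from the
    # gene's cis window (same chromosome, within 1 Mb of the TSS anchor)
    var = genotypes.variants
    anchors = genes.window_anchor.to_numpy()
    chroms = genes.genes["chrom"].to_numpy()
    n_eqtl = int(round(config.frac_eqtl_genes * g))
    eqtl_gene_idx = np.sort(rng.choice(g, size=n_eqtl, replace=False))
    effect_grid = np.asarray(config.eqtl_effect_sizes, dtype=float)

    truth_rows = []
    y = rng.normal(0.0, noise_sd, size=(g, n))

    # covariate, batch and latent-factor structure
    age_std = (covariates["age"] - covariates["age"].mean()).to_numpy()
    age_std /= age_std.std() or 1.0
    sex = covariates["sex"].to_numpy().astype(float)
    batch_codes = pd.Categorical(covariates["batch"]).codes
    gamma_age = rng.normal(0, 0.2, size=g)
    gamma_sex = rng.normal(0, 0.2, size=g)
    batch_eff = rng.normal(0, 0.5, size=(g, config.batch_levels))
    y += gamma_age[:, None] * age_std[None, :]
    y += gamma_sex[:, None] * sex[None, :]
    y += batch_eff[:, batch_codes]
    if config.n_latent_factors > 0:
        factors = rng.normal(0, 1, size=(config.n_latent_factors, n))
        loadings = rng.normal(0, 0.5, size=(g, config.n_latent_factors))
        y += loadings @ factors

    pos_arr = var["pos"].to_numpy()
    chrom_arr = var["chrom"].to_numpy()
    for k, gi in enumerate(eqtl_gene_idx):
        cis = np.where(
            (chrom_arr == chroms[gi]) & (np.abs(pos_arr - anchors[gi]) <= 1_000_000)
        )[0]
        dos = genotypes.dosages[cis]
        ok = cis[dos.std(axis=1) > 0]
        if ok.size == 0:
            continue
        vi = int(rng.choice(ok))
        beta_s = float(effect_grid[k % effect_grid.size])
        gvec = genotypes.dosages[vi]
        sd_g = gvec.std()
        y[gi] += beta_s * (gvec - gvec.mean()) / sd_g
        denom = sd_g * np.sqrt(noise_sd**2 + beta_s**2)
        beta_analysis = beta_s / denom if denom > 0 else 0.0
        truth_rows.append(
            {
                "gene_id": genes.genes["gene_id"].iloc[gi],
                "variant_id": var["id"].iloc[vi],
                "beta_std": beta_s,
                "beta": beta_analysis,
            }
        )

    expression = pd.DataFrame(
        np.exp(y),
        index=pd.Index(genes.genes["gene_id"], name="gene_id"),
        columns=genotypes.sample_ids,
    )
    eqtl_truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "variant_id", "beta_std", "beta"]
    )
    return expression, covariates, eqtl_truth
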
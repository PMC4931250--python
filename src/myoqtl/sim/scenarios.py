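"""Focused single-locus scenarios for the conditional GWAS-eQTL analysis.

Two canonical situations decide whether a GWAS variant is an independent
eQTL or a mere LD shadow of a stronger signal:

* shadow: the GWAS variant is only an LD proxy (target r^2 ~ 0.6) of the one
  causal cis variant; after the causal variant enters the model the GWAS
  variant's conditional p should look null.
* independent: the GWAS variant carries its own effect on top of a stronger
  causal variant it is uncorrelated with; its conditional p should stay
  significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import GeneAnnotation, GenotypeMatrix


def _hap_block(
    n: int, n_var: int, freq: float, copy_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Copying-model dosages (n_var, n): adjacent haplotype corr = copy_prob."""
    haps = np.empty((2 * n, n_var), dtype=np.int8)
    haps[:, 0] = rng.random(2 * n) < freq
    for j in range(1, n_var):
        copy = rng.random(2 * n) < copy_prob
        fresh = (rng.random(2 * n) < freq).astype(np.int8)
        haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    return (haps[:n] + haps[n:]).T.astype(float)


def _assemble(
    dosages: np.ndarray, rng: np.random.Generator
) -> tuple[GenotypeMatrix, GeneAnnotation]:
    n_var, n = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": 10_000 + np.arange(n_var) * 2_000,
            "id": [f"var{i:04d}" for i in range(n_var)],
            "ref": "A",
            "alt": "G",
        }
    )
    gm = GenotypeMatrix(
        variants=variants,
        dosages=dosages,
        sample_ids=[f"S{i:04d}" for i in range(n)],
    )
    genes = GeneAnnotation(
        genes=pd.DataFrame(
            {
                "gene_id": ["GENE"],
                "chrom": ["chr1"],
                "strand": ["+"],
                "tss_list": [(10_000,)],
            }
        )
    )
    return gm, genes


def conditional_shadow_scenario(
    n: int = 267,
    n_null_variants: int = 20,
    beta: float = 0.7,
    proxy_r: float = 0.775,  # r^2 ~ 0.6
    freq: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GenotypeMatrix, GeneAnnotation, str]:
    """GWAS variant = LD proxy of the sole causal variant; no own effect.

    Returns (expression frame with one gene, genotypes, genes, gwas variant id).
    Variant 0 is causal; variant 1 is the GWAS proxy; the rest are null.
    """
    rng = np.random.default_rng(seed)
    pair = _hap_block(n, 2, freq, proxy_r, rng)
    nulls = _hap_block(n, n_null_variants, freq, 0.0, rng)
    dos = np.vstack([pair, nulls])
    gm, genes = _assemble(dos, rng)
    g = dos[0]
    gs = (g - g.mean()) / (g.std() or 1.0)
    y = beta * gs + rng.normal(0, 1, n)
    Y = pd.DataFrame([y], index=pd.Index(["GENE"], name="gene_id"), columns=gm.sample_ids)
    return Y, gm, genes, gm.variants["id"].iloc[1]


def conditional_independent_scenario(
    n: int = 267,
    n_null_variants: int = 20,
    beta_causal: float = 0.7,
    beta_gwas: float = 0.3,
    freq: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GenotypeMatrix, GeneAnnotation, str]:
    """GWAS variant with its own effect beside a stronger, uncorrelated eQTL."""
    rng = np.random.default_rng(seed)
    dos = _hap_block(n, 2 + n_null_variants, freq, 0.0, rng)
    gm, genes = _assemble(dos, rng)
    g1, g2 = dos[0], dos[1]
    s1 = (g1 - g1.mean()) / (g1.std() or 1.0)
    s2 = (g2 - g2.mean()) / (g2.std() or 1.0)
    y = beta_causal * s1 + beta_gwas * s2 + rng.normal(0, 1, n)
    Y = pd.DataFrame([y], index=pd.Index(["GENE"], name="gene_id"), columns=gm.sample_ids)
    return Y, gm, genes, gm.variants["id"].iloc[1]
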
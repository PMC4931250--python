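"""Genotype simulation: HWE dosages with block LD from a haplotype-copying chain.

Haplotypes are generated per LD block: the first variant's allele is a
Bernoulli draw at the block's alternate-allele frequency, and each subsequent
variant copies the previous variant's allele with probability ``ld_decay``
(drawing fresh otherwise). All variants in a block share one allele
frequency, which keeps the marginal frequency exact under copying; the
haplotype correlation between variants ``d`` steps apart is ``ld_decay**d``,
so the dosage r-squared decays as ``ld_decay**(2d)``. Blocks are independent
and each chromosome holds a fixed number of blocks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import GenotypeMatrix
from .config import SimConfig

_BASES = np.array(list("ACGT"))


def simulate_genotypes(config: SimConfig, rng: np.random.Generator) -> GenotypeMatrix:
    """Simulate hard-call dosages in {0,1,2} with block LD structure."""
    n, m = config.n_samples, config.n_variants
    if n < 2:
        raise ValueError("n_samples must be >= 2")
    bs = config.ld_block_size
    n_blocks = int(np.ceil(m / bs))
    lo, hi = config.maf_range

    dosages = np.empty((m, n), dtype=np.int8)
    freqs = np.empty(m)
    for b in range(n_blocks):
        start = b * bs
        size = min(bs, m - start)
        f = rng.uniform(lo, hi)
        haps = np.empty((2 * n, size), dtype=np.int8)
        haps[:, 0] = rng.random(2 * n) < f
        for j in range(1, size):
            copy = rng.random(2 * n) < config.ld_decay
            fresh = (rng.random(2 * n) < f).astype(np.int8)
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
        dosages[start : start + size] = (haps[:n] + haps[n:]).T
        freqs[start : start + size] = f

    # genome layout: blocks_per_chrom blocks per artificial chromosome
    per_chrom = config.blocks_per_chrom * bs
    vidx = np.arange(m)
    chrom_no = vidx // per_chrom + 1
    within = vidx % per_chrom
    pos = 10_000 + within * config.variant_spacing_bp  # 1-based
    ref = _BASES[rng.integers(0, 4, size=m)]
    alt_off = rng.integers(1, 4, size=m)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_off) % 4]
    variants = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom_no],
            "pos": pos,
            "id": [f"var{i:06d}" for i in vidx],
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypeMatrix(
        variants=variants,
        dosages=dosages.astype(float),
        sample_ids=[f"S{i:04d}" for i in range(n)],
    )
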